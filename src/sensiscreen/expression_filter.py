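"""Quantile normalization and the differential-expression union filter.

The filter nominates candidate target genes from expression profiling
of treated vs control samples: after quantile normalization, a gene
passes when (i) its fold change exceeds 2 in either direction, (ii) its
mean intensity exceeds 10, and (iii) its two-sample p-value is below
0.05.  Passing sets from several cell lines are combined by set union
(intersection available).

Fold change is evaluated symmetrically — max(fc, 1/fc) — so strongly
down-regulated targets clear the same ">2" gate as up-regulated ones.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Gene x sample intensity matrix with a condition label per sample."""

    values: pd.DataFrame  # index: genes, columns: samples
    conditions: pd.Series  # index: samples -> condition label

    def __post_init__(self) -> None:
        self.conditions = pd.Series(self.conditions)
        missing = set(self.values.columns) - set(self.conditions.index)
        if missing:
            raise ValueError(f"samples without condition labels: {sorted(missing)}")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene IDs")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative intensities")

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions[s] == condition]


def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample onto the common distribution of mean order statistics.

    Each column is ranked; rank i is replaced by the cross-column mean
    of the i-th order statistics.  Ties within a column receive the
    mean of the order-statistic means their positions span.  Idempotent.
    """
    df = matrix.values
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    arr = df.to_numpy(dtype=float)
    mean_sorted = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        if np.ptp(col) == 0:
            warnings.warn(f"sample {df.columns[j]!r} has all-identical values")
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = mean_sorted
        # ties span consecutive order statistics -> each gets the span mean
        tie_mean = pd.DataFrame({"v": col, "a": assigned}).groupby("v")["a"].transform("mean")
        out[:, j] = tie_mean.to_numpy()
    res = pd.DataFrame(out, index=df.index, columns=df.columns)
    return ExpressionMatrix(res, matrix.conditions.copy())


@dataclass(frozen=True)
class DEResult:
    """Per-gene differential-expression statistics and the pass flag."""

    gene: str
    fold_change: float  # treated/control ratio (direction preserved)
    abs_fold_change: float  # max(fc, 1/fc)
    mean_intensity: float
    p_value: float
    passes: bool
    excluded: bool = False


def de_filter(
    matrix: ExpressionMatrix,
    control: str,
    treated: str,
    fc_threshold: float = 2.0,
    intensity_threshold: float = 10.0,
    p_threshold: float = 0.05,
    test: str = "welch",
    intensity_rule: str = "mean",
) -> list[DEResult]:
    """Apply the three-criterion differential-expression filter per gene.

    ``test`` is 'welch' (default; array variances rarely match) or
    'pooled'.  ``intensity_rule`` is 'mean' (mean normalized intensity
    over all samples; default) or 'min' (every sample must exceed the
    floor).  Genes with a zero control mean have no defined fold change
    and are returned flagged ``excluded``.
    """
    if test not in ("welch", "pooled"):
        raise ValueError("test must be 'welch' or 'pooled'")
    ctrl_samples = matrix.samples_in(control)
    trt_samples = matrix.samples_in(treated)
    if len(ctrl_samples) < 2 or len(trt_samples) < 2:
        raise ValueError("need >=2 samples per condition")
    results: list[DEResult] = []
    for gene, row in matrix.values.iterrows():
        c = row[ctrl_samples].to_numpy(dtype=float)
        t = row[trt_samples].to_numpy(dtype=float)
        mean_int = float(row.mean())
        if c.mean() == 0.0:
            results.append(DEResult(str(gene), np.nan, np.nan, mean_int, np.nan,
                                    passes=False, excluded=True))
            continue
        fc = float(t.mean() / c.mean())
        abs_fc = max(fc, 1.0 / fc) if fc > 0 else np.inf
        if c.var(ddof=1) == 0.0 and t.var(ddof=1) == 0.0:
            p = 1.0 if t.mean() == c.mean() else 0.0
        else:
            p = float(stats.ttest_ind(t, c, equal_var=(test == "pooled")).pvalue)
        if intensity_rule == "mean":
            intense = mean_int > intensity_threshold
        else:
            intense = bool(row.min() > intensity_threshold)
        passes = (abs_fc > fc_threshold) and intense and (p < p_threshold)
        results.append(DEResult(str(gene), fc, float(abs_fc), mean_int, p, passes))
    return results


def passing_genes(results: list[DEResult]) -> set[str]:
    return {r.gene for r in results if r.passes}


def union_gene_set(
    results_per_cell_line: list[list[DEResult]], mode: str = "union"
) -> set[str]:
    """Combine passing-gene sets across cell lines (union by default)."""
    if mode not in ("union", "intersect"):
        raise ValueError("mode must be 'union' or 'intersect'")
    sets = [passing_genes(r) for r in results_per_cell_line]
    if not sets:
        return set()
    if mode == "union":
        return set().union(*sets)
    out = sets[0]
    for s in sets[1:]:
        out &= s
    return out


def de_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def read_expression(values_path, conditions_path) -> ExpressionMatrix:
    """Read a gene x sample CSV plus a (sample, condition) map CSV."""
    values = pd.read_csv(values_path, index_col=0)
    cond = pd.read_csv(conditions_path)
    if not {"sample", "condition"} <= set(cond.columns):
        raise ValueError("condition map needs 'sample' and 'condition' columns")
    series = cond.set_index("sample")["condition"]
    return ExpressionMatrix(values, series)
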