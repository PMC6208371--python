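"""End-to-end pipeline orchestration: simulate/ingest -> QC -> hit calls.

The pipeline is configured from a YAML mapping with sections
``generator`` (GeneratorConfig fields), ``hits`` (HitCallConfig
fields) and top-level keys ``normalization`` ('plate'|'screen'),
``contrast`` ('arm'|'nc'), ``ssmd_threshold`` and ``qc_policy``.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import hit_calling, qc_normalize, screen_model, synthetic_data
from .errors import SchemaError, SensiscreenError

log = logging.getLogger("sensiscreen")


class QCFailure(SensiscreenError):
    """The screen failed the SSMD quality gate."""


_TOP_KEYS = {"generator", "hits", "normalization", "contrast", "ssmd_threshold", "qc_policy"}


def _build(cls, mapping: dict, what: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise SchemaError(f"unknown {what} key(s): {sorted(unknown)}")
    return cls(**mapping)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    generator: synthetic_data.GeneratorConfig
    hits: hit_calling.HitCallConfig
    normalization: str = "plate"
    contrast: str = "arm"
    ssmd_threshold: float = qc_normalize.DEFAULT_SSMD_THRESHOLD
    qc_policy: str = "all"

    @classmethod
    def from_mapping(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict):
            raise SchemaError("pipeline config must be a mapping")
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise SchemaError(f"unknown pipeline config key(s): {sorted(unknown)}")
        gen_raw = dict(raw.get("generator") or {})
        if "fractions" in gen_raw:
            gen_raw["fractions"] = dict(gen_raw["fractions"])
        for key in ("sensitizer_ratio", "desensitizer_ratio", "vehicle_toxic_low",
                    "vehicle_toxic_high", "drug_curve"):
            if key in gen_raw:
                gen_raw[key] = tuple(gen_raw[key])
        gen = _build(synthetic_data.GeneratorConfig, gen_raw, "generator")
        hits = _build(hit_calling.HitCallConfig, dict(raw.get("hits") or {}), "hit-call")
        return cls(
            generator=gen,
            hits=hits,
            normalization=raw.get("normalization", "plate"),
            contrast=raw.get("contrast", "arm"),
            ssmd_threshold=float(raw.get("ssmd_threshold", qc_normalize.DEFAULT_SSMD_THRESHOLD)),
            qc_policy=raw.get("qc_policy", "all"),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise SchemaError(f"malformed YAML config {path}: {exc}") from exc
        return cls.from_mapping(raw or {})


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    seed: int | None = None,
    force: bool = False,
) -> dict:
    """Simulate -> QC -> hit-call; write qc.csv, hits.csv, truth.csv, summary.json.

    Raises :class:`QCFailure` after writing partial outputs (plus a
    manifest marking incompleteness) if the SSMD gate fails and
    ``force`` is not set.  Returns the summary dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    if seed is not None:
        gen = dataclasses.replace(gen, seed=seed)
    log.info("simulating screen: %d mimics, seed %d", gen.n_mimics, gen.seed)
    dataset, truth = synthetic_data.simulate_screen(gen)
    screen_model.write_screen(dataset, outdir / "signals.csv", outdir / "maps.csv")
    truth.to_csv(outdir / "truth.csv", index=False)

    qc = qc_normalize.plate_qc(dataset, config.ssmd_threshold)
    drift = qc_normalize.control_drift(dataset)
    qc.to_csv(outdir / "qc.csv", index=False)
    qc_ok = qc_normalize.screen_passes_qc(qc, config.qc_policy)
    log.info("QC: min SSMD %.2f, pass=%s, mean NC drift %.3f",
             qc["ssmd"].min(), qc_ok, drift.mean_drift)
    if not qc_ok and not force:
        (outdir / "manifest.json").write_text(
            json.dumps({"complete": False, "failed_stage": "qc"}, indent=2)
        )
        raise QCFailure(
            f"{int((~qc['pass']).sum())} plate/arm(s) below SSMD "
            f"{config.ssmd_threshold}; rerun with force to continue"
        )

    results = hit_calling.score_screen(dataset, config.normalization, config.contrast)
    results = hit_calling.classify(results, config.hits)
    screen_model.write_results(results, outdir / "hits.csv")
    counts = hit_calling.class_counts(results)
    log.info("hit classes: %s", counts)

    summary = {
        "seed": gen.seed,
        "n_mimics": gen.n_mimics,
        "n_plates": gen.n_plates,
        "normalization": config.normalization,
        "contrast": config.contrast,
        "ssmd_threshold": config.ssmd_threshold,
        "qc_pass": bool(qc_ok),
        "min_ssmd": float(qc["ssmd"].min()),
        "mean_nc_drift": drift.mean_drift,
        "sd_nc_drift": drift.sd_drift,
        "hit_counts": counts,
        "hit_config": dataclasses.asdict(config.hits),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (outdir / "manifest.json").write_text(json.dumps({"complete": True}, indent=2))
    return summary
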