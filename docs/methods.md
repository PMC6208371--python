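# Methods

This note documents the statistical models, the synthetic-data
generator, the numerical choices, and the limits of what the test suite
demonstrates.

## Screen data model

A screen is a set of 96-well plates (rows A–H, columns 1–12), each well
holding one library entry (test), a non-targeting negative-control
mimic (NC), a PLK1-silencing positive control (PC), or nothing. Every
plate layout is measured in both a vehicle arm and a drug arm, in
replicate. The canonical interchange format is long CSV (one row per
measurement); a wide 8×12 grid importer exists only as a convenience
and converts to long form immediately. Viability tables must declare
percent vs fraction explicitly — auto-detection is refused because a
silent 100× scale error is the worst failure mode of this kind of
plumbing.

The number of control wells per plate in the original screen design is
not something one can derive from the assay description, so the layout
is configurable; the default is 84 test + 8 NC + 4 PC wells, a common
arrangement that leaves both control groups large enough for stable
per-plate summaries.

## Normalization and QC

Normalization is **per plate and per arm**, anchored to that plate's NC
wells pooled across replicates: z = (x − μ_NC)/σ_NC, viability =
x/μ_NC (sample SDs use n − 1 throughout). Per-plate anchoring is the
standard guard against plate-to-plate baseline drift and makes "NC
wells sit at z = 0 / viability = 1" exactly true on every plate; a
screen-wide mode (`normalization="screen"`) is provided for comparison.
All downstream hit statistics operate on the viability scale — the
selection quantity is a ratio of mean viabilities — while z-scores are
retained for reporting.

SSMD = (μ_NC − μ_PC)/√(σ_NC² + σ_PC²) is computed per plate per arm;
the default pass threshold is 3 and a screen passes only if every
plate/arm does (policy configurable). When both control SDs are zero
with distinct means the statistic is reported as a signed infinity
sentinel rather than an error, since that situation (noiseless
synthetic data) is informative, not broken.

Control drift — 1 − mean_NC(drug)/mean_NC(vehicle) per plate — is the
pipeline's sanity check that the drug arm was actually dosed: a drug at
its IC20 should remove ≈20% of NC viability.

## Hit calling

Per entry, the drug-arm and vehicle-arm replicate viabilities are
compared with the classical pooled-variance two-sample *t* test
(df = n₁ + n₂ − 2, two-sided). Degenerate inputs are given explicit
conventions: zero pooled variance with equal means → t = 0, p = 1;
with unequal means → a signed infinite-t sentinel with p = 0. An
alternative contrast (`contrast="nc"`: drug-arm entry vs drug-arm NC
wells) is available because the assay description admits either
reading; drug-vs-vehicle is the default as it directly measures the
interaction.

Multiplicity is controlled by Benjamini–Hochberg at Q = 0.5%
(q(i) = min_{j≥i} m·p(j)/j, capped at 1), delegated to
`statsmodels.stats.multitest` behind the module surface; an independent
brute-force step-up oracle in the tests verifies equivalence up to
m = 2000.

Classification precedence:

1. **drug_neutral** — |vehicle viability change| > 25% AND Welch
   p < 0.05 vs the plate's NC wells (Welch, because the NC well count
   differs from the replicate count). The ">25%" magnitude is combined
   with a significance requirement because a magnitude-only rule would
   fire constantly at high noise.
2. **sensitizer** — BH q ≤ Q AND ratio ≤ the empirical 2.5th
   percentile of the screen's ratios AND (1 − ratio) ≥ 10%. The FDR
   gate and the magnitude gate are combined with AND ("significant and
   large"); the 10% floor is kept as an explicit extra gate rather than
   assuming the percentile implies it, since that equivalence is a
   property of one particular screen's distribution, not a rule.
3. **desensitizer** — BH q ≤ Q AND ratio ≥ the 97.5th percentile
   (mirrored gate; configurable off, as the magnitude rule was stated
   for sensitizers only).
4. **no_effect** otherwise.

Percentiles use linear interpolation between closest ranks
(`numpy.percentile` default); with fewer than 40 entities the
percentile gate is flagged unreliable but still computed. Sensitizers
are ranked by ascending ratio, ties broken by ascending q.

**Detection power caveat.** With triplicates (df = 4) and 5% CV noise,
the Q = 0.5% gate is deliberately conservative: in the default
synthetic screen only the strongest planted sensitizers are called
(the rest fall to the FDR gate, not the magnitude gate). This mirrors
how primary screens are actually used — a strict primary list feeding
a secondary screen — and is why exactness of the logic is demonstrated
separately on noiseless data, where recovery of the generator's truth
classes is exact for every entity.

## Dose–response

The curve family is the four-parameter logistic
V(D) = bottom + (top − bottom)/(1 + (D/IC50)^h), the field standard
behind IC values. Fitting is bounded trust-region least squares
(`scipy.optimize.curve_fit`) with bottom ≥ 0 and top ≤ 1.2× the
maximum observed response (both relaxable), multi-started over a
7-point log-spaced IC50 grid spanning the nonzero dose range with hill
initialized at 1; the best-SSR converged start wins. Zero doses
contribute to asymptote estimation but not to the grid. Tolerances are
set tight (xtol = ftol = gtol = 1e-15) so noise-free synthetic data
reproduce their generating parameters to ~1e-9, which the tests pin at
1e-6.

IC_f = IC50·(f/(1−f))^(1/h) inverts the curve exactly (f = 0.5 returns
IC50; f = 0.2 is the screening-dose IC20). Curve comparison is the
extra-sum-of-squares F test with all four parameters shared in the
null model by default (Δdf = 4); `share="ic50"` fits a joint
7-parameter model sharing potency only (Δdf = 1). The shared SSR is
clamped to be at least the separate SSR, so floating-point jitter can
never produce a negative F. Noise-free identical inputs give F = 0,
p = 1; noise-free separated inputs give SSR_sep = 0, handled as
F = ∞, p = 0.

## Synergy

The median-effect line log(fa/(1−fa)) = m·log D − m·log Dm is fitted by
OLS; points with fa at 0 or 1 (or dose 0) are excluded with a warning,
and m ≤ 0 is flagged as a nonstandard slope rather than an error. The
combination index is the classic two-term (mutually exclusive) form,
evaluated non-constant-ratio — each combination point against its own
doses — because the emulated design crosses increasing concentrations
of both agents without a fixed ratio; a constant-ratio analysis is
just this computation on a diagonal grid. Verdicts use a ±0.1
additivity band purely for reporting; the CI value itself is the
result. fa for viability data is 1 − normalized viability, and the
normalization anchor must be declared by the caller. Points whose fa
lies outside both agents' observed ranges are scored but flagged as
extrapolated; per-point failures inside a matrix are recorded in an
error column and never abort the remaining points.

## Expression filter

Quantile normalization replaces each column's rank-i value by the
cross-column mean of the i-th order statistics; ties receive the mean
of the order-statistic means their positions span. This is implemented
directly (no installed Python package provides this microarray-style
operation; scikit-learn's QuantileTransformer maps to a reference
distribution, a different thing) and is idempotent to 1e-12.

The per-gene filter is fold change > 2 — evaluated symmetrically as
max(fc, 1/fc) so down-regulated targets clear the same gate — mean
normalized intensity > 10, and two-sample p < 0.05. Welch's test is
the default (array group variances rarely match; pooled available).
Genes with a zero control mean have no defined fold change and are
returned flagged as excluded. Passing sets from several cell lines
combine by **union** by default with intersection behind a flag: the
phrase "union of genes differential in both lines" is internally
contradictory, so both readings are offered and the default follows
the word "union"; the worked analysis reports both sizes side by side.

## Power

Exact two-sample t power through the noncentral t distribution
(noncentrality d·√(n/2), df 2n − 2), delegated to statsmodels'
`TTestIndPower` with a tail-safe fallback for extreme noncentrality
where the far tail underflows to NaN (it is then negligible and
dropped). Alpha is two-sided by default — the design statement gives
no sidedness, and two-sided is the conservative reading — with a
one-sided option. `min_n` scans upward from n = 2, which is exact and
instantaneous at the scale this is used. The motivating design (a
1 log10 bioluminescence difference against SD 0.5, i.e. d = 2, 80%
power, α = 0.05) yields n = 6 per group.

## Synthetic-data generator

The generator defines the study conditions; its defaults are the
emulated screen's: 1902 library entries, 84/8/4 well layout,
triplicate, two arms, multiplicative log-normal noise at 5% CV
(σ_log = √ln(1 + CV²), mean exactly 1), PC wells at 10% viability,
drug arm dosed at 2 nM on a 4PL(bottom 0, top 1, IC50 8 nM, hill 1) —
an IC20, so the drug alone leaves g = 0.8 of signal. Signals follow

    vehicle: S = B·v_m·ε        drug: S = B·v_m·g·s_m·ε

with a per-plate baseline B (log-normal, 10% CV, drawn once per plate
and shared by both arms so per-plate normalization is exercised), v_m
the entry's vehicle effect and s_m its drug-interaction ratio.

Class proportions default to 2% sensitizers (true ratio 0.5–0.9), 1%
desensitizers (1.2–1.5), 2% vehicle-toxic entries (viability 0.4–0.7
or 1.3–1.6, half each, so both directions of the >25% rule occur), 95%
null — a realistic sparse-hit library in which the planted sensitizer
fraction sits inside the 2.5-percentile magnitude gate, keeping
noiseless recovery well-defined. Mimic-to-plate assignment is
deterministic library order, so layouts need no extra seed stream;
everything else derives from one `numpy` generator seeded from the
config.

Combination tables are constructed by solving the Loewe equation
d₁/Dx₁(fa) + d₂/Dx₂(fa) = 1 for fa by Brent's method at each grid
point; "boost" mode multiplies agent 1's effective contribution by k,
which makes the downstream CI equal 1 − (k − 1)·d₁/Dx₁ < 1 — an
algebraic construction oracle, not a fit.

**What the generator does not emulate:** spatial plate artifacts (edge
effects, gradients), carry-over, batch drift across screening days,
heavy-tailed or signal-dependent noise, and transfection-efficiency
variation. Passing tests therefore demonstrate correctness of the
statistics under a well-behaved multiplicative-noise model, not
robustness to the artifacts a real campaign also fights.

## Problem sizes and tolerances

The worked analyses and checks run the full 1902-entry screen (23
plates, ~13k measurements, seconds to simulate and QC; hit scoring of
all entries takes a few seconds). Dose–response recovery checks use
100 seeded datasets of 8 doses × 3 replicates. Monte-Carlo assertions
use tolerances derived from their sampling error (e.g. drift 20% ± 1
percentage point over 23 plates; binomial bounds for type-I error
rates); exact identities (round-trips, closed-form inversions,
additive CI) are pinned at 1e-6 to 1e-12 as noted above.

## Known limitations

- The drug-neutral significance test compares n replicates against NC
  wells within one plate; with very few NC wells its Welch df is small.
- The 4PL fitter assumes a monotone response; biphasic curves are out
  of scope and will fit poorly (flagged only through SSR).
- CI values for fa outside both agents' observed ranges are
  extrapolations of the median-effect line and should be read with the
  `extrapolated` flag in hand.
- BH q-values are computed screen-wide across all test entities; no
  plate-level stratification of the FDR is attempted.
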