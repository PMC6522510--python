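# Methods

## Scope and data model

`screenkit` analyses luminescence viability screens on AML cell-line panels.
The in-memory containers are pandas objects: a long-format plate table (one
row per well: plate, well, cell line, compound, molar concentration,
replicate, luminescence, control role), a compounds × cell-lines percent-
inhibition matrix for the primary screen, and a compounds × cell-lines EC50
matrix (µM) for the secondary screen. Fits are returned as small dataclasses
(`FourPLFit`, `HillBindingFit`) that are also callables evaluating the
fitted curve.

## Normalization and scoring

Luminescence is log10-transformed first and the control-anchored inhibition
formula is applied to the log values; this follows the order in which the
two operations are conventionally stated for this assay. Whether the
original screens scored on the log or raw scale is not recoverable, so
`normalize_plates(..., scale="raw")` provides the raw-scale variant; both
satisfy the anchoring identities (negative-control mean ↦ 0,
positive-control mean ↦ 100) exactly. Percent values are never clipped:
downstream rules see raw percentages, and wells with non-positive
luminescence are rejected at load rather than imputed. Control means are
per-plate, since plates drift between runs.

No Z′-factor formula is attached to this assay in the source material;
the standard definition on log10 values with a 0.5 pass threshold is used,
both configurable.

## Constrained 4PL fitting

The response scale is % activity (100 = negative control). The model is the
log-logistic `f(x) = c + (d−c)/(1+exp(b(ln x − ln e)))` with `b ≤ 0`, so `c`
is the low-dose and `d` the high-dose asymptote and `f(e) = (c+d)/2`.

Box constraints: `−10 ≤ b ≤ 0`; `0 ≤ c, d ≤ A_max`; `10⁻¹⁰ ≤ e ≤ 10⁻⁴` M.
The EC50 bounds correspond to the tested concentration span of the screen
(0.5 nM–10 µM) with a decade of headroom below. `A_max` is the maximum over
concentrations of the per-concentration median response, with one deliberate
refinement: the default cap is `max(100, A_max)`. The activity scale is
anchored at 100% of the negative control, and on a decreasing curve the
lowest tested dose always samples strictly below the true low-dose
asymptote, so a literal data-derived cap would make even noiseless
self-consistency unattainable; the anchored cap preserves the purpose of
the constraint (preventing runaway asymptotes) without that artefact.
`asymptote_cap="data"` restores the strict data cap.

Rows at the single highest tested concentration carry weight 0.1, all others
1.0 (replicates at the top dose are all down-weighted); `top_dose_weights`
can extend this to the top k concentrations. Optimization is multi-start
bounded least squares in `(b, c, d, log10 e)` with an analytic Jacobian:
eight deterministic lattice starts plus the two best nodes of a coarse
profiled grid, pruned to the four most promising by initial cost, a cheap
first pass (tolerances 1e-8), and a tight polish (1e-12) from the best
solution. The polish is skipped when the cheap pass already shows the
sigmoid explains less than half the fallback threshold of the weighted
variance, since such fits are routed to the spline regardless.

A fit is treated as a failure — triggering the fallback — when any of the
following holds:

- the responses are constant (no dose effect to model);
- weighted R² < 0.3: a sigmoid explaining less than about a third of the
  weighted variance is not a usable dose-response curve (this catches both
  inactive compounds and strongly non-monotone, e.g. bell-shaped, data);
- the fitted midpoint is pinned at an EC50 bound while lying outside the
  tested range;
- the fitted slope is pinned at the steep bound (−10): a step steeper than
  the dose spacing is not resolvable as a sigmoid.

The thresholds are arguments of `fit_4pl`, with the values above as
documented defaults.

## Spline fallback and AUC

The fallback fits a cubic smoothing spline to (log10 concentration, mean
response per concentration) with the smoothing parameter chosen by
generalized cross-validation, evaluated only within the tested range. Which
smoothing rule the original analysis used is unknowable; GCV is the stated
substitute. With fewer than five distinct concentrations (or a flat mean
profile) linear interpolation is used instead. AUC — for both sigmoid and
spline modes — is the trapezoid-rule mean of the curve over
`[log10 x_min, log10 x_max]` on a 512-point grid, so a 0–100 activity curve
yields a 0–100 AUC. Fallback fits report no `b, c, d, e` and
`relative_ic50` raises for them; downstream they become "NE" (not
evaluable) entries of the EC50 matrix.

## Grid oracle

`grid_oracle_sse` profiles the weighted SSE over a lattice in `(b, log10 e)`
(steps 0.1 and 0.05) solving `(c, d)` at each node by box-constrained
weighted linear least squares — exact for a two-variable box QP by
enumerating the interior solution and the four clipped edge solutions. It is
a brute-force lower envelope used to verify the nonlinear optimizer is not
trapped in poor local minima: any acceptable converged fit must reach a
weighted SSE no larger than the grid minimum.

## Hit calling and advancement

All thresholds are strict inequalities; boundary values fail. A compound
with missing data in some line can still be a total hit elsewhere but is
ineligible for selectivity calls (the "< low in all others" clause cannot be
verified) and is logged. When replicates exist in a primary screen the
median is taken before thresholding. Annotation flags are tri-state
(true/false/unknown); an unknown flag blocks advancement and is reported as
`<criterion>:unknown` rather than passing silently. Secondary-candidate
selection applies the analog rule to a fixed point, so an analog of an
analog of a selected compound is also selected.

## Potency profiling

EC50s are stored in µM. The broad-potency rule requires a numeric EC50 below
the cut in *every* line — an NE entry disqualifies. Cell-line ordering uses
agglomerative clustering on log10(EC50 µM) profiles with pairwise-complete
Euclidean distance (missing entries ignored pair by pair), average linkage,
and scipy's deterministic leaf order; distance and linkage are configurable
because no particular choice is canonical for this display. The subtype
selectivity ratio — median EC50 of non-target lines over median EC50 of
target lines, with missing entries censored at the 10 µM assay ceiling — is
this package's own quantification of a qualitative pattern; the censoring
value is the top tested concentration and is an argument.

## Expression quantification

Gene expression from exon coverage is the maximum per-sample coverage over
the gene's exons ("best covered exon"), retaining genes with expression
≥ 10 (inclusive) in at least one sample. FPKM divides counts by gene length
in kb and library size in millions. Quantile normalization maps each
sample's rank-r value to the mean across samples of the r-th order
statistics; tied values receive the mean of the target quantiles their ranks
span. For tie-free columns the sorted value vectors are exactly identical
afterwards; with ties the tied block shares one value, which is the intended
behaviour of the averaging rule. Expression–sensitivity correlation uses
Pearson r with a two-sided t-test (n−2 df) and OLS of log10 IC50 on
expression; potency spans orders of magnitude, so the log scale is the
default and `ic50_scale="linear"` restores the linear scale.

## Synthetic screen

The generator emulates the study conditions the analysis assumes: 384-well
plates, ~10% of wells given to controls (split between DMSO-negative and
cycloheximide-positive, in fixed layout positions), compound wells whose
expected luminescence is `neg_mean · V(x)/100` for a truth 4PL viability
`V`, and multiplicative lognormal noise `exp(ε), ε ~ N(0, σ)` — plate
readers show roughly constant CV, and no replicate-variance estimate exists
to calibrate against, so the default σ = 0.05 (5% CV) is a design choice,
not an estimate. The positive-control floor defaults to 2% of the negative
mean rather than zero so the log10 transform is always defined. The default
dose design is the 10-point log-spaced 1 nM–10 µM curve in triplicate.
Ground truth is written to a sidecar table only. The expression simulator
multiplies one gene's mean by the requested fold change in the elevated
group (6 by default in the examples, matching the effect size the pipeline
is expected to detect) and constructs the sensitivity vector with an exact
sample correlation to the elevated gene by orthogonalized projection.

What the simulator does *not* model: spatial plate artifacts (edge effects,
gradients), liquid-handling failures, cell-growth kinetics, or
compound-specific deviations from the 4PL shape. Passing tests therefore
demonstrate the correctness of the analysis arithmetic under the assumed
noise model, not robustness to systematic plate pathologies, which are out
of scope.

## Problem sizes and determinism

The benchmark computations use 100 seeded curves for EC50 recovery and for
grid-oracle dominance, 100 seeded six-line screens (four compounds each) for
the selectivity ranking, 500 replicate simulations for the Monte-Carlo
inhibition check, and 100–200 seeds for the expression statistics — sizes at
which the Monte-Carlo standard errors are comfortably below the tolerances
being checked. All simulators take explicit integer seeds
(`numpy.random.default_rng`); identical seed and configuration give
byte-identical outputs.

## Known limitations

- No 5PL/asymmetric models, absolute-IC50 crossing points, or
  drug-combination scores.
- No B-score/spatial normalization or statistical (SSMD/FDR) hit calling;
  the implemented rules are the deterministic thresholds of the screen
  design.
- The clustering leaf order is deterministic but, like any dendrogram
  ordering, not unique; analyses should not attach meaning to exact leaf
  positions beyond cluster membership.
- The Kd fit assumes the slope-(−1) Hill form exactly; cooperative binding
  is out of scope.
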