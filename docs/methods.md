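# Methods

## Problem setting

A toxic treatment perturbs the proteome through two superimposed programs:
regulation specific to its mechanism, and generic death/survival
regulation that any equally cytotoxic agent induces. The pipeline infers
mechanism candidates by (i) contrasting the treatment's expression profile
against pooled co-treatments so that shared regulation cannot discriminate
the classes, and (ii) corroborating candidates with two readouts that do
not depend on abundance at all: cysteine oxidation state and thermal
stability.

## Quantification model

Input is a MaxQuant-dialect protein table with reporter-ion intensities.
Zero intensities are treated as *not quantified* (missing), never as true
zeros: isobaric reporters of a detected peptide are never exactly zero,
and MaxQuant writes 0 for absence. Proteins enter quantification only with
≥ 2 razor+unique peptides and with decoy ("Reverse") and contaminant rows
removed.

Normalization is a per-protein ratio to the designated reference channel
of each labeling set — a row-wise operation yielding dimensionless
relative abundances, not a column-loading correction (a column-median
loading normalization is available as an optional pre-step, off by
default). Multiplexed sets are combined by dividing each row by the
geometric mean of that row's bridge-channel values (the vehicle-control
aliquots carried in every set; the geometric mean is symmetric in the two
controls and stable on ratios), then inner-joining sets on protein id.
Channel labels are opaque strings; no TMT N/C naming convention is
assumed. Log2 transformation happens immediately before model fitting
(multiplicative error model), never before ratio computation.

## OPLS-DA and VIP

The supervised projection uses the standard orthogonal signal correction
construction: with column-scaled `X` (unit-variance scaling after
mean-centering by default; Pareto and center-only available) and centered
±1 class code `y`,

1. `w = X'y / ||X'y||`;
2. per orthogonal component: `t = Xw`, `p = X't/t't`,
   `w_o ∝ p − (w'p)w`, `t_o = X w_o`, `p_o = X't_o/t_o't_o`, deflate
   `X ← X − t_o p_o'`;
3. a final 1-component PLS fit on the deflated matrix gives the predictive
   `t`, `p`, and y-loading `c`.

Orthogonal scores are exactly uncorrelated with the class code by
construction. One orthogonal component is the default — the minimal model
that separates class-orthogonal structure — and is configurable.

VIP is defined on the single predictive component:
`VIP_j = sqrt(K)·|w_j|` with unit-norm `w` over the `K` retained
(non-constant) variables, which makes `mean(VIP²) = 1` an exact algebraic
identity used as a test invariant. Ranking ties break by protein id so
results are reproducible. The sign of `w_j·c` classifies a protein as up-
or downregulated in the target class.

Cross-validation uses deterministic venetian-blind folds (sample *i* →
fold *i* mod 7) so `Q²` needs no random seed: `Q² = 1 − PRESS/SS` on
held-out class predictions, where each training fold refits scaling and
all components. Model significance is a CV-ANOVA-style F comparison of
`(SS − PRESS)` over the model degrees of freedom (1 + number of orthogonal
components) against `PRESS` over the remaining `n − 1 − df` degrees of
freedom; simulations in the test suite show the resulting p values are
conservative under the null (≤ 5% rejections at α = 0.05). A contrast
whose `Q²` ≤ 0 is flagged non-significant with a warning but still
returns its lists.

With very many background proteins and few regulated ones, `Q²` can sit
near or below zero even while the top of the VIP ranking is almost pure
signal — `Q²` measures whole-profile class prediction, not ranking
quality. The specificity tests therefore score recovery of planted
proteins, not `Q²`.

## Time-course rules

Relative abundances (ratios to the late vehicle bridge) are examined at
each designed timepoint. Two onset rules are implemented exactly as used
in practice: the single-marker rule (earliest timepoint where the marker
protein's mean ratio deviates from 1 by ≥ 20%; the marker defaults to the
highest-VIP upregulated protein and is configurable) and the group rule
(earliest timepoint where a Welch *t* test separates the log2 regulations
of the top-50 up and down sets at *p* < 0.05).

## Redox percentages

Free thiols are labeled by the first three sixplex channels, reversibly
oxidized thiols (after TCEP reduction) by the last three; pairing follows
label order (126↔129, 127↔130, 128↔131) unless an explicit pair column
overrides it. The oxidation percentage `100·ox/(free+ox)` cancels any
per-replicate labeling-efficiency or loading factor — an exact invariance
checked by property test. Protein-level aggregation sums free and
oxidized intensities over the protein's cysteine peptides before taking
the ratio (intensity weighting downweights noisy low-intensity peptides);
mean-of-peptide-percentages is available for peptide-level reporting.
Rows must be quantified in every replicate of every condition (complete
cases) before contrasts. The volcano uses the ratio of condition-mean
percentages and a Student *t* test by default (Welch optional); raw
*p* = 0.05 is the default decision threshold, with Benjamini–Hochberg
adjustment behind a flag. The average oxidation level of a condition is
the mean over proteins of the condition-mean percentage (averaging over
proteins, not peptide measurements, is a deliberate choice; both levels
are exposed).

## Melting curves

Soluble fractions normalized to the lowest temperature are fitted to
`f(T) = pl + (1 − pl)/(1 + exp((T − Tm)/s))`, chosen so that `Tm` is
literally the curve midpoint: `f(Tm) = (1 + pl)/2` holds to machine
precision for every fit. A 1/T parameterization
(`f = (1 − pl)/(1 + exp(b − a/T)) + pl`) is available as an alternative,
with its `Tm` solved numerically from the same midpoint condition.

Fitting is bounded nonlinear least squares (`30 ≤ Tm ≤ 75` °C,
`0.1 ≤ s ≤ 20` °C, `0 ≤ pl < 1`) with deterministic multi-start
initialization: `Tm₀` at the temperature closest to the half-range of the
observed fractions, `s₀ = 2` °C, `pl₀ = min(fraction)` clipped to
[0, 0.4), plus three extra starts at `Tm₀ ± 5` °C with `s₀ = 5` °C.
Refitting identical input is bit-identical. A curve needs ≥ 5 quantified
points; convergence additionally requires `r² ≥ 0.8` and `pl < 0.5`
(a "melted" state retaining half the signal is not a usable transition),
both configurable. On noisy curves the least-squares solution matches or
beats an exhaustive grid search over (Tm, s, pl) in residual sum of
squares — the oracle used in the acceptance suite.

`ΔTm` is the difference of mean per-replicate melting points, positive
when the treatment stabilizes the protein, with a two-tailed unpaired
Student *t* test (Welch optional). With the design's two replicates per
condition that test has 2 degrees of freedom and little power, so a
seeded residual-bootstrap p (`bootstrap_delta_tm_p`, 999 draws resampled
onto a common-Tm null) is available as a secondary readout; the t test
remains the decision column. Volcano thresholds default to
`|ΔTm| ≥ 1.5` °C and *p* < 0.05.

## Candidate ledger

One row per protein of the contrast's top lists, joined on protein
accession (gene-name fallback behind a flag, since displayed gene names
are ambiguous). Relative oxidation is the treatment/control ratio of
condition-mean protein Ox%; ΔTm comes from the thermal arm; an assay that
did not quantify the protein leaves its field absent, rendered "/" in the
text output. Ranking is a stable sort by evidence count, then VIP, then
accession. The row set is exactly the union of the up and down lists.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of parameters and seed; every planted truth
is serialized with matching protein ids and a referential-integrity
validator.

* **Expression** (defaults: 4 replicates, 5 conditions — control + 4
  treatments, effect 0.8 log2, technical CV 10%): reporter intensity is
  `2^(base + batch + effect + ε)`, `ε ~ N(0, log2(1+CV))`, with base
  abundance uniform on 20–30 log2 units. Treatment-specific proteins move
  only in the target condition; shared death/survival proteins move
  identically in every non-control condition — the structure the contrast
  must reject. Each TMT10 set carries a reference and a bridge vehicle
  channel plus a per-set, per-protein batch factor that only the bridges
  remove. Samples are allocated replicate-major so every condition spreads
  across sets, mirroring block randomization; confounding a condition with
  a set would (verifiably) leak the set's shared bridge noise into the
  contrast.
* **Redox** (3 replicates, baseline Ox% drawn around 18 with SD 6 points,
  planted shifts +16 points, intensity CV 10%): each protein carries 1–5
  cysteine peptides; per replicate a log-normal total intensity splits
  into free and oxidized channels with independent multiplicative noise.
  Baseline and shift magnitudes sit in the regime a control-vs-treatment
  comparison must resolve (≈18% → ≈34%).
* **TPP** (2 conditions × 2 replicates, Tm uniform 44–58 °C, plateau
  0–0.25, slope 1–4 °C, additive fraction noise SD 0.03, planted +2 °C
  shifts): fractions are the sigmoid plus Gaussian noise clipped at zero.
* **Time course** (5 timepoints 4–48 h, 2 replicates): planted up/down
  proteins step from ratio 1 to `2^±effect` at the onset; ratios are
  already relative to the late vehicle bridge.

Not emulated: peptide-spectrum matching and identification error, isotope
impurity between reporter channels, missing-not-at-random dropout
(a uniform dropout option exists), co-eluting interference compression of
TMT ratios, and in-vitro oxidation during sample preparation. Passing
tests therefore demonstrate correctness of the statistical machinery
under its own error model, not robustness to every artifact of real
spectra.

## Problem sizes

The acceptance checks run the expression contrast at 2000 proteins ×
20 samples (25 seeds), redox recovery at 500 proteins with a 2000-protein
null calibration, thermal detection at 100 proteins × 4 curves, the onset
rule at 50 seeded runs, and the integrated end-to-end pipeline at
600/200/40 proteins per arm — sizes chosen so every planted-recovery
statistic is stable while the whole battery completes in about a minute.

## Known limitations

* Two-class contrasts only; no multi-class OPLS-DA.
* CV-ANOVA degrees of freedom follow the F-comparison convention described
  above; other software may use slightly different df and give different
  (typically similarly conservative) p values.
* Protein-level tables are the quantification unit; no PSM- or
  peptide-level normalization before aggregation.
* No isothermal dose-response or spline-based thermal analysis; the
  sigmoid with plateau is the only curve family.
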