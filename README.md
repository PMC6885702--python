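# mstriad

Three-armed chemoproteomics inference for drug-mechanism deconvolution.

When a treatment kills cells, most of the proteome response is generic
death/survival signaling shared by *any* cytotoxic agent. `mstriad`
implements the statistical machinery that separates treatment-*specific*
protein regulation from that shared response and corroborates the
candidates with two orthogonal biophysical readouts:

1. **Expression contrast** — TMT reporter abundances for one treatment are
   contrasted against pooled co-treatments (chosen to be equally
   growth-suppressive) and control with an orthogonal projections to latent
   structures discriminant analysis (OPLS-DA). With scaled matrix $X$ and
   centered class code $y$, the orthogonal components absorb
   class-independent variation and the single predictive component carries
   the specific signal; proteins are ranked by the predictive VIP,
   $\mathrm{VIP}_j = \sqrt{K}\,|w_j|$ with unit-norm weights $w$ over $K$
   proteins, so $\overline{\mathrm{VIP}^2} = 1$. Model quality is reported
   as $R^2X$[cum], $R^2Y$, 7-fold cross-validated $Q^2$ and a CV-ANOVA
   *p* value.
2. **Cysteine redox proteomics** — paired iodoTMT sixplex channels (126–128
   label free thiols, 129–131 label reversibly oxidized thiols after TCEP
   reduction) give per-peptide and per-protein oxidation percentages
   $\mathrm{Ox\%} = 100\cdot\mathrm{ox}/(\mathrm{free}+\mathrm{ox})$,
   contrasted between conditions with a volcano (mean-ratio ≥ 2,
   two-tailed unpaired *t* test *p* < 0.05).
3. **Thermal proteome profiling (TPP)** — soluble fraction after heating at
   ten temperatures (37–67 °C) is fitted per protein to
   $f(T) = pl + (1-pl)/(1+e^{(T-T_m)/s})$, so $T_m$ is the curve midpoint;
   shifts $\Delta T_m$ between treatment and control (positive =
   stabilized) enter a volcano at $|\Delta T_m| \ge 1.5$ °C, *p* < 0.05.

The three per-protein evidence streams join into a ranked candidate ledger
(regulation direction + VIP, relative oxidation, ΔTm, evidence count). A
ground-truth-annotated synthetic generator (`mstriad.synthetic`) emulates
all four experimental designs so the entire pipeline is testable without
raw mass-spectrometry data; real MaxQuant `proteinGroups.txt`-style tables
are read directly.

## Worked example

The `analysis/` scripts run the whole study on synthetic data
(seed 1). From the repository root:

```bash
python analysis/01_simulate_datasets.py
python analysis/02_expression_contrast.py
python analysis/03_timecourse.py
python analysis/04_redox_oxidation.py
python analysis/05_thermal_shifts.py
python analysis/06_integrate_candidates.py
```

which prints, step by step:

```
expression: 800 proteins, 26 channels over 3 TMT10 sets
...
model: R2Y=0.976 Q2=0.297 CV-ANOVA p=5.01e-02
recovered 20/20 planted DDW-specific proteins; 4 shared-response proteins slipped into the top lists
...
single-marker rule (>=20% change): 26.0 h
group-p rule (up vs down, p<0.05): 26.0 h
...
  average oxidation in DDW: 18.3%
  average oxidation in NW: 17.4%
condition means within 2 points of truth: 96.4% of proteins
...
240 curves fitted, 100% converged (median r2 = 0.995)
planted +2 degC shifts with |dTm| >= 1.5: 9/9; null-protein dTm RMSE = 0.31 degC
...
100 candidates: 25 with all three evidence types, 26 with two, 49 expression-only
```

Reading the numbers: the OPLS-DA contrast of the DDW treatment against the
four pooled co-treatments recovered all 20 planted DDW-specific proteins
in its top-50 VIP lists while admitting only 4 of the 30 planted shared
death/survival proteins — the specificity the contrast design exists for.
Both onset rules date the planted proteome response to the correct
timepoint; protein oxidation percentages come back within 2 points of
truth for ~96% of proteins; and 9/9 planted +2 °C thermal shifts clear the
volcano threshold with sub-0.5 °C error on unshifted proteins. Tables land
under `results/`.

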