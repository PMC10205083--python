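# Methods

## The positional isotopomer model

The flux engine rests on a steady-state model of hepatic
[3-¹³C]lactate metabolism. Lactate exchanges rapidly with pyruvate, so
the tracer delivers fractional enrichment `x_lac` to pyruvate C3 (C1
and C2 stay unlabeled: pyruvate-kinase and malic-enzyme back-flux,
which would label C2, are small under fasting conditions and are set to
zero). Alanine exchanges with pyruvate and reports its C3 enrichment.

Carbon routing (the atom-transition table in
`fluxscale.isotopomer.ATOM_TRANSITIONS`, editable in one place):

- **PDH** decarboxylates C1 and maps pyruvate C2,C3 → acetyl-CoA C1,C2.
  Acetyl-CoA entering citrate synthase is a mixture: a fraction
  `r_pdh = V_PDH/V_CS` from PDH, the rest from β-oxidation and other
  unlabeled sources, so acetyl C2 carries `r_pdh · x_lac`.
- **PC** maps pyruvate C1–C3 → oxaloacetate C1–C3 and fixes CO₂ into
  C4 (bicarbonate enrichment `x_co2`, 0 by default — hepatic and renal
  bicarbonate labeling is negligible in such studies).
- **CS + IDH + αKGDH**: acetyl C2 → α-ketoglutarate C4, acetyl C1 →
  C5; OAA C4,C3,C2 → αKG C1,C2,C3; OAA C1 is lost at the IDH
  decarboxylation, αKG C1 at the αKGDH step. Glutamate mirrors αKG.
- **Succinate/fumarate** are symmetric: a 50/50 carbon-skeleton
  reversal averages positions 1↔4 and 2↔3 (complete scrambling).
- **PEPCK** maps OAA C1–C3 → PEP, losing C4; trioses inherit PEP
  carbons, and glucose condenses two trioses (triose C1 → glucose
  C3/C4, C2 → C2/C5, C3 → C1/C6).

The OAA/malate pool receives `V_PC` of freshly carboxylated pyruvate
and `V_CS` of scrambled cycle return, so its enrichment vector solves
an affine fixed point in the anaplerotic ratio `r_pc = V_PC/V_CS`. The
solver builds the 4×4 affine map by probing and solves it directly;
fixed-point iteration (to residual < 1e-12) is retained as an
independent cross-check and agrees to ~1e-11.

Two consequences of the network are theorems of the model rather than
inputs, and the test suite asserts them to 1e-12 at every fixed point:
**glutamate C5 carries no label** (acetyl C1 is only fed by unlabeled
pyruvate C2) and **malate C1 = C4** (both positions are fed only by the
scrambled cycle return when `x_co2 = 0`). The fragment equations below
rely on exactly these facts.

Complete (50/50) scrambling was chosen over partial scrambling: the
C1 = C4 identity the fragment algebra uses holds only in the complete
case, and the symmetric intermediates make anything else hard to
motivate physically.

## Observables

`observe` computes what a mass spectrometer reports: alanine C3; malate
total and C1C2C3 fragment sums; glutamate total and C4C5 fragment;
glucose whole-molecule M+1/M+2 and the carbons-4–6 fragment M+1/M+2.
Triose mass-isotopomer distributions treat carbon positions as
independent (exact for the M+1-dominated patterns this tracer
produces); glucose patterns are the convolution of two independent
trioses, diluted by the non-pyruvate-derived glucose fraction
`1 − f_pc`. Plasma tracer enrichments ([²H₇]glucose, [U-¹³C₁₆]
palmitate) follow one-pool steady-state dilution,
`E_plasma = E_inf · F / (F + Ra)`.

Noise is multiplicative log-normal per observable with a given
coefficient of variation, mean-preserving (σ² = ln(1+cv²)), reflecting
the roughly constant relative precision of enrichment measurements.

## Inference equations and their conditioning

All closed forms are derived from the same steady-state model, so on
noiseless model data they are exact up to documented constants:

- `V_PC/V_CS`: the malate C2+C3 balance gives a quadratic in `r_pc`
  (`VPC_VCS_TOLERANCE = 1e-9` relative, pure floating point). At high
  glucose oxidation the quadratic can have two admissible roots; the
  total malate enrichment (whose C1 = C4 component depends on `r_pc`
  differently) disambiguates, and the pipeline always passes it. An
  unresolvable ambiguity raises rather than guessing.
- MIDA `f_pc`: corrected for doubly labeled trioses through
  `t₀ = 1 − t₁ − t₂`; triply labeled trioses (~x_lac³) are neglected,
  bounding the relative error by `MIDA_TOLERANCE = 5e-4` across the
  validation grid.
- `V_PDH/V_CS = glutamate C4 / alanine C3` is exact.

Error handling under noise: malate C4 implied negative is clipped to 0
with a warning; `V_PDH/V_CS` and `f_pc` above 1 are clipped with a
warning (gluconeogenic fractions more than 50 % above 1 raise, as a
genuine inconsistency rather than noise); malate C2+C3 outside the
model-representable range falls back to the nearest admissible ratio
on [0, 50] with a warning. Nothing is clipped silently.

Conditioning differs sharply between estimates, and the Monte-Carlo
targets acknowledge it. The dilution-based rates (EGP, palmitate Ra)
and `V_PC = 2·f_pc·GNG` are nearly linear in the measurements: at 5 %
observation noise their group-mean fold differences recover the truth
to a few percent and are scored on means. The anaplerotic ratio sits in
a flat region of the malate response (∂u/∂r ≈ 0.005 per unit `r` at
`r ≈ 3`), so per-animal `V_PC/V_CS` — and `V_CS`, which divides by
it — has heavy-tailed errors at that noise level; its recovery is
scored on medians and coverage of the 95 % interval, not means. This is
intrinsic to inverting these observables, not an implementation
artifact: the least-squares inversion of the full forward model
(`invert_numerically`, kept as an oracle) reduces but does not remove
it (median |Δr_pc|/r_pc ≈ 8 % at 5 % noise).

Unit bookkeeping: infusions are specified in mg/(kg·min) and converted
through a molar-mass table (glucose 180.16, palmitate 256.42 g/mol);
fluxes are reported in µmol/(kg·min) with the unit string carried in
the results; per-g-liver values are the caller's division by liver
mass (a 1500 g human liver is the conventional assumption when
comparing species). The factor 2 in `V_PC = 2·f_pc·GNG` converts
glucose-unit gluconeogenesis to triose-unit carboxylase flux.
`V_PEPCK ≈ V_PC` because pyruvate-kinase recycling is taken as zero; a
nonzero `v_pk` can be set on `FluxParams` for sensitivity checks.
Steady-state is verified by an OLS slope test on the late-infusion
samples (default template 100/110/120 min, α = 0.05, pass when the
slope is indistinguishable from zero).

In vitro and slice rates: net glucose production is the OLS slope of
media glucose over the incubation (endpoint mode available), per mg
protein; slice production is amount/(weight × duration), emitted per
hour (multiply by the incubation time for per-incubation totals).

## The expression screen

Counts are normalised to CPM; TMM scaling factors use the canonical
trim fractions (30 % on log-ratios, 5 % on absolute expression),
precision weights from the asymptotic variance of the log-ratio,
pairwise exclusion of zero genes, a reference sample whose
upper-quartile expression is closest to the mean upper quartile, and a
final rescaling to geometric mean 1.

Ortholog collapse sums many-to-one collisions by default (preserving
total signal; mean available) and keeps only reference symbols present
in every species — a cross-species comparison is undefined otherwise.

The monotone filter compares per-species replicate means and demands
strict decrease along increasing body mass. A stricter per-replicate
mode (every replicate of each species above every replicate of the
next) exists but is off by default: with two replicates per species it
mostly re-tests measurement noise.

ANOVA runs per gene on log2(CPM+1) — the variance stabilisation any
expression analysis would use; count noise is strongly heteroscedastic
on the raw scale and the F-test loses power there. A raw-scale option
remains. The Bonferroni family is the set of genes that entered the
test (those passing the monotone filter), matching the
filter-then-test sequence, with dfW = Σ(nᵢ−1). Designs with a
single replicate per species (typical of cross-species proteomics)
skip ANOVA and report the filter result alone.

Gene-set enrichment is a one-sided hypergeometric upper-tail test over
user-supplied GMT collections with Bonferroni adjustment across sets —
an offline, exactly-specified statistic (web enrichment services are
not reproducible offline, so none is wrapped). It agrees with direct
combinatorial enumeration exactly.

Clustering (screen heatmap and flux panels) z-scores rows/features and
uses Euclidean distance with average linkage — unweighted defaults that
are deterministic for a fixed input; both are configurable. Species
purity cuts the sample tree at k = 2 and scores the majority-label
fraction.

## Synthetic data: what it emulates, what it does not

`gen_counts` draws gamma-Poisson (negative-binomial) counts with
dispersion 0.1 — a typical bulk-RNA-seq overdispersion — log-normal
baseline means, expected library size 1e6, five species spanning 30 g
to 900 kg, two replicates each. Planted genes decrease log-linearly
with body-mass rank at 4-fold per adjacent species (256-fold across the
panel), emulating the strong monotone profiles the screen is meant to
find; background genes are exchangeable across species. Under these
conditions the monotone filter recovers essentially all plants while
the Bonferroni-corrected ANOVA at adjusted p ≤ 0.01 admits roughly
two-thirds of them with ~no false discoveries: with two replicates per
group the F(4,5) test simply has limited power at family-wise 0.01, and
that trade-off is reported as-is rather than hidden by easier
conditions.

`gen_tracer_study` encodes the two-species in vivo effects as
generating truth (mouse vs rat: EGP and V_PC ≈ 2.2×, V_CS 3×, palmitate
turnover 2.5×, equal `f_pc = 0.9` and `r_pdh = 0.25`), group sizes 4
and 6, measurement CV 5 %, and pyruvate C3 enrichment `x_lac = 0.12`
(a 20 mM lactate pool at ~20 % plasma enrichment, diluted by hepatic
unlabeled influx). These values are used for recovery testing of the
pipeline, never as a claimed reproduction of animal data. The
generators do not simulate natural-abundance isotope envelopes,
kinetic (pre-steady-state) labeling, inter-animal biological variance
beyond the observation noise, or the full structure of public
transcriptome datasets — so passing tests demonstrate correctness of
the estimation machinery under the stated noise model, not performance
on raw instrument data (inputs are assumed background-corrected APE).

OCR traces are piecewise-constant phase levels plus Gaussian noise,
three measurements per phase; phase summaries use the mean (a
last-measurement convention is available). Flux panels are Gaussian
with multiplicative CV around species-level means.

## Determinism and formats

Every generator and every stochastic routine takes a single integer
seed (or a shared `numpy` Generator); identical seeds give identical
bytes in all outputs (UTF-8, headers, 6-significant-digit floats). All
file formats are plain text: TSV for counts and annotations, GMT for
gene sets, CSV for enrichments/OCR/panels, JSON for ledgers and
summaries.
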