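# Methods

## Forward model

An analyte's isotope envelope is modeled as the convolution of per-atom
isotope patterns.  Natural envelopes use a shipped terrestrial-abundance
table (`data/isotope_abundances.yaml`, IUPAC representative values); every
envelope function takes the table as an argument so toy tables can be
substituted in tests.  Envelopes are computed by truncated convolution
(exponentiation by squaring on the leading `M0..M5` channels); because all
per-atom patterns start at mass offset zero, truncation is exact for the
retained channels.

A labeled (fully newly synthesized) population replaces `n` of the
hydrogen positions with label-carrying sites whose deuterium probability is
`p_eff = p + a_H`, where `p` is the excess body-water enrichment and `a_H`
the natural deuterium abundance (a configuration switch selects `p` alone;
with baseline subtraction the two conventions almost cancel).  The site
envelope is `Binomial(n, p_eff)`; the remaining atoms stay at natural
abundance.  Non-integer effective `n` — the rule rather than the exception
with per-residue site tables — is handled by linear interpolation between
the envelopes at `floor(n)` and `ceil(n)`.

Measured channels are `M0..M3` for peptides and `M0..M2` for the palmitate
GC-MS fragments.  Envelopes are renormalized over the measured channels
before excess abundances `EMx = Mx(labeled) − Mx(baseline)` are formed;
the internal depth (`M0..M5`) keeps truncation bias out of the
renormalization.  Whether the historical pipelines renormalized over
`M0..M3` or `M0..M4` is not documented; the renormalization depth is a
setting (`k`), defaulting to the measured channels.

Per-residue effective site counts are the Commerford-derived values used
throughout heavy-water kinetic proteomics, shipped as
`data/residue_sites.tsv` and explicitly replaceable; all downstream math
depends only on the summed `n`.  Peptide elemental compositions come from
the standard residue formulas (via pyteomics) plus one water; fixed
carbamidomethylation of cysteine is an option for iodoacetamide workflows.
Palmitate uses `n = 22` effective sites (the established MIDA value),
configurable on `LipidAnalyteModel`.  The methyl-ester fragment composition
is C17H34O2; the composition registered for the acetyl-derivative window is
a synthetic stand-in (the true protocol-specific fragment formula should be
substituted when known) and the methyl ester is the default derivative.

## Estimation

Mixtures are formed in the renormalized channel space:
`M(f) = (1−f)·M_nat + f·M_lab`, which makes `f` exactly linear in the
measured envelope and gives noise-free closure of estimator∘generator to
machine precision.  Two estimators are provided:

* **`lsq` (default for peptides)** — project the measured excess vector
  onto the direction `M_lab − M_nat` over all measured channels:
  `f = ⟨M_meas − M_base, d⟩ / ⟨d, d⟩`.
* **`em1`** — the classical single-channel ratio `EM1 / EM1_max`.

The single-channel EM1 estimator is ill-conditioned for many-site
analytes: the binomial M1 term `n·p(1−p)^{n−1}` peaks near `n ≈ 1/p`, so at
`p = 0.05` the EM1 asymptote of a typical tryptic peptide (n ≈ 15–40)
passes through zero and 1% channel noise can be amplified by an order of
magnitude or more.  The combined projection uses the monotone M0 depletion
alongside M1–M3 and is well-conditioned for every composition, which is why
it is the default; `em1` remains available and is the estimator for
palmitate DNL, where `n·p ≈ 1.1` is below the turnover and
`EM1_max ≈ 0.27` at `p = 0.05`.  The same phenomenon limits the polynomial
asymptote-vs-p curve fit (`mida_curve`): a quadratic is adequate for
small-`n` analytes but visibly biased across `p ∈ [0.01, 0.06]` for large
peptides, so the fit always reports its maximum deviation from the direct
computation and the direct asymptote is the reference path.

Raw ratios are retained unclamped for QC; the reported `f` is clamped to
[0, 1].  Rate constants use one-compartment rise-to-plateau kinetics
`k = −ln(1−f)/t` with a constant precursor — appropriate for the
bolus-plus-drinking-water design that holds body water near 5% throughout —
with `f` capped at 0.999 (warning) before the logarithm.

Per-animal body-water enrichments are obtained from acetone-exchange GC-MS
signals by least-squares linear calibration against standards measured in
the same batch (exact interpolation for two standards); samples outside the
standards' span are rejected rather than extrapolated.  Each animal's own
`p` feeds its asymptotes, with the cohort nominal (default 0.05) as
fallback.

## Rollup, filtering, contrasts

Peptide fractions are rolled up per protein and animal by the median
(robust to a single aberrant peptide; mean available), and proteins with
fewer than 2 peptide measurements are dropped.  Treated/control tables use
the ratio of group means for the fold-change and a classic equal-variance
two-tailed t-test (Welch optional); groups with zero variance and unequal
means report the numeric floor 1e-300 with a flag, identical groups report
p = 1.  No multiple-testing correction is applied to the significance
flag; a Benjamini–Hochberg q-value column is emitted for reference.  The
alternative of averaging per-protein ratios instead of ratioing group
means is deliberately not the default (ratios of means match how pathway
heat maps are usually drawn); the per-protein means are in the table for
anyone wanting the other convention.

Pathway aggregation weights each protein's group-mean `f` by its pooled
peptide-measurement count over the group's animals (per-animal weighting
is available through the underlying per-animal table), and pathways with
fewer than 5 measured proteins are dropped.  Aggregation runs off a static
accession→pathway TSV; no live ontology service is queried.

## Synthetic cohorts

The generator emulates the reference design: 2×2 cohort (young/aged ×
control/tunicamycin), 5 animals per group, 96 h label, body water
5% ± 0.2% (animal-level), ~150 proteins in 10 synthetic pathways with
peptides per protein from a geometric distribution (mean 4, minimum 1 — so
the ≥2-peptide filter is genuinely exercised), random tryptic-like
sequences of 8–25 residues.  Programmed effects mirror the expected
ER-stress flux signature: the ER-processing pathway ×2.6 under treatment
at both ages, mild global reduction in aged controls (×0.9), broad
suppression (×0.5–0.75) of non-ER pathways in aged treated animals, and a
BiP-like chaperone with ×2.0 (young) and ×3.3 (aged) treatment effects.
DNL truths: triglyceride suppressed by treatment at both ages, phospholipid
suppressed only in aged animals.

Noise has three components, all scenario fields: multiplicative Gaussian
per channel (CV 1%, typical Q-ToF isotopomer precision), an additive floor
(1e-5), and biological animal-level lognormal spread on true `f`
(σ = 0.15, mean-corrected) — the last is what makes group t-tests
meaningful.  Ground truth records both the group-level design values and
the realized per-animal fractions.  A fixed seed makes outputs
byte-identical across runs.

What the generator does *not* emulate: peptide-level systematic biases
(ionization, co-elution, misidentification), retention-time drift,
missing-at-random peptide dropout across animals, multi-pool precursor
kinetics, and inter-protein correlation of biological noise.  Passing
tests therefore demonstrate correctness of the estimation machinery and
statistical pipeline under the stated noise model, not robustness to every
artifact of real LC-MS data.

## Numerical choices and problem sizes

* Envelope truncation depth `M0..M5` internally; asymptotes below 1e-9
  are rejected as numerically meaningless.
* Raw DNL ratios below −0.05 are flagged as QC failures (beyond what
  baseline noise explains).
* Table writes are deterministic: stable sort, 6-significant-digit floats.
* The test suite runs the full reference cohort (150 proteins, 20 animals,
  ~11k peptide measurements) once per noise condition, plus a reduced
  cohort (3 pathways × 6 proteins) for replicate-based checks: the
  power property uses 20 replicates of the reduced young cohort, and DNL
  recovery bias uses 20 lipid-only replicates of the reference scenario.
  These sizes were chosen to keep the suite fast while leaving every rule
  (filters, weights, contrasts) exercised at full scale.

## Known limitations

* Single-pool precursor model; no lag or de-enrichment kinetics.
* No absolute protein synthesis rates; absolute DNL requires a
  user-supplied depot pool mass.
* The EM1 estimator should not be used for peptides above ~15 effective
  sites at 5% enrichment (see Estimation); the default does not have this
  restriction.
* Cholesterol GC-MS channels are parsed but not analyzed.
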