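# midaflux

Metabolic flux signatures from heavy-water (²H₂O) labeling experiments:
proteome-wide protein synthesis rates, de novo lipogenesis, and
pathway-level flux contrasts.

## The problem

Giving an animal deuterated water labels every molecule it synthesizes
during the labeling window: new protein incorporates deuterium at C–H
positions of amino acids drawn from body water, and new palmitate builds
~22 hydrogen positions from the same precursor pool.  Mass isotopomer
distribution analysis (MIDA) turns the measured isotope envelope of an
analyte into the fraction of its pool that is newly made.  For a tryptic
peptide with elemental composition giving the natural envelope
(M0, M1, M2, M3) and `n` effective labeling sites at precursor enrichment
`p`, the envelope of a partially turned-over pool is the mixture

```
M(f) = (1 − f) · M_natural + f · M_labeled(p, n)
```

so the fraction newly synthesized is the position of the measured envelope
between the two endpoints — classically the excess-M1 ratio
`f = EM1 / EM1_max(p, n)`, where `EM1_max` is the theoretical maximum
excess of a fully turned-over pool.  Under rise-to-plateau kinetics the
replacement rate constant follows as `k = −ln(1 − f) / t`.  The same
combinatorial model applied to palmitate M0–M2 envelopes in triglyceride
and phospholipid fractions gives `f_DNL`, the fraction of the depot
palmitate pool made by de novo lipogenesis during labeling.

The package is written for kinetic-proteomics and lipid-flux studies of
the kind that compare treated and control cohorts — its reference scenario
is chronic ER stress (daily tunicamycin) in young versus aged mice, where
the expected signature is induction of ER-processing chaperone synthesis
(BiP and friends), broad suppression of other translation in aged animals,
and suppressed lipogenesis.

## What it provides

* `midaflux.isotopes` — elemental compositions of peptides, natural and
  label-perturbed isotope envelopes (truncated convolution), excess (EMx)
  vectors, MIDA asymptotes, and polynomial asymptote-vs-p curve fits.
* `midaflux.bodywater` — precursor enrichment from acetone-exchange GC-MS
  signals against calibration standards.
* `midaflux.turnover` — `ProteinTurnoverModel(...).fit()` →
  `ProteinTurnoverResults`: per-peptide fraction-new, protein rollup with
  the ≥2-peptide filter, rate constants, treated/control volcano tables,
  and cross-age contrasts.
* `midaflux.lipogenesis` — `LipogenesisModel(...).fit()` →
  `LipogenesisResults`: per-animal `f_DNL` by lipid fraction, optional
  absolute DNL, group contrasts.
* `midaflux.pathways` — peptide-count-weighted KEGG-pathway aggregation
  (≥5 measured proteins per pathway), fold-change tables and heat maps.
* `midaflux.simulate` — seeded synthetic cohorts with known ground truth
  (isotopomer tables, lipid tables, body-water signals, pathway maps).
* A CLI: `midaflux simulate | fsr | dnl | pathways | report`.

## Worked example

```python
from midaflux import (CohortDesign, LipogenesisModel, ProteinTurnoverModel,
                      default_upr_scenario, simulate_experiment)
from midaflux.bodywater import enrichment_table
from midaflux.pathways import load_pathway_map, pathway_aggregate, pathway_fold_change

sim = simulate_experiment(default_upr_scenario(seed=17))
body_water = enrichment_table(sim.body_water, sim.standards)

results = ProteinTurnoverModel(sim.peptides, CohortDesign(), body_water).fit()
print(results.summary())

records = pathway_aggregate(results.proteins, load_pathway_map(sim.pathway_map))
young = records[records["age"] == "young"]
folds = pathway_fold_change(young[young["treatment"] == "tunicamycin"],
                            young[young["treatment"] == "control"])
print(folds[["pathway_name", "fold"]].round(3).to_string(index=False))
```

prints

```
Protein turnover model (heavy-water labeling, MIDA)
=======================================================
peptide measurements:     11260
proteins (>= 2 peptides): 114
label duration:           96.0 h
estimator:                lsq (channel M1), rollup=median
...
                               pathway_name  fold
Protein processing in endoplasmic reticulum 2.452
                                   Ribosome 0.993
                     Fatty acid degradation 0.713
                     PPAR signaling pathway 0.777
...
```

114 proteins survive the ≥2-peptide filter; the ER-processing pathway is
the most induced under treatment (~2.5-fold, the programmed ~2.6× effect
recovered through the full pipeline), lipid-handling pathways are
suppressed, and the rest sit near 1.  The lipogenesis side:

```python
dnl = LipogenesisModel(sim.lipids, body_water).fit()
print(dnl.summary())
```

shows triglyceride `f_DNL` falling from 0.21 to 0.10 under treatment in
young animals (fold 0.50, p = 3e-4) while the young phospholipid fraction
is unchanged (p = 0.23), and both fractions suppressed in aged animals —
the expected age-exaggerated pattern.

The same pipeline runs from the shell:

```sh
midaflux report --simulate default_upr --seed 17 --out results/run
```

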