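"""Proteome-wide fractional synthesis rates from peptide isotopomer envelopes.

Each tryptic peptide's measured M0..M3 envelope is a mixture of pre-existing
molecules (natural envelope) and molecules synthesized during the labeling
window (label-perturbed envelope at that animal's body-water enrichment).
Because the mixture is linear in the renormalized channel space, the fraction
newly synthesized is

    f = EM1_measured / EM1_asymptote(composition, p, n)

with the asymptote from the MIDA forward model (:mod:`midaflux.isotopes`).
Peptide-level fractions are rolled up to proteins (dropping proteins with
fewer than 2 peptide measurements), converted to first-order replacement rate
constants k = -ln(1 - f) / t under rise-to-plateau kinetics, and contrasted
between treated and control groups as volcano tables (fold-change plus
two-tailed t-test).

The public surface follows the statsmodels convention: build a
:class:`ProteinTurnoverModel` from the peptide table and cohort metadata, call
``fit()``, and read estimates and contrasts off the returned
:class:`ProteinTurnoverResults`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .isotopes import (
    DEFAULT_K_INTERNAL,
    ElementalComposition,
    IsotopeTable,
    LabelingParameters,
    composition_from_sequence,
    default_residue_sites,
    labeled_distribution,
    labeling_sites,
    natural_distribution,
)

__all__ = [
    "TurnoverSettings",
    "CohortDesign",
    "ProteinTurnoverModel",
    "ProteinTurnoverResults",
    "peptide_fraction_new",
    "filter_and_rollup",
    "replacement_rate",
    "differential_table",
    "cross_age_contrast",
]

logger = logging.getLogger(__name__)

EM_FLOOR = 1e-9  # asymptotes below this are numerically meaningless


@dataclass(frozen=True)
class CohortDesign:
    """2x2 labeling cohort: age x treatment, n animals/group, label duration."""

    ages: tuple[str, ...] = ("young", "aged")
    treatments: tuple[str, ...] = ("control", "tunicamycin")
    n_per_group: int = 5
    t_hours: float = 96.0
    nominal_p: float = 0.05

    def __post_init__(self) -> None:
        if self.t_hours <= 0:
            raise ValueError("label duration must be positive")
        if self.n_per_group < 1:
            raise ValueError("need at least one animal per group")


@dataclass(frozen=True)
class TurnoverSettings:
    """Tunables of the FSR estimation pipeline (defaults follow the study design)."""

    min_peptides: int = 2          # protein filter: >= 2 peptide measurements
    rollup: str = "median"         # peptide -> protein central estimate
    # "lsq" projects the measured envelope onto the natural->labeled direction
    # over all monitored channels; "em1" uses the M1 excess alone.  The single
    # EM1 channel is ill-conditioned for large peptides (the M1 excess changes
    # sign as label shifts mass into M2/M3), so the combined fit is the default.
    estimator: str = "lsq"
    channel: int = 1
    k: int = 3                     # renormalize over M0..Mk (monitored channels)
    k_internal: int = DEFAULT_K_INTERNAL
    t_test: str = "student"        # "student" (equal variance) or "welch"
    f_max: float = 0.999           # cap before k computation
    carbamidomethyl: bool = False
    site_mode: str = "excess_plus_natural"


# ---------------------------------------------------------------------------
# envelope cache and peptide-level estimator
# ---------------------------------------------------------------------------

_ENVELOPE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}


def _envelope_pair(
    comp: ElementalComposition,
    n: float,
    p: float,
    table: IsotopeTable,
    settings: TurnoverSettings,
) -> tuple[np.ndarray, np.ndarray]:
    """Renormalized (natural, fully-labeled) envelopes for one analyte at one p."""
    key = (comp.formula(), round(n, 9), round(p, 12), settings.k, settings.k_internal,
           settings.site_mode, id(table))
    hit = _ENVELOPE_CACHE.get(key)
    if hit is not None:
        return hit
    nat = natural_distribution(comp, table, settings.k_internal).renormalize(settings.k).as_array()
    lab = labeled_distribution(
        comp, LabelingParameters(p=p, n=n), table, settings.k_internal,
        site_mode=settings.site_mode,
    ).renormalize(settings.k).as_array()
    if len(_ENVELOPE_CACHE) > 200_000:  # unbounded growth guard
        _ENVELOPE_CACHE.clear()
    _ENVELOPE_CACHE[key] = (nat, lab)
    return nat, lab


def peptide_fraction_new(
    measured,
    *,
    peptide: str | None = None,
    comp: ElementalComposition | None = None,
    n: float | None = None,
    p: float,
    table: IsotopeTable | None = None,
    site_table=None,
    baseline=None,
    settings: TurnoverSettings | None = None,
) -> tuple[float, float]:
    """Fraction newly synthesized for one peptide measurement.

    Parameters
    ----------
    measured : sequence of float
        Measured fractional abundances M0..Mk (renormalized internally).
    peptide, comp, n
        Provide either the sequence (composition and sites are derived) or an
        explicit composition plus site count.
    p : float
        The animal's excess body-water enrichment; must be positive.
    baseline : sequence of float, optional
        Measured unlabeled baseline envelope; computed from the composition
        when absent.

    Returns
    -------
    (f, raw) : tuple of float
        ``f`` clamped to [0, 1]; ``raw`` is the unclamped ratio kept for QC.
    """
    settings = settings or TurnoverSettings()
    table = table or IsotopeTable.default()
    if p <= 0:
        raise ValueError("precursor enrichment p must be positive to estimate f")
    if comp is None or n is None:
        if peptide is None:
            raise ValueError("provide either peptide sequence or (comp, n)")
        comp = composition_from_sequence(peptide, carbamidomethyl=settings.carbamidomethyl)
        n = labeling_sites(peptide, site_table or default_residue_sites())
    nat, lab = _envelope_pair(comp, n, p, table, settings)
    meas = np.asarray(list(measured), dtype=float)[: settings.k + 1]
    if meas.size != settings.k + 1:
        raise ValueError(f"measured envelope needs {settings.k + 1} channels, got {meas.size}")
    meas = meas / meas.sum()
    if baseline is not None:
        base = np.asarray(list(baseline), dtype=float)[: settings.k + 1]
        base = base / base.sum()
    else:
        base = nat
    if settings.estimator == "em1":
        ch = settings.channel
        denom = lab[ch] - nat[ch]
        if abs(denom) < EM_FLOOR:
            raise ValueError("EM asymptote below numeric floor; cannot estimate f")
        raw = (meas[ch] - base[ch]) / denom
    elif settings.estimator == "lsq":
        direction = lab - nat
        norm = float(direction @ direction)
        if norm < EM_FLOOR**2:
            raise ValueError("EM asymptote below numeric floor; cannot estimate f")
        raw = float((meas - base) @ direction) / norm
    else:
        raise ValueError(f"unknown estimator {settings.estimator!r}")
    return float(min(max(raw, 0.0), 1.0)), float(raw)


# ---------------------------------------------------------------------------
# rollup, kinetics, contrasts
# ---------------------------------------------------------------------------


def replacement_rate(f: float, t_hours: float, *, f_max: float = 0.999) -> float:
    """First-order replacement rate constant k = -ln(1-f)/t (per hour)."""
    if t_hours <= 0:
        raise ValueError("t must be positive")
    if f < 0:
        raise ValueError("f must be non-negative")
    if f >= 1.0:
        warnings.warn(f"f={f} >= 1 capped at {f_max} before rate computation")
        f = f_max
    return -math.log1p(-f) / t_hours


def filter_and_rollup(
    peptide_f: pd.DataFrame,
    *,
    t_hours: float,
    min_peptides: int = 2,
    rollup: str = "median",
    f_max: float = 0.999,
    group_cols: tuple[str, ...] = ("age", "treatment"),
) -> pd.DataFrame:
    """Protein-level f and k per animal from peptide-level fractions.

    Proteins with fewer than ``min_peptides`` peptide measurements for an
    animal are dropped, mirroring the >= 2 peptide filter applied to FSR data.
    The central estimate is the median by default (mean via ``rollup``);
    dispersion is reported as the standard deviation of peptide f.
    """
    if min_peptides < 1:
        raise ValueError("min_peptides must be >= 1")
    if rollup not in ("median", "mean"):
        raise ValueError(f"unknown rollup {rollup!r}")
    if peptide_f.empty:
        cols = ["accession", "animal", *group_cols, "f", "k", "n_peptides", "f_sd"]
        return pd.DataFrame(columns=cols)
    agg = rollup
    keys = ["accession", "animal", *[c for c in group_cols if c in peptide_f.columns]]
    grouped = peptide_f.groupby(keys, sort=True)["f"].agg(
        f=agg, n_peptides="size", f_sd="std"
    ).reset_index()
    grouped = grouped[grouped["n_peptides"] >= min_peptides].reset_index(drop=True)
    grouped["f"] = grouped["f"].clip(0.0, f_max)
    grouped["k"] = [-math.log1p(-f) / t_hours for f in grouped["f"]]
    return grouped


def _two_group_p(treated: np.ndarray, control: np.ndarray, variant: str) -> tuple[float, str]:
    """Two-tailed two-sample t-test p-value with degenerate-variance handling."""
    if len(treated) < 2 or len(control) < 2:
        return float("nan"), "too_few_animals"
    vt, vc = np.var(treated, ddof=1), np.var(control, ddof=1)
    if vt == 0.0 and vc == 0.0:
        if np.isclose(treated.mean(), control.mean()):
            return 1.0, "zero_variance_equal_means"
        return 1e-300, "zero_variance"
    res = stats.ttest_ind(treated, control, equal_var=(variant == "student"))
    return float(res.pvalue), ""


def differential_table(
    proteins: pd.DataFrame,
    *,
    treated: str = "tunicamycin",
    control: str = "control",
    treatment_col: str = "treatment",
    value_col: str = "f",
    t_test: str = "student",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-protein treated/control volcano table.

    Fold-change is the ratio of group means; the p-value is a two-tailed
    two-sample t-test (classic equal-variance by default, Welch via
    ``t_test='welch'``).  No multiple-testing correction is applied to the
    significance flag; a Benjamini-Hochberg q-value column is emitted for
    reference.
    """
    records = []
    for accession, sub in proteins.groupby("accession", sort=True):
        ft = sub.loc[sub[treatment_col] == treated, value_col].to_numpy(dtype=float)
        fc = sub.loc[sub[treatment_col] == control, value_col].to_numpy(dtype=float)
        rec = {
            "accession": accession,
            "n_treated": len(ft),
            "n_control": len(fc),
            "mean_f_treated": ft.mean() if len(ft) else float("nan"),
            "mean_f_control": fc.mean() if len(fc) else float("nan"),
        }
        if len(ft) == 0 or len(fc) == 0:
            rec.update(fold=float("nan"), log2_fold=float("nan"), p=float("nan"),
                       flag="missing_group")
        else:
            fold = rec["mean_f_treated"] / rec["mean_f_control"] if rec["mean_f_control"] > 0 else float("nan")
            p, flag = _two_group_p(ft, fc, t_test)
            rec.update(
                fold=fold,
                log2_fold=math.log2(fold) if fold and fold > 0 else float("nan"),
                p=p,
                flag=flag,
            )
        records.append(rec)
    out = pd.DataFrame(records)
    if out.empty:
        return out
    out["significant"] = out["p"] < alpha
    valid = out["p"].notna()
    out["q_bh"] = float("nan")
    if valid.any():
        out.loc[valid, "q_bh"] = stats.false_discovery_control(out.loc[valid, "p"])
    return out.sort_values("accession").reset_index(drop=True)


def cross_age_contrast(
    young: pd.DataFrame, aged: pd.DataFrame
) -> pd.DataFrame:
    """Pair young and aged treated/control log2 fold-changes per protein.

    Inner-joins the two differential tables on accession (young columns on the
    left) and adds the aged-vs-young ratio of treated-condition synthesis.
    """
    merged = young.merge(aged, on="accession", suffixes=("_young", "_aged"), how="inner")
    if merged.empty:
        warnings.warn("no proteins shared between young and aged tables")
        return merged
    merged["ratio_aged_young_treated"] = (
        merged["mean_f_treated_aged"] / merged["mean_f_treated_young"]
    )
    merged["log2_ratio_aged_young_treated"] = np.log2(merged["ratio_aged_young_treated"])
    return merged.sort_values("accession").reset_index(drop=True)


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


class ProteinTurnoverModel:
    """Proteome-wide turnover model for a heavy-water labeling cohort.

    Parameters
    ----------
    peptides : DataFrame
        Peptide isotopomer table with columns ``accession, peptide, animal,
        age, treatment, M0..M3`` (optional ``baseline_M0..M3``).
    design : CohortDesign
        Label duration and cohort structure; ``nominal_p`` is the fallback
        enrichment for animals without a body-water measurement.
    body_water : DataFrame, mapping, or float, optional
        Per-animal excess enrichment (columns ``animal, p``); a scalar applies
        to every animal.
    """

    def __init__(
        self,
        peptides: pd.DataFrame,
        design: CohortDesign,
        body_water=None,
        *,
        isotope_table: IsotopeTable | None = None,
        site_table=None,
        settings: TurnoverSettings | None = None,
    ) -> None:
        self.settings = settings or TurnoverSettings()
        self.design = design
        self.table = isotope_table or IsotopeTable.default()
        self.site_table = site_table or default_residue_sites()
        required = {"accession", "peptide", "animal"} | {f"M{i}" for i in range(self.settings.k + 1)}
        missing = required - set(peptides.columns)
        if missing:
            raise ValueError(f"peptide table missing columns: {sorted(missing)}")
        self.peptides = peptides.reset_index(drop=True)
        self._p_by_animal = self._resolve_body_water(body_water)

    @classmethod
    def from_tables(cls, peptides, design, body_water_samples=None, standards=None, **kw):
        """Build from raw tables, converting body-water signals via calibration."""
        from .bodywater import enrichment_table

        bw = None
        if body_water_samples is not None:
            if standards is None:
                raise ValueError("body-water samples require calibration standards")
            bw = enrichment_table(body_water_samples, standards)
        return cls(peptides, design, bw, **kw)

    def _resolve_body_water(self, body_water) -> dict[str, float]:
        animals = self.peptides["animal"].unique()
        if body_water is None:
            return {a: self.design.nominal_p for a in animals}
        if isinstance(body_water, (int, float)):
            return {a: float(body_water) for a in animals}
        if isinstance(body_water, pd.DataFrame):
            mapping = dict(zip(body_water["animal"], body_water["p"]))
        else:
            mapping = dict(body_water)
        out = {}
        for a in animals:
            if a in mapping:
                out[a] = float(mapping[a])
            else:
                logger.warning("no body-water measurement for animal %s; using nominal p=%s",
                               a, self.design.nominal_p)
                out[a] = self.design.nominal_p
        return out

    def fit(self) -> "ProteinTurnoverResults":
        s = self.settings
        mcols = [f"M{i}" for i in range(s.k + 1)]
        bcols = [f"baseline_M{i}" for i in range(s.k + 1)]
        has_baseline = all(c in self.peptides.columns for c in bcols)

        # per-sequence composition and site count, computed once
        seq_info: dict[str, tuple[ElementalComposition, float]] = {}
        for seq in self.peptides["peptide"].unique():
            comp = composition_from_sequence(seq, carbamidomethyl=s.carbamidomethyl)
            seq_info[seq] = (comp, labeling_sites(seq, self.site_table))

        f_vals = np.empty(len(self.peptides))
        raw_vals = np.empty(len(self.peptides))
        meas = self.peptides[mcols].to_numpy(dtype=float)
        base = self.peptides[bcols].to_numpy(dtype=float) if has_baseline else None
        animals = self.peptides["animal"].to_numpy()
        seqs = self.peptides["peptide"].to_numpy()
        for i in range(len(self.peptides)):
            comp, n = seq_info[seqs[i]]
            f_vals[i], raw_vals[i] = peptide_fraction_new(
                meas[i],
                comp=comp,
                n=n,
                p=self._p_by_animal[animals[i]],
                table=self.table,
                baseline=base[i] if base is not None else None,
                settings=s,
            )
        group_cols = tuple(c for c in ("age", "treatment") if c in self.peptides.columns)
        pep = self.peptides[["accession", "peptide", "animal", *group_cols]].copy()
        pep["f"] = f_vals
        pep["f_raw"] = raw_vals
        proteins = filter_and_rollup(
            pep,
            t_hours=self.design.t_hours,
            min_peptides=s.min_peptides,
            rollup=s.rollup,
            f_max=s.f_max,
            group_cols=group_cols,
        )
        return ProteinTurnoverResults(self, pep, proteins)


class ProteinTurnoverResults:
    """Fitted per-protein synthesis fractions, rates, and group contrasts."""

    def __init__(self, model: ProteinTurnoverModel, peptides: pd.DataFrame,
                 proteins: pd.DataFrame) -> None:
        self.model = model
        self.peptide_f = peptides
        self.proteins = proteins

    @property
    def n_proteins(self) -> int:
        """Number of distinct proteins surviving the peptide filter."""
        return self.proteins["accession"].nunique()

    @property
    def p_by_animal(self) -> dict[str, float]:
        return dict(self.model._p_by_animal)

    def differential(self, age: str | None = None, **kw) -> pd.DataFrame:
        """Treated/control volcano table, optionally restricted to one age."""
        sub = self.proteins
        if age is not None:
            sub = sub[sub["age"] == age]
        kw.setdefault("t_test", self.model.settings.t_test)
        return differential_table(sub, **kw)

    def cross_age_contrast(self, young: str = "young", aged: str = "aged", **kw) -> pd.DataFrame:
        return cross_age_contrast(self.differential(young, **kw), self.differential(aged, **kw))

    def summary(self) -> str:
        s = self.model.settings
        lines = [
            "Protein turnover model (heavy-water labeling, MIDA)",
            "=" * 55,
            f"peptide measurements:     {len(self.peptide_f)}",
            f"proteins (>= {s.min_peptides} peptides): {self.n_proteins}",
            f"label duration:           {self.model.design.t_hours} h",
            f"estimator:                {s.estimator} (channel M{s.channel}), rollup={s.rollup}",
        ]
        if {"age", "treatment"} <= set(self.proteins.columns):
            g = self.proteins.groupby(["age", "treatment"])["f"].agg(["mean", "median", "count"])
            lines.append("")
            lines.append("group-level f (protein medians per animal):")
            lines.append(g.to_string(float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
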