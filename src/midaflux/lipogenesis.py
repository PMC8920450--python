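"""De novo lipogenesis (DNL) from palmitate GC-MS isotopomer envelopes.

Newly synthesized palmitate assembles ~22 effective hydrogen positions from
body water during the labeling period, so its M1 excess over an unlabeled
baseline rises toward a theoretical maximum set by the combinatorial
polymerization model at the animal's precursor enrichment ``p``.  The
fractional contribution of DNL to the depot pool is

    f_DNL = EM1_measured / EM1_max(p, n)

computed per animal and lipid fraction (triglyceride, phospholipid) from the
monitored M0-M2 channels, with concurrent unlabeled standards as baseline.
Absolute DNL is f_DNL times the depot pool mass when a pool size is supplied.

As with protein turnover, a :class:`LipogenesisModel` wraps the per-sample
computation; ``fit()`` returns :class:`LipogenesisResults` with the per-animal
table, group contrasts, and a text summary.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bodywater import enrichment_table
from .isotopes import (
    DEFAULT_K_INTERNAL,
    ElementalComposition,
    IsotopeTable,
    LabelingParameters,
    em_asymptote,
)

__all__ = [
    "LipidAnalyteModel",
    "DNLResult",
    "LipogenesisModel",
    "LipogenesisResults",
    "dnl_fraction",
    "absolute_dnl",
    "dnl_group_contrast",
    "PALMITATE_METHYL_ESTER",
    "PALMITATE_ACETYL",
]

EM_FLOOR = 1e-9
NEGATIVE_RATIO_TOLERANCE = -0.05  # raw ratios below this flag a QC failure

LIPID_K = 2  # GC-MS monitors three channels: M0, M1, M2


@dataclass(frozen=True)
class LipidAnalyteModel:
    """Monitored lipid fragment: composition plus effective labeling sites.

    The default palmitate site count (n = 22) is the established value from
    the MIDA fatty-acid literature and is configuration, not a fit.
    """

    composition: ElementalComposition
    n: float = 22.0
    name: str = "palmitate"

    def __post_init__(self) -> None:
        if self.n > self.composition.hydrogen:
            raise ValueError(
                f"n={self.n} exceeds hydrogen count of {self.composition.formula()}"
            )


#: Palmitate methyl ester, the m/z 270-272 GC-MS species (standard composition).
PALMITATE_METHYL_ESTER = LipidAnalyteModel(
    composition=ElementalComposition({"C": 17, "H": 34, "O": 2}),
    n=22.0,
    name="palmitate_methyl_ester",
)

#: Synthetic stand-in composition for the m/z 385-387 acetyl-derivative window;
#: the true fragment formula is instrument-protocol specific and not part of the
#: shipped reference data.  Replace with the protocol's fragment when known.
PALMITATE_ACETYL = LipidAnalyteModel(
    composition=ElementalComposition({"C": 18, "H": 34, "O": 2}),
    n=22.0,
    name="palmitate_acetyl_synthetic",
)

DERIVATIVES = {
    "methyl_ester": PALMITATE_METHYL_ESTER,
    "acetyl": PALMITATE_ACETYL,
}


@dataclass(frozen=True)
class DNLResult:
    """Fractional (and optionally absolute) DNL for one animal and fraction."""

    animal: str
    fraction: str
    f_dnl: float
    raw_ratio: float
    qc_flag: str = ""
    absolute_dnl: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.f_dnl <= 1.0):
            raise ValueError(f"f_DNL must lie in [0, 1], got {self.f_dnl}")


def dnl_fraction(
    measured,
    baseline,
    model: LipidAnalyteModel,
    p: float,
    table: IsotopeTable | None = None,
    *,
    animal: str = "",
    fraction: str = "",
    k: int = LIPID_K,
    k_internal: int = DEFAULT_K_INTERNAL,
) -> DNLResult:
    """Fraction of the palmitate pool derived from DNL during labeling.

    ``measured`` and ``baseline`` are M0..M2 abundances (renormalized
    internally); ``baseline`` is the concurrent unlabeled standard.
    """
    table = table or IsotopeTable.default()
    if p <= 0:
        raise ValueError("precursor enrichment p must be positive")
    meas = np.asarray(list(measured), dtype=float)[: k + 1]
    base = np.asarray(list(baseline), dtype=float)[: k + 1]
    if meas.size != k + 1 or base.size != k + 1:
        raise ValueError(f"need {k + 1} channels (M0..M{k})")
    meas = meas / meas.sum()
    base = base / base.sum()
    em1_max = em_asymptote(
        model.composition, LabelingParameters(p=p, n=model.n), table,
        channel=1, k=k, k_internal=k_internal,
    )
    if em1_max < EM_FLOOR:
        raise ValueError("EM1 asymptote below numeric floor; cannot estimate f_DNL")
    raw = float((meas[1] - base[1]) / em1_max)
    flag = ""
    if raw < NEGATIVE_RATIO_TOLERANCE:
        flag = "negative_excess"
        warnings.warn(
            f"raw DNL ratio {raw:.3f} below tolerance {NEGATIVE_RATIO_TOLERANCE}; QC failure"
        )
    return DNLResult(
        animal=animal,
        fraction=fraction,
        f_dnl=float(min(max(raw, 0.0), 1.0)),
        raw_ratio=raw,
        qc_flag=flag,
    )


def absolute_dnl(result: DNLResult, pool_mass_g: float) -> DNLResult:
    """Grams of palmitate synthesized de novo: f_DNL times depot pool mass."""
    if pool_mass_g < 0:
        raise ValueError("pool mass must be non-negative")
    return DNLResult(
        animal=result.animal,
        fraction=result.fraction,
        f_dnl=result.f_dnl,
        raw_ratio=result.raw_ratio,
        qc_flag=result.qc_flag,
        absolute_dnl=result.f_dnl * pool_mass_g,
    )


def dnl_group_contrast(
    fdnl: pd.DataFrame,
    *,
    treated: str = "tunicamycin",
    control: str = "control",
    t_test: str = "student",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group means and treated/control contrasts per (age, lipid fraction).

    Returns ``(means, contrasts)``: per-group mean and SD of f_DNL, and per
    (age, fraction) fold-change with a two-tailed t-test p-value.
    """
    means = (
        fdnl.groupby(["age", "treatment", "fraction"])["f_dnl"]
        .agg(mean="mean", sd="std", n="size")
        .reset_index()
        .sort_values(["age", "treatment", "fraction"])
        .reset_index(drop=True)
    )
    records = []
    for (age, fraction), sub in fdnl.groupby(["age", "fraction"]):
        ft = sub.loc[sub["treatment"] == treated, "f_dnl"].to_numpy(dtype=float)
        fc = sub.loc[sub["treatment"] == control, "f_dnl"].to_numpy(dtype=float)
        if len(ft) == 0 or len(fc) == 0:
            warnings.warn(f"empty group for age={age}, fraction={fraction}; contrast omitted")
            continue
        fold = ft.mean() / fc.mean() if fc.mean() > 0 else float("nan")
        if len(ft) >= 2 and len(fc) >= 2:
            vt, vc = np.var(ft, ddof=1), np.var(fc, ddof=1)
            if vt == 0.0 and vc == 0.0:
                p = 1.0 if np.isclose(ft.mean(), fc.mean()) else 1e-300
            else:
                p = float(stats.ttest_ind(ft, fc, equal_var=(t_test == "student")).pvalue)
        else:
            p = float("nan")
        records.append(
            {
                "age": age,
                "fraction": fraction,
                "mean_treated": ft.mean(),
                "mean_control": fc.mean(),
                "fold": fold,
                "log2_fold": math.log2(fold) if fold and fold > 0 else float("nan"),
                "p": p,
                "significant": p < 0.05 if not math.isnan(p) else False,
            }
        )
    contrasts = pd.DataFrame(records)
    return means, contrasts


class LipogenesisModel:
    """DNL model for a cohort's lipid GC-MS table.

    Parameters
    ----------
    lipids : DataFrame
        Columns ``animal, age, treatment, fraction, derivative, M0..M2,
        baseline_M0..M2``.
    body_water : DataFrame, mapping, or float
        Per-animal excess enrichment (columns ``animal, p``) or a scalar.
    pool_mass_g : mapping, optional
        Depot palmitate pool mass per (animal, fraction); enables absolute DNL.
    """

    def __init__(
        self,
        lipids: pd.DataFrame,
        body_water,
        *,
        analytes: dict[str, LipidAnalyteModel] | None = None,
        isotope_table: IsotopeTable | None = None,
        pool_mass_g: dict | None = None,
        t_test: str = "student",
    ) -> None:
        required = {"animal", "fraction", "M0", "M1", "M2",
                    "baseline_M0", "baseline_M1", "baseline_M2"}
        missing = required - set(lipids.columns)
        if missing:
            raise ValueError(f"lipid table missing columns: {sorted(missing)}")
        self.lipids = lipids.reset_index(drop=True)
        self.analytes = analytes or dict(DERIVATIVES)
        self.table = isotope_table or IsotopeTable.default()
        self.pool_mass_g = pool_mass_g or {}
        self.t_test = t_test
        self._p_by_animal = self._resolve_body_water(body_water)

    @classmethod
    def from_tables(cls, lipids, body_water_samples, standards, **kw):
        """Build from raw tables, calibrating body-water signals first."""
        bw = enrichment_table(body_water_samples, standards)
        return cls(lipids, bw, **kw)

    def _resolve_body_water(self, body_water) -> dict[str, float]:
        animals = self.lipids["animal"].unique()
        if isinstance(body_water, (int, float)):
            return {a: float(body_water) for a in animals}
        if isinstance(body_water, pd.DataFrame):
            mapping = dict(zip(body_water["animal"], body_water["p"]))
        else:
            mapping = dict(body_water)
        missing = [a for a in animals if a not in mapping]
        if missing:
            raise ValueError(f"no body-water enrichment for animals: {missing}")
        return {a: float(mapping[a]) for a in animals}

    def fit(self) -> "LipogenesisResults":
        rows = []
        for _, row in self.lipids.iterrows():
            derivative = row.get("derivative", "methyl_ester")
            if derivative not in self.analytes:
                raise ValueError(f"unknown derivative {derivative!r}")
            res = dnl_fraction(
                [row["M0"], row["M1"], row["M2"]],
                [row["baseline_M0"], row["baseline_M1"], row["baseline_M2"]],
                self.analytes[derivative],
                self._p_by_animal[row["animal"]],
                self.table,
                animal=str(row["animal"]),
                fraction=str(row["fraction"]),
            )
            pool = self.pool_mass_g.get((res.animal, res.fraction))
            if pool is not None:
                res = absolute_dnl(res, pool)
            rec = {
                "animal": res.animal,
                "fraction": res.fraction,
                "f_dnl": res.f_dnl,
                "raw_ratio": res.raw_ratio,
                "qc_flag": res.qc_flag,
                "absolute_dnl_g": res.absolute_dnl,
            }
            for c in ("age", "treatment"):
                if c in row.index:
                    rec[c] = row[c]
            rows.append(rec)
        fdnl = pd.DataFrame(rows).sort_values(["animal", "fraction"]).reset_index(drop=True)
        return LipogenesisResults(self, fdnl)


class LipogenesisResults:
    """Per-animal f_DNL values and group contrasts."""

    def __init__(self, model: LipogenesisModel, fdnl: pd.DataFrame) -> None:
        self.model = model
        self.fdnl = fdnl

    def contrasts(self, **kw) -> tuple[pd.DataFrame, pd.DataFrame]:
        kw.setdefault("t_test", self.model.t_test)
        return dnl_group_contrast(self.fdnl, **kw)

    def summary(self) -> str:
        lines = [
            "De novo lipogenesis (MIDA combinatorial model)",
            "=" * 50,
            f"measurements: {len(self.fdnl)}",
        ]
        if {"age", "treatment"} <= set(self.fdnl.columns):
            means, contrasts = self.contrasts()
            lines.append("")
            lines.append("group means (f_DNL):")
            lines.append(means.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
            if not contrasts.empty:
                lines.append("")
                lines.append("treated/control contrasts:")
                lines.append(contrasts.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        return "\n".join(lines)
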