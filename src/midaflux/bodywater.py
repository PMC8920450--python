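"""Body-water deuterium enrichment from acetone-exchange GC-MS signals.

Deuterium in body water exchanges into acetone, whose isotopic shift is read
by GC-MS against calibration standards of known enrichment run in the same
batch.  The calibration is a least-squares line through the standards (which
reduces to exact interpolation for two points); sample signals outside the
span of the standards are rejected rather than extrapolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CalibrationCurve", "PrecursorEnrichment", "body_water_enrichment", "enrichment_table"]


@dataclass(frozen=True)
class PrecursorEnrichment:
    """Excess deuterium mole fraction of one animal's body water."""

    animal: str
    p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 0.10):
            raise ValueError(
                f"body-water enrichment {self.p!r} outside the design range [0, 0.10]"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear signal-vs-enrichment calibration from acetone standards."""

    enrichments: tuple[float, ...]
    signals: tuple[float, ...]

    def __post_init__(self) -> None:
        enr = tuple(float(e) for e in self.enrichments)
        sig = tuple(float(s) for s in self.signals)
        if len(enr) != len(sig):
            raise ValueError("enrichments and signals must have equal length")
        if len(set(sig)) < 2:
            raise ValueError("calibration needs at least 2 distinct standard signals")
        object.__setattr__(self, "enrichments", enr)
        object.__setattr__(self, "signals", sig)

    @property
    def slope_intercept(self) -> tuple[float, float]:
        slope, intercept = np.polyfit(self.enrichments, self.signals, 1)
        return float(slope), float(intercept)

    def signal_for(self, enrichment: float) -> float:
        """Forward model: expected signal at a given enrichment."""
        slope, intercept = self.slope_intercept
        return slope * enrichment + intercept

    def enrichment_for(self, signal: float, *, allow_extrapolation: bool = False) -> float:
        lo, hi = min(self.signals), max(self.signals)
        if not allow_extrapolation and not (lo - 1e-12 <= signal <= hi + 1e-12):
            raise ValueError(
                f"sample signal {signal!r} outside calibration span [{lo}, {hi}]; "
                "refusing to extrapolate"
            )
        slope, intercept = self.slope_intercept
        return (signal - intercept) / slope


def body_water_enrichment(
    animal: str,
    signal: float,
    standards: CalibrationCurve,
    *,
    allow_extrapolation: bool = False,
) -> PrecursorEnrichment:
    """Convert one animal's acetone-exchange signal to excess enrichment p."""
    p = standards.enrichment_for(signal, allow_extrapolation=allow_extrapolation)
    return PrecursorEnrichment(animal=animal, p=p)


def enrichment_table(
    samples: pd.DataFrame,
    standards: pd.DataFrame | CalibrationCurve,
    *,
    signal_col: str = "signal",
    animal_col: str = "animal",
) -> pd.DataFrame:
    """Per-animal enrichments for a table of samples.

    ``standards`` is either a :class:`CalibrationCurve` or a DataFrame with
    ``enrichment`` and ``signal`` columns.
    """
    if isinstance(standards, pd.DataFrame):
        standards = CalibrationCurve(
            tuple(standards["enrichment"]), tuple(standards["signal"])
        )
    rows = [
        {"animal": row[animal_col], "p": standards.enrichment_for(row[signal_col])}
        for _, row in samples.iterrows()
    ]
    return pd.DataFrame(rows).sort_values("animal").reset_index(drop=True)
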