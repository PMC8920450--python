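"""Run configuration: every tunable of the pipeline in one place.

Defaults follow the study design where one is stated: 2-peptide protein
filter, 5-protein pathway floor, 96 h label, nominal 5% body-water
enrichment.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .turnover import CohortDesign, TurnoverSettings

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All tunables surfaced by the analysis modules."""

    t_hours: float = 96.0
    nominal_p: float = 0.05
    min_peptides: int = 2
    min_proteins: int = 5
    rollup: str = "median"
    estimator: str = "lsq"
    t_test: str = "student"
    f_max: float = 0.999
    carbamidomethyl: bool = False
    seed: int = 17

    def turnover_settings(self) -> TurnoverSettings:
        return TurnoverSettings(
            min_peptides=self.min_peptides,
            rollup=self.rollup,
            estimator=self.estimator,
            t_test=self.t_test,
            f_max=self.f_max,
            carbamidomethyl=self.carbamidomethyl,
        )

    def design(self, **kw) -> CohortDesign:
        return CohortDesign(t_hours=self.t_hours, nominal_p=self.nominal_p, **kw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def merged(self, **overrides) -> "RunConfig":
        """Copy with non-None overrides applied (CLI flags win over file values)."""
        data = asdict(self)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return RunConfig(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)
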