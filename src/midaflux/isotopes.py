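"""Forward model of mass-isotopomer envelopes under heavy-water labeling.

Mass isotopomer distribution analysis (MIDA) treats a biosynthetic product as a
combinatorial polymer assembled from precursor subunits.  During a ``2H2O``
labeling period, hydrogen atoms at exchangeable C-H positions of newly made
molecules carry deuterium with probability set by the body-water enrichment
``p``; the number of such positions, ``n``, is a property of the analyte.  The
isotope envelope of a molecule population is then the convolution of

* the natural-abundance envelope of all atoms outside the labeling sites, and
* a binomial site envelope ``Binomial(n, p_eff)`` over the labeling sites,

where ``p_eff`` is the deuterium probability per site.  This module implements
that forward model: elemental compositions of tryptic peptides, natural
envelopes, label-perturbed envelopes, excess-isotopomer (``EMx``) vectors, the
theoretical-maximum (fully turned over) excess used as the MIDA asymptote, and
a polynomial curve fit of the asymptote against ``p``.

Envelopes are computed to a configurable internal depth (default ``M0..M5``)
and renormalized over the experimentally monitored channels (``M0..M3`` for
peptides, ``M0..M2`` for GC-MS lipid fragments) before excess abundances are
formed, mirroring how extracted isotopomer abundances are handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml
from pyteomics import mass as _pmass

__all__ = [
    "ElementalComposition",
    "IsotopeTable",
    "MassIsotopomerDistribution",
    "LabelingParameters",
    "ExcessDistribution",
    "MidaCurve",
    "composition_from_sequence",
    "labeling_sites",
    "load_residue_sites",
    "default_residue_sites",
    "natural_distribution",
    "labeled_distribution",
    "excess_distribution",
    "em_asymptote",
    "mida_curve",
    "CANONICAL_RESIDUES",
]

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: carbamidomethyl adduct added to each cysteine when iodoacetamide alkylation
#: is part of the sample preparation.
CARBAMIDOMETHYL = {"C": 2, "H": 3, "N": 1, "O": 1}

# internal envelope depth: compute beyond the monitored channels to limit
# truncation bias before renormalizing.
DEFAULT_K_INTERNAL = 5


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of an analyte (C, H, N, O, S, ...)."""

    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        clean = {}
        for el, c in dict(self.counts).items():
            if c != int(c) or c < 0:
                raise ValueError(f"count for element {el!r} must be a non-negative integer, got {c}")
            if c > 0:
                clean[str(el)] = int(c)
        if not clean:
            raise ValueError("composition must contain at least one atom")
        object.__setattr__(self, "counts", clean)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def hydrogen(self) -> int:
        return self["H"]

    @property
    def total_atoms(self) -> int:
        return sum(self.counts.values())

    def remove(self, element: str, count: int) -> "ElementalComposition":
        if count > self[element]:
            raise ValueError(f"cannot remove {count} {element} from {self.counts}")
        new = dict(self.counts)
        new[element] = new[element] - count
        if new[element] == 0:
            del new[element]
        return ElementalComposition(new)

    def formula(self) -> str:
        order = ["C", "H", "N", "O", "S"]
        keys = [k for k in order if k in self.counts] + sorted(set(self.counts) - set(order))
        return "".join(f"{k}{self.counts[k]}" for k in keys)


@dataclass(frozen=True)
class LabelingParameters:
    """Precursor enrichment and labeling-site count for one analyte.

    Parameters
    ----------
    p : float
        Excess deuterium mole fraction of body water (unitless; in vivo
        designs target ~0.05).
    n : float
        Effective number of C-H positions incorporating label.  Non-integer
        values arise from per-residue effective-site tables and are handled
        by interpolation.
    """

    p: float
    n: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p < 1.0):
            raise ValueError(f"enrichment p must be in [0, 1), got {self.p}")
        if self.n < 0:
            raise ValueError(f"site count n must be non-negative, got {self.n}")


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element isotope patterns: mass offset -> relative abundance."""

    isotopes: Mapping[str, Mapping[int, float]]

    def __post_init__(self) -> None:
        clean: dict[str, dict[int, float]] = {}
        for el, pattern in dict(self.isotopes).items():
            pat = {int(off): float(ab) for off, ab in dict(pattern).items()}
            if len(pat) != len(dict(pattern)):
                raise ValueError(f"duplicate mass offsets for element {el!r}")
            if any(off < 0 for off in pat):
                raise ValueError(f"negative mass offset for element {el!r}")
            if any(not (0.0 <= ab <= 1.0) for ab in pat.values()):
                raise ValueError(f"abundances for {el!r} must lie in [0, 1]")
            total = sum(pat.values())
            if abs(total - 1.0) > 1e-12:
                raise ValueError(f"abundances for {el!r} sum to {total!r}, expected 1")
            clean[str(el)] = pat
        object.__setattr__(self, "isotopes", clean)

    def pattern(self, element: str) -> np.ndarray:
        """Dense abundance vector for one element, indexed by mass offset."""
        if element not in self.isotopes:
            raise KeyError(f"element {element!r} absent from isotope table")
        pat = self.isotopes[element]
        out = np.zeros(max(pat) + 1)
        for off, ab in pat.items():
            out[off] = ab
        return out

    def natural_h2(self) -> float:
        """Natural deuterium abundance (mass offset 1 of H)."""
        return float(self.isotopes.get("H", {}).get(1, 0.0))

    def with_hydrogen(self, d_fraction: float) -> "IsotopeTable":
        """Copy of the table with the H pattern replaced by (1-d, d)."""
        new = {el: dict(p) for el, p in self.isotopes.items()}
        new["H"] = {0: 1.0 - d_fraction, 1: d_fraction}
        return IsotopeTable(new)

    @classmethod
    def from_yaml(cls, path) -> "IsotopeTable":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(raw)

    @classmethod
    def default(cls) -> "IsotopeTable":
        ref = resources.files("midaflux").joinpath("data/isotope_abundances.yaml")
        raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
        return cls(raw)


@dataclass(frozen=True)
class MassIsotopomerDistribution:
    """Fractional abundances (M0, M1, ..., Mk) of an isotope envelope.

    ``renormalized`` distinguishes raw truncations of the full envelope
    (sum <= 1) from distributions renormalized over the retained channels
    (sum == 1).
    """

    abundances: tuple[float, ...]
    renormalized: bool = False

    def __post_init__(self) -> None:
        ab = tuple(float(a) for a in self.abundances)
        if len(ab) < 1:
            raise ValueError("distribution needs at least one channel")
        if any(a < -1e-12 or a > 1.0 + 1e-9 for a in ab):
            raise ValueError(f"abundances must lie in [0, 1]: {ab}")
        total = sum(ab)
        if self.renormalized:
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"renormalized distribution sums to {total!r}")
        elif total > 1.0 + 1e-9:
            raise ValueError(f"raw truncated distribution sums to {total!r} > 1")
        object.__setattr__(self, "abundances", ab)

    def __getitem__(self, channel: int) -> float:
        return self.abundances[channel]

    def __len__(self) -> int:
        return len(self.abundances)

    @property
    def k(self) -> int:
        return len(self.abundances) - 1

    def as_array(self) -> np.ndarray:
        return np.asarray(self.abundances)

    def renormalize(self, k: int | None = None) -> "MassIsotopomerDistribution":
        """Truncate to channels M0..Mk and rescale to unit sum."""
        arr = self.as_array()
        if k is not None:
            if k + 1 > len(arr):
                raise ValueError(f"cannot renormalize over M0..M{k}: only {len(arr)} channels")
            arr = arr[: k + 1]
        total = arr.sum()
        if total <= 0:
            raise ValueError("cannot renormalize a zero distribution")
        return MassIsotopomerDistribution(tuple(arr / total), renormalized=True)


@dataclass(frozen=True)
class ExcessDistribution:
    """Signed differences EMx = labeled Mx - baseline Mx."""

    values: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))

    def __getitem__(self, channel: int) -> float:
        return self.values[channel]

    def __len__(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values)


# ---------------------------------------------------------------------------
# composition and labeling sites
# ---------------------------------------------------------------------------


def composition_from_sequence(peptide: str, *, carbamidomethyl: bool = False) -> ElementalComposition:
    """Elemental composition of a peptide: residue formulas plus one water.

    Parameters
    ----------
    peptide : str
        One-letter amino-acid sequence (20 canonical residues).
    carbamidomethyl : bool
        Apply fixed carbamidomethylation (+C2H3NO) to every cysteine, as
        produced by iodoacetamide alkylation during sample preparation.
    """
    if not peptide:
        raise ValueError("peptide sequence must be non-empty")
    for i, ch in enumerate(peptide):
        if ch not in CANONICAL_RESIDUES:
            raise ValueError(f"unknown residue {ch!r} at position {i + 1}")
    comp = dict(_pmass.Composition(sequence=peptide))
    if carbamidomethyl:
        n_cys = peptide.count("C")
        if n_cys:
            for el, c in CARBAMIDOMETHYL.items():
                comp[el] = comp.get(el, 0) + c * n_cys
    return ElementalComposition(comp)


def load_residue_sites(path) -> dict[str, float]:
    """Read a per-residue effective deuterium-site table (TSV: residue, n_sites)."""
    table: dict[str, float] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if "residue" not in header:
            raise ValueError("site table must have a header with a 'residue' column")
        for line in fh:
            line = line.strip()
            if not line:
                continue
            residue, value = line.split("\t")
            table[residue] = float(value)
    return table


def default_residue_sites() -> dict[str, float]:
    """The shipped per-residue effective-site table used in heavy-water
    kinetic proteomics (replaceable; see ``data/residue_sites.tsv``)."""
    ref = resources.files("midaflux").joinpath("data/residue_sites.tsv")
    table: dict[str, float] = {}
    lines = ref.read_text(encoding="utf-8").strip().splitlines()
    for line in lines[1:]:
        residue, value = line.split("\t")
        table[residue] = float(value)
    return table


def labeling_sites(peptide: str, site_table: Mapping[str, float]) -> float:
    """Effective number of deuterium-incorporating C-H positions of a peptide.

    The per-residue values are summed over the sequence; missing residues are
    an error rather than silently contributing zero.
    """
    if not peptide:
        raise ValueError("peptide sequence must be non-empty")
    n = 0.0
    for i, ch in enumerate(peptide):
        if ch not in site_table:
            raise ValueError(f"residue {ch!r} at position {i + 1} missing from site table")
        n += float(site_table[ch])
    return n


# ---------------------------------------------------------------------------
# envelope computation
# ---------------------------------------------------------------------------


def _convolve_trunc(a: np.ndarray, b: np.ndarray, kmax: int) -> np.ndarray:
    return np.convolve(a, b)[: kmax + 1]


def _pattern_power(pattern: np.ndarray, count: int, kmax: int) -> np.ndarray:
    """pattern ** count under truncated convolution (exponentiation by squaring)."""
    result = np.zeros(kmax + 1)
    result[0] = 1.0
    base = pattern[: kmax + 1].copy()
    while count:
        if count & 1:
            result = _convolve_trunc(result, base, kmax)
        count >>= 1
        if count:
            base = _convolve_trunc(base, base, kmax)
    return result


def _natural_vector(comp: ElementalComposition, table: IsotopeTable, kmax: int) -> np.ndarray:
    out = np.zeros(kmax + 1)
    out[0] = 1.0
    for el in sorted(comp.counts):
        try:
            pattern = table.pattern(el)
        except KeyError as exc:
            raise ValueError(str(exc)) from exc
        out = _convolve_trunc(out, _pattern_power(pattern, comp.counts[el], kmax), kmax)
    return out


def natural_distribution(
    comp: ElementalComposition, table: IsotopeTable, k: int = 3
) -> MassIsotopomerDistribution:
    """Natural-abundance envelope of a composition, truncated at Mk (raw).

    The envelope is the convolution of every atom's isotope pattern; truncation
    keeps the leading channels exactly (patterns start at offset 0, so no mass
    below Mk is lost).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    return MassIsotopomerDistribution(tuple(_natural_vector(comp, table, k)), renormalized=False)


def _labeled_vector_int(
    comp: ElementalComposition,
    n_sites: int,
    p_eff: float,
    table: IsotopeTable,
    kmax: int,
) -> np.ndarray:
    from scipy import stats

    rest_counts = dict(comp.counts)
    if n_sites:
        rest_counts["H"] = rest_counts.get("H", 0) - n_sites
        if rest_counts["H"] == 0:
            del rest_counts["H"]
    site_vec = stats.binom.pmf(np.arange(kmax + 1), n_sites, p_eff)
    if not rest_counts:  # composition is all labeling sites
        return site_vec
    rest_vec = _natural_vector(ElementalComposition(rest_counts), table, kmax)
    return _convolve_trunc(rest_vec, site_vec, kmax)


def labeled_distribution(
    comp: ElementalComposition,
    lab: LabelingParameters,
    table: IsotopeTable,
    k: int = 3,
    *,
    site_mode: str = "excess_plus_natural",
) -> MassIsotopomerDistribution:
    """Envelope of a fully labeled (newly synthesized) population.

    ``lab.n`` of the hydrogen positions carry deuterium with probability
    ``p_eff`` (binomial over sites); all other atoms stay at natural
    abundance.  ``site_mode`` selects whether ``p_eff`` is ``p`` plus the
    natural deuterium abundance (default, so the unlabeled limit matches the
    natural envelope) or the excess ``p`` alone.  Fractional effective ``n``
    is handled by linear interpolation between the floor and ceil site
    counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if lab.n > comp.hydrogen + 1e-9:
        raise ValueError(
            f"labeling sites n={lab.n} exceed hydrogen count {comp.hydrogen} of {comp.formula()}"
        )
    if site_mode == "excess_plus_natural":
        p_eff = lab.p + table.natural_h2()
    elif site_mode == "excess_only":
        p_eff = lab.p
    else:
        raise ValueError(f"unknown site_mode {site_mode!r}")
    p_eff = min(p_eff, 1.0 - 1e-15)

    lo = int(math.floor(lab.n))
    hi = int(math.ceil(lab.n))
    vec_lo = _labeled_vector_int(comp, lo, p_eff, table, k)
    if hi == lo:
        vec = vec_lo
    else:
        vec_hi = _labeled_vector_int(comp, hi, p_eff, table, k)
        w = lab.n - lo
        vec = (1.0 - w) * vec_lo + w * vec_hi
    return MassIsotopomerDistribution(tuple(vec), renormalized=False)


def excess_distribution(
    labeled: MassIsotopomerDistribution, baseline: MassIsotopomerDistribution
) -> ExcessDistribution:
    """EMx vector: labeled minus baseline, channel by channel.

    Both inputs must be renormalized over the same channels; the components
    then sum to zero by construction.
    """
    if len(labeled) != len(baseline):
        raise ValueError(f"channel mismatch: {len(labeled)} vs {len(baseline)}")
    if not (labeled.renormalized and baseline.renormalized):
        raise ValueError("excess distribution requires renormalized inputs")
    return ExcessDistribution(tuple(labeled.as_array() - baseline.as_array()))


def em_asymptote(
    comp: ElementalComposition,
    lab: LabelingParameters,
    table: IsotopeTable,
    channel: int = 1,
    *,
    k: int = 3,
    k_internal: int = DEFAULT_K_INTERNAL,
    site_mode: str = "excess_plus_natural",
) -> float:
    """Theoretical-maximum excess abundance EMx of a fully turned-over pool.

    This is the MIDA asymptote: the excess at ``channel`` when every molecule
    in the pool was synthesized at precursor enrichment ``p``.  Envelopes are
    computed to ``M0..M{k_internal}`` and renormalized over ``M0..Mk`` (the
    monitored channels) before subtraction.
    """
    if not (1 <= channel <= k):
        raise ValueError(f"channel must be in 1..{k}, got {channel}")
    nat = natural_distribution(comp, table, k_internal).renormalize(k)
    labd = labeled_distribution(comp, lab, table, k_internal, site_mode=site_mode).renormalize(k)
    return labd[channel] - nat[channel]


@dataclass(frozen=True)
class MidaCurve:
    """Polynomial approximation of the EM asymptote as a function of p."""

    coefficients: tuple[float, ...]  # ascending powers of p
    channel: int
    max_abs_deviation: float

    def __call__(self, p) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(p, self.coefficients)


def mida_curve(
    comp: ElementalComposition,
    n: float,
    table: IsotopeTable,
    channel: int,
    p_grid: Sequence[float],
    *,
    degree: int = 2,
    k: int = 3,
    k_internal: int = DEFAULT_K_INTERNAL,
    site_mode: str = "excess_plus_natural",
) -> MidaCurve:
    """Least-squares polynomial fit of EM asymptote vs precursor enrichment.

    A convenience approximation for pipelines that precompute curve-fit
    parameters per analyte; the reference path calls :func:`em_asymptote`
    directly.  The maximum absolute deviation from the direct computation on
    the grid is reported alongside the coefficients.
    """
    p_grid = np.asarray(list(p_grid), dtype=float)
    if p_grid.size < degree + 1:
        raise ValueError(f"p_grid needs at least {degree + 1} points for degree {degree}")
    if p_grid.min() < 0.0 or p_grid.max() > 0.10:
        raise ValueError("p_grid must lie within [0, 0.10]")
    direct = np.array(
        [
            em_asymptote(
                comp, LabelingParameters(p=p, n=n), table, channel,
                k=k, k_internal=k_internal, site_mode=site_mode,
            )
            for p in p_grid
        ]
    )
    if np.allclose(direct, 0.0, atol=1e-15) and np.allclose(p_grid, p_grid[0]):
        coeffs = np.zeros(degree + 1)
    else:
        # ascending coefficients via the numpy polynomial fit on the raw scale
        series = np.polynomial.Polynomial.fit(p_grid, direct, deg=degree)
        coeffs = series.convert().coef
        if coeffs.size < degree + 1:
            coeffs = np.pad(coeffs, (0, degree + 1 - coeffs.size))
    dev = float(np.max(np.abs(np.polynomial.polynomial.polyval(p_grid, coeffs) - direct)))
    return MidaCurve(tuple(coeffs), channel=channel, max_abs_deviation=dev)
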