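"""Independent oracles for envelope computations.

These deliberately avoid the package's convolution path: envelopes are built
by exhaustive enumeration over isotope assignments (per-atom Cartesian
product for tiny molecules, per-element count vectors with exact multinomial
coefficients for anything enumerable), and the labeled site distribution by
the closed-form binomial.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def _count_vectors(total: int, bins: int):
    """All ways to distribute `total` identical atoms into `bins` isotopes."""
    if bins == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _count_vectors(total - first, bins - 1):
            yield (first, *rest)


def envelope_multinomial(counts: dict[str, int], isotopes: dict[str, dict[int, float]],
                         kmax: int) -> np.ndarray:
    """Exhaustive envelope via per-element isotope count vectors.

    For each element, every distinct assignment of its atoms to isotopes is
    enumerated with its exact multinomial weight; elements are then combined
    over the Cartesian product of assignments.
    """
    per_element = []
    for el, count in counts.items():
        pats = sorted(isotopes[el].items())
        states = []
        for vec in _count_vectors(count, len(pats)):
            coef = math.factorial(count)
            prob = 1.0
            mass = 0
            for c, (off, ab) in zip(vec, pats):
                coef //= math.factorial(c)
                prob *= ab**c
                mass += c * off
            states.append((mass, coef * prob))
        per_element.append(states)
    out = np.zeros(kmax + 1)
    for combo in itertools.product(*per_element):
        mass = sum(m for m, _ in combo)
        if mass <= kmax:
            prob = 1.0
            for _, p in combo:
                prob *= p
            out[mass] += prob
    return out


def envelope_per_atom(counts: dict[str, int], isotopes: dict[str, dict[int, float]],
                      kmax: int) -> np.ndarray:
    """Brute-force envelope over every per-atom isotope choice (tiny molecules)."""
    atoms = [el for el, c in counts.items() for _ in range(c)]
    out = np.zeros(kmax + 1)
    for choice in itertools.product(*[sorted(isotopes[el].items()) for el in atoms]):
        mass = sum(off for off, _ in choice)
        if mass <= kmax:
            prob = 1.0
            for _, ab in choice:
                prob *= ab
            out[mass] += prob
    return out


def labeled_envelope_binomial(counts: dict[str, int], n_sites: int, p_eff: float,
                              isotopes: dict[str, dict[int, float]], kmax: int) -> np.ndarray:
    """Fully-labeled envelope: closed-form binomial sites x multinomial rest."""
    rest = dict(counts)
    rest["H"] = rest.get("H", 0) - n_sites
    if rest["H"] < 0:
        raise ValueError("n exceeds hydrogen count")
    if rest["H"] == 0:
        del rest["H"]
    rest_env = envelope_multinomial(rest, isotopes, kmax) if rest else None
    site = np.array([math.comb(n_sites, j) * p_eff**j * (1 - p_eff) ** (n_sites - j)
                     for j in range(kmax + 1)])
    if rest_env is None:
        return site
    out = np.zeros(kmax + 1)
    for a in range(kmax + 1):
        for b in range(kmax + 1 - a):
            out[a + b] += rest_env[a] * site[b]
    return out


def random_composition(rng: np.random.Generator, isotopes: dict,
                       max_atoms: int = 20) -> dict[str, int]:
    """Random small composition over the table's elements (>= 1 atom)."""
    elements = sorted(isotopes)
    while True:
        counts = {}
        budget = int(rng.integers(1, max_atoms + 1))
        for el in elements:
            c = int(rng.integers(0, budget + 1))
            if c:
                counts[el] = c
            budget -= c
            if budget <= 0:
                break
        if counts:
            return counts
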