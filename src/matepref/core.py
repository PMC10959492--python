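"""Genotype space and the non-mating parts of the life cycle.

Five biallelic haploid loci: two displayed traits (T1, T2), two preference
loci (P1, P2) coding the preferred value of each trait, and the weighting
locus M.  Distributions over the 32 genotypes are plain numpy arrays of
shape (32,) in the canonical order defined in :mod:`matepref._tables`
(binary encoding, T1 most significant bit).

Operations here: viability selection (fitness ``(1 + t1*s1)(1 + t2*s2)``
renormalised by the mean), Mendelian segregation with free recombination,
and symmetric per-locus mutation.
"""

from __future__ import annotations

from typing import Iterable, Mapping, NamedTuple

import numpy as np

from ._tables import (BITS, FLIP32, LOCI, N_GENOTYPES, RELABEL32, SHIFTS)
from .params import ModelParams

SIMPLEX_TOL = 1e-12


class Genotype(NamedTuple):
    """One haploid five-locus genotype; each field is the allele (0 or 1)."""

    t1: int
    t2: int
    p1: int
    p2: int
    m: int

    @property
    def index(self) -> int:
        """Position in the canonical genotype order (T1 most significant bit)."""
        return (self.t1 << 4) | (self.t2 << 3) | (self.p1 << 2) | (self.p2 << 1) | self.m

    @classmethod
    def from_index(cls, index: int) -> "Genotype":
        if not 0 <= index < N_GENOTYPES:
            raise ValueError(f"genotype index must be in [0, 32); got {index}")
        return cls(*(int(b) for b in BITS[index]))


def enumerate_genotypes() -> list[Genotype]:
    """All 32 genotypes in canonical order.

    The order is the binary encoding over (T1, T2, P1, P2, M) with T1 as
    the most significant bit, so index 0 is (0,0,0,0,0) and index 31 is
    (1,1,1,1,1).  It is fixed and stable across runs.
    """
    return [Genotype.from_index(i) for i in range(N_GENOTYPES)]


def validate_distribution(dist: np.ndarray, tol: float = SIMPLEX_TOL) -> np.ndarray:
    """Check that ``dist`` is a frequency vector on the 32-genotype simplex.

    Raises ``ValueError`` on negative entries or a total differing from 1
    by more than ``tol``; returns the array (as float64) otherwise.
    """
    f = np.asarray(dist, dtype=float)
    if f.shape != (N_GENOTYPES,):
        raise ValueError(f"expected a frequency vector of shape (32,); got {f.shape}")
    if np.any(f < -tol):
        raise ValueError("genotype frequencies must be non-negative")
    total = f.sum()
    if abs(total - 1.0) > max(tol, 1e-9):
        raise ValueError(f"genotype frequencies must sum to 1; got {total!r}")
    return f


def distribution_from_allele_freqs(freqs: Mapping[str, float]) -> np.ndarray:
    """Linkage-equilibrium distribution with the given allele-1 frequencies.

    ``freqs`` maps locus names (subset of T1, T2, P1, P2, M) to allele-1
    frequencies; unlisted loci are fixed for allele 0.
    """
    p = np.zeros(len(LOCI))
    for name, value in freqs.items():
        key = name.upper()
        if key not in SHIFTS:
            raise KeyError(f"unknown locus {name!r}; expected one of {LOCI}")
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"allele frequency at {key} must be in [0, 1]; got {value}")
        p[LOCI.index(key)] = value
    f = np.prod(np.where(BITS == 1, p[None, :], 1.0 - p[None, :]), axis=1)
    return f


def fitness_vector(params: ModelParams) -> np.ndarray:
    """Viability ``w_i = (1 + (T1)_i s1)(1 + (T2)_i s2)`` for all genotypes."""
    return (1.0 + BITS[:, 0] * params.s1) * (1.0 + BITS[:, 1] * params.s2)


def viability_selection(dist: np.ndarray, params: ModelParams) -> np.ndarray:
    """Apply one round of viability selection and renormalise by mean fitness."""
    f = validate_distribution(dist)
    w = fitness_vector(params)
    wf = w * f
    return wf / wf.sum()


def segregation_probability(offspring: Genotype, mother: Genotype,
                            father: Genotype) -> float:
    """Probability beta(i, j, k) that a (mother, father) pair produces ``offspring``.

    Free recombination: each locus is inherited independently, from either
    parent with probability one half.
    """
    prob = 1.0
    for o, mo, fa in zip(offspring, mother, father):
        if mo == fa:
            if o != mo:
                return 0.0
        else:
            prob *= 0.5
    return prob


def apply_mutation(dist: np.ndarray, params: ModelParams) -> np.ndarray:
    """Symmetric allele flips at T1, T2, P1, P2 (never at M).

    For each locus with rate ``u`` a fraction ``u`` of each allele class
    switches to the other allele: ``f <- (1-u) f + u f[flip]``.
    """
    f = validate_distribution(dist)
    for locus, u in (("T1", params.u_t1), ("T2", params.u_t2),
                     ("P1", params.u_p1), ("P2", params.u_p2)):
        if u > 0.0:
            f = (1.0 - u) * f + u * f[FLIP32[locus]]
    return f


def allele_frequency(dist: np.ndarray, locus: str) -> float:
    """Marginal frequency of allele 1 at ``locus`` (one of T1, T2, P1, P2, M)."""
    key = locus.upper()
    if key not in SHIFTS:
        raise KeyError(f"unknown locus {locus!r}; expected one of {LOCI}")
    f = np.asarray(dist, dtype=float)
    return float(f @ BITS[:, LOCI.index(key)])


def allele_frequencies(dist: np.ndarray) -> dict[str, float]:
    """Allele-1 frequencies at all five loci."""
    return {name: allele_frequency(dist, name) for name in LOCI}


def relabel_distribution(dist: np.ndarray) -> np.ndarray:
    """Distribution under the T1<->T2, P1<->P2 relabeling symmetry.

    Together with :meth:`ModelParams.swap_traits` and the weighting map
    ``gamma -> 1 - gamma`` this symmetry commutes with every life-cycle
    operation.
    """
    f = np.asarray(dist, dtype=float)
    out = np.empty_like(f)
    out[RELABEL32] = f
    return out


def degrees_of_freedom(loci: Iterable[str] = LOCI) -> int:
    """Number of independent genotype frequencies for the given polymorphic loci.

    The frequencies over ``2**k`` genotypes sum to one, leaving ``2**k - 1``
    free variables: 15 for the resident system (M fixed) and 31 once M is
    polymorphic.
    """
    return 2 ** len(tuple(loci)) - 1
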