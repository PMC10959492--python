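"""Female mate choice and the offspring-frequency recursion.

A female's attention is split between the two male traits by the evolving
weighting ``gamma`` through the trade-off ``f(x) = x**a``: attention
``f(1-gamma)`` on T1 and ``f(gamma)`` on T2.  She rejects a male
mismatching her preferred value at a trait with probability ``rho`` times
her attention on that trait, encounters conspecific and heterospecific
males sequentially (monandry: at most one mating; after a rejection she
finds no further male with probability ``c``), and heterospecific matings
are sterile.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._tables import BETA32, BITS, N_GENOTYPES
from .core import Genotype, validate_distribution
from .params import ModelParams


class ReproductionError(RuntimeError):
    """The population cannot reproduce (mean pair contribution is zero)."""


@dataclasses.dataclass(frozen=True)
class PreferenceWeights:
    """Resident and mutant relative preference weightings at locus M.

    A female carrying allele 0 (resp. 1) at M expresses ``gamma_r``
    (resp. ``gamma_m``).  ``gamma = 0`` puts all attention on trait T1,
    ``gamma = 1`` on trait T2.
    """

    gamma_r: float
    gamma_m: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma_r <= 1.0:
            raise ValueError(f"gamma_r must be in [0, 1]; got {self.gamma_r}")
        if self.gamma_m is None:
            object.__setattr__(self, "gamma_m", self.gamma_r)
        elif not 0.0 <= self.gamma_m <= 1.0:
            raise ValueError(f"gamma_m must be in [0, 1]; got {self.gamma_m}")

    def realized(self, m_allele: int) -> float:
        """The weighting expressed by a female with the given allele at M."""
        return self.gamma_m if m_allele else self.gamma_r


@dataclasses.dataclass(frozen=True)
class HeterospecificPool:
    """Males of species B: trait value 1 fixed at both trait loci."""

    t1: int = 1
    t2: int = 1

    def __post_init__(self) -> None:
        if (self.t1, self.t2) != (1, 1):
            raise ValueError("species B males display trait value 1 at both traits")


@dataclasses.dataclass(frozen=True)
class MatingStats:
    """Per-female-genotype mating probabilities.

    ``t_acc``: realized probability of accepting a conspecific at one
    encounter (encounter-share weighted); ``tri_acc``: same for a
    heterospecific; ``p_mate``: probability of ultimately mating with a
    conspecific.
    """

    t_acc: np.ndarray
    tri_acc: np.ndarray
    p_mate: np.ndarray


def _tradeoff(x: np.ndarray | float, a: float) -> np.ndarray | float:
    """Attention function f(x) = x**a with f(0) = 0 enforced for all a.

    The convention 0**0 = 0 keeps "choice relies on a single trait at the
    extremes" true in the a = 0 edge case.
    """
    x = np.asarray(x, dtype=float)
    out = np.where(x > 0.0, np.power(np.where(x > 0.0, x, 1.0), a), 0.0)
    return out if out.shape else float(out)


def attention_weights(gamma: float, a: float) -> tuple[float, float]:
    """Attention on (T1, T2) of a female with weighting ``gamma``."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1]; got {gamma}")
    if a < 0:
        raise ValueError(f"a must be >= 0; got {a}")
    return float(_tradeoff(1.0 - gamma, a)), float(_tradeoff(gamma, a))


def acceptance_probability(female: Genotype, male_traits: tuple[int, int],
                           weights: PreferenceWeights, params: ModelParams) -> float:
    """Probability phi that the female accepts a male with the given traits."""
    gamma = weights.realized(female.m)
    att1, att2 = attention_weights(gamma, params.a)
    t1, t2 = male_traits
    phi = 1.0
    if female.p1 != t1:
        phi *= 1.0 - params.rho * att1
    if female.p2 != t2:
        phi *= 1.0 - params.rho * att2
    return phi


def acceptance_matrix(weights: PreferenceWeights, params: ModelParams) -> np.ndarray:
    """phi(j, k) for every (female genotype j, male genotype k) pair."""
    gamma = np.where(BITS[:, 4] == 1, weights.gamma_m, weights.gamma_r)
    att1 = _tradeoff(1.0 - gamma, params.a)
    att2 = _tradeoff(gamma, params.a)
    mism1 = BITS[:, 2][:, None] != BITS[:, 0][None, :]
    mism2 = BITS[:, 3][:, None] != BITS[:, 1][None, :]
    return ((1.0 - mism1 * params.rho * att1[:, None])
            * (1.0 - mism2 * params.rho * att2[:, None]))


def heterospecific_acceptance_vector(weights: PreferenceWeights,
                                     params: ModelParams) -> np.ndarray:
    """Tri(j) for every female genotype (species B males display (1, 1))."""
    gamma = np.where(BITS[:, 4] == 1, weights.gamma_m, weights.gamma_r)
    att1 = _tradeoff(1.0 - gamma, params.a)
    att2 = _tradeoff(gamma, params.a)
    phi = ((1.0 - (BITS[:, 2] != 1) * params.rho * att1)
           * (1.0 - (BITS[:, 3] != 1) * params.rho * att2))
    return params.share_b * params.cri * phi


def conspecific_acceptance(female: Genotype, dist_after_selection: np.ndarray,
                           weights: PreferenceWeights, params: ModelParams) -> float:
    """Realized per-encounter probability T(j) of accepting a conspecific."""
    f = validate_distribution(dist_after_selection)
    phi_row = acceptance_matrix(weights, params)[female.index]
    return float(params.share_a * (phi_row @ f))


def heterospecific_acceptance(female: Genotype, pool: HeterospecificPool,
                              weights: PreferenceWeights, params: ModelParams) -> float:
    """Realized per-encounter probability Tri(j) of accepting a heterospecific."""
    phi = acceptance_probability(female, (pool.t1, pool.t2), weights, params)
    return params.share_b * params.cri * phi


def conspecific_mating_probability(t_acc, tri_acc, c: float):
    """Probability P(j) that a female ultimately mates with a conspecific.

    Closed form of the sequential-encounter geometric series:
    ``P = T / (c + (1-c) (T + Tri))``.  The degenerate case
    ``T = Tri = 0`` with ``c = 0`` returns 0 (the female never mates).
    Accepts scalars or arrays.
    """
    t = np.asarray(t_acc, dtype=float)
    tri = np.asarray(tri_acc, dtype=float)
    if np.any(t < 0) or np.any(tri < 0) or np.any(t + tri > 1.0 + 1e-9):
        raise ValueError("need t_acc >= 0, tri_acc >= 0 and t_acc + tri_acc <= 1")
    if not 0.0 <= c <= 1.0:
        raise ValueError(f"c must be in [0, 1]; got {c}")
    denom = c + (1.0 - c) * (t + tri)
    out = np.divide(t, denom, out=np.zeros_like(t + denom), where=denom > 0.0)
    return out if out.shape else float(out)


def mating_stats(dist_after_selection: np.ndarray, weights: PreferenceWeights,
                 params: ModelParams) -> MatingStats:
    """T, Tri and P for every female genotype against the given male pool."""
    f = validate_distribution(dist_after_selection)
    phi = acceptance_matrix(weights, params)
    t_acc = params.share_a * (phi @ f)
    tri_acc = heterospecific_acceptance_vector(weights, params)
    p_mate = conspecific_mating_probability(t_acc, tri_acc, params.c)
    return MatingStats(t_acc=t_acc, tri_acc=tri_acc, p_mate=np.asarray(p_mate))


def reproduce(dist_after_selection: np.ndarray, pool: HeterospecificPool | None,
              weights: PreferenceWeights, params: ModelParams) -> np.ndarray:
    """Offspring genotype frequencies after one round of mating.

    Implements the pair-contribution recursion: each (female j, male k)
    pair contributes ``m_jk = P(j) * phi(j,k) / sum_l f'_l phi(j,l)``,
    normalised by the population mean contribution, and offspring are drawn
    through the free-recombination segregation kernel.  ``pool`` (species B
    males, fixed traits (1,1)) enters through Tri; passing ``None`` uses
    the default pool.
    """
    f = validate_distribution(dist_after_selection)
    if pool is None:
        pool = HeterospecificPool()
    phi = acceptance_matrix(weights, params)
    stats = mating_stats(f, weights, params)
    d_norm = phi @ f  # per-female conspecific acceptance normaliser
    u = np.divide(f * stats.p_mate, d_norm,
                  out=np.zeros(N_GENOTYPES), where=d_norm > 0.0)
    pair_w = (u[:, None] * f[None, :]) * phi
    mbar = pair_w.sum()
    if mbar <= 0.0:
        raise ReproductionError("mean pair contribution is zero: no mating pair "
                                "has positive success under these parameters")
    offspring = (pair_w.ravel() / mbar) @ BETA32
    return offspring
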