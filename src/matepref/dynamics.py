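"""Life-cycle composition and resident equilibria.

One generation is viability selection, then reproduction (mate choice with
heterospecific interference), then mutation.  For a fixed resident
weighting ``gamma_r`` (allele 0 fixed at locus M) the recursion is iterated
to its equilibrium genotype distribution, the starting point of every
invasion analysis.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np

from . import core
from ._engine import ResidentEngine, lift_to_full, project_to_resident
from ._tables import BITS16, RESIDENT_LOCI
from .mating import HeterospecificPool, PreferenceWeights, reproduce
from .params import ModelParams

#: default convergence tolerance: L-inf per-generation genotype-frequency change
CONVERGENCE_TOL = 1e-12
#: default cap on the number of generations
MAX_GENERATIONS = 2_000_000

_DEFAULT_INIT = {"T1": 0.5, "T2": 0.5, "P1": 0.5, "P2": 0.5}


class ConvergenceError(RuntimeError):
    """The recursion failed to reach a fixed point within the generation cap."""


@dataclasses.dataclass(frozen=True)
class ResidentEquilibrium:
    """Equilibrated resident state for a fixed weighting ``gamma_r``.

    ``dist`` is the full 32-genotype distribution (allele 0 fixed at M);
    ``allele_freqs`` holds the equilibrium allele-1 frequencies at the four
    evolving loci; ``residual`` is the L-inf frequency change of one
    further generation.
    """

    gamma_r: float
    dist: np.ndarray
    allele_freqs: dict[str, float]
    iterations: int
    converged: bool
    residual: float

    @property
    def resident_dist(self) -> np.ndarray:
        """The 16-genotype distribution over (T1, T2, P1, P2)."""
        return project_to_resident(self.dist)


def generation_step(dist: np.ndarray, weights: PreferenceWeights,
                    params: ModelParams) -> np.ndarray:
    """One full generation: selection, reproduction, mutation (in that order)."""
    f = core.viability_selection(dist, params)
    f = reproduce(f, HeterospecificPool(), weights, params)
    f = core.apply_mutation(f, params)
    f = np.clip(f, 0.0, None)
    return f / f.sum()


def _initial_state16(init_freqs: Mapping[str, float] | np.ndarray | None) -> np.ndarray:
    """Resident 16-genotype start: linkage equilibrium at the given allele
    frequencies (default 0.5 everywhere, i.e. no genetic association)."""
    if init_freqs is None:
        init_freqs = _DEFAULT_INIT
    if isinstance(init_freqs, Mapping):
        freqs = {k.upper(): float(v) for k, v in init_freqs.items()}
        unknown = set(freqs) - set(RESIDENT_LOCI)
        if unknown:
            raise KeyError(f"unknown loci in init_freqs: {sorted(unknown)}")
        p = np.array([freqs.get(name, 0.5) for name in RESIDENT_LOCI])
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError("initial allele frequencies must lie in (0, 1)")
        return np.prod(np.where(BITS16 == 1, p[None, :], 1.0 - p[None, :]), axis=1)
    arr = np.asarray(init_freqs, dtype=float)
    if arr.shape == (32,):
        return project_to_resident(arr)
    if arr.shape == (16,):
        return arr / arr.sum()
    raise ValueError("init_freqs must be a locus->frequency mapping or a "
                     "16- or 32-genotype distribution")


def find_resident_equilibrium(params: ModelParams, gamma_r: float,
                              init_freqs: Mapping[str, float] | np.ndarray | None = None,
                              tol: float = CONVERGENCE_TOL,
                              max_generations: int = MAX_GENERATIONS,
                              ) -> ResidentEquilibrium:
    """Equilibrate the resident recursion for a fixed ``gamma_r``.

    Starts from linkage equilibrium at the given allele frequencies
    (default 0.5 at T1, T2, P1, P2) and iterates the life cycle until one
    generation changes no genotype frequency by more than ``tol``.  A
    Newton polish accelerates the terminal approach; the result is always
    verified against the fixed-point criterion itself.  Non-convergence
    within ``max_generations`` is reported via ``converged=False``.
    """
    engine = ResidentEngine(params, gamma_r)
    f0 = _initial_state16(init_freqs)
    f16, iters, converged, residual = engine.equilibrate(
        f0, tol=tol, max_generations=max_generations)
    dist = lift_to_full(f16)
    freqs = {name: core.allele_frequency(dist, name) for name in RESIDENT_LOCI}
    return ResidentEquilibrium(gamma_r=gamma_r, dist=dist, allele_freqs=freqs,
                               iterations=iters, converged=converged,
                               residual=residual)


@dataclasses.dataclass(frozen=True)
class IndependenceReport:
    """Sensitivity of the equilibrium to the initial allele frequencies."""

    equilibria: list[ResidentEquilibrium]
    max_distance: float
    multistable: bool


def check_equilibrium_independence(params: ModelParams, gamma_r: float,
                                   init_freqs_list: Sequence[Mapping[str, float]],
                                   tol: float = 1e-8) -> IndependenceReport:
    """Equilibrate from several initialisations and compare the outcomes.

    Returns the maximum pairwise L-inf distance between the resulting
    genotype distributions and flags multistability when it exceeds
    ``tol``.
    """
    if len(init_freqs_list) < 2:
        raise ValueError("need at least two initialisations to compare")
    eqs = [find_resident_equilibrium(params, gamma_r, init_freqs=init)
           for init in init_freqs_list]
    dmax = 0.0
    for i in range(len(eqs)):
        for j in range(i + 1, len(eqs)):
            dmax = max(dmax, float(np.max(np.abs(eqs[i].dist - eqs[j].dist))))
    return IndependenceReport(equilibria=eqs, max_distance=dmax,
                              multistable=dmax > tol)


def allele_trajectory(params: ModelParams, weights: PreferenceWeights,
                      n_generations: int,
                      init_freqs: Mapping[str, float] | np.ndarray | None = None,
                      ) -> "np.ndarray":
    """Deterministic allele-1 frequency trajectories at the four evolving loci.

    Returns an array of shape (n_generations + 1, 4) with columns ordered
    (T1, T2, P1, P2); row 0 is the initial state.  Used as the reference
    for the stochastic individual-based oracle.
    """
    engine = ResidentEngine(params, weights.gamma_r)
    f = _initial_state16(init_freqs)
    out = np.empty((n_generations + 1, 4))
    out[0] = f @ BITS16
    for g in range(n_generations):
        f = engine.step(f)
        out[g + 1] = f @ BITS16
    return out
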