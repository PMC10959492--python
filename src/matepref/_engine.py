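"""Vectorised recursion engines.

Two fast paths behind the public API:

* :class:`ResidentEngine` — the resident life cycle on the 16-genotype
  subspace with allele 0 fixed at the weighting locus M (an exact
  reduction: every operator preserves that subspace), with an accelerated
  fixed-point solver.
* :class:`InvasionEngine` — the full 32-genotype life cycle with a mutant
  weighting allele at M, optionally restricted so that the mutant's gamma
  deviation enters only one fitness pathway (used by the selection-gradient
  decomposition).

The female mating probability is factored exactly as ``P = Q * R`` with
``Q = (T+Tri)/(c + (1-c)(T+Tri))`` (probability of ever mating; identically
1 when c = 0) and ``R = T/(T+Tri)`` (conspecific share of matings;
identically 1 when cri = 0).  Pathway restriction chooses, slot by slot,
whether the mutant-aware or the resident acceptance enters Q, R and the
mate-identity kernel.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from ._tables import (BETA16, BETA32, BITS16, FLIP16, FLIP32, LIFT,
                      N_GENOTYPES)
from .mating import (PreferenceWeights, ReproductionError, _tradeoff,
                     acceptance_matrix, heterospecific_acceptance_vector)
from .params import ModelParams

#: pathway-restriction modes for InvasionEngine
MODES = ("full", "choice", "share", "retention")


def lift_to_full(f16: np.ndarray) -> np.ndarray:
    """Embed a resident (M = 0) distribution into the 32-genotype space."""
    f32 = np.zeros(N_GENOTYPES)
    f32[LIFT] = f16
    return f32


def project_to_resident(f32: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Restrict a 32-genotype distribution with M fixed at 0 to 16 genotypes."""
    f32 = np.asarray(f32, dtype=float)
    if f32[LIFT + 1].sum() > tol:
        raise ValueError("distribution carries mutant M alleles; not a resident state")
    f16 = f32[LIFT].copy()
    return f16 / f16.sum()


def _acceptance_matrix16(gamma_r: float, params: ModelParams) -> np.ndarray:
    """phi(j, k) over the resident subspace (all females express gamma_r)."""
    att1 = float(_tradeoff(1.0 - gamma_r, params.a))
    att2 = float(_tradeoff(gamma_r, params.a))
    mism1 = BITS16[:, 2][:, None] != BITS16[:, 0][None, :]
    mism2 = BITS16[:, 3][:, None] != BITS16[:, 1][None, :]
    return ((1.0 - mism1 * params.rho * att1)
            * (1.0 - mism2 * params.rho * att2))


def _tri_vector16(gamma_r: float, params: ModelParams) -> np.ndarray:
    att1 = float(_tradeoff(1.0 - gamma_r, params.a))
    att2 = float(_tradeoff(gamma_r, params.a))
    phi = ((1.0 - (BITS16[:, 2] != 1) * params.rho * att1)
           * (1.0 - (BITS16[:, 3] != 1) * params.rho * att2))
    return params.share_b * params.cri * phi


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0.0)


class ResidentEngine:
    """One-generation map and equilibrium solver for the resident system."""

    def __init__(self, params: ModelParams, gamma_r: float):
        self.params = params
        self.gamma_r = gamma_r
        self.w = (1.0 + BITS16[:, 0] * params.s1) * (1.0 + BITS16[:, 1] * params.s2)
        self.phi = _acceptance_matrix16(gamma_r, params)
        self.tri = _tri_vector16(gamma_r, params)
        self.mut = [(FLIP16[name], u) for name, u in
                    (("T1", params.u_t1), ("T2", params.u_t2),
                     ("P1", params.u_p1), ("P2", params.u_p2)) if u > 0.0]

    def step(self, f: np.ndarray) -> np.ndarray:
        """selection -> reproduction -> mutation on the 16-genotype simplex."""
        p = self.params
        wf = self.w * f
        fs = wf / wf.sum()
        d = self.phi @ fs
        t = p.share_a * d
        denom = p.c + (1.0 - p.c) * (t + self.tri)
        pmate = _safe_div(t, denom)
        u = _safe_div(fs * pmate, d)
        pair_w = (u[:, None] * fs[None, :]) * self.phi
        mbar = pair_w.sum()
        if mbar <= 0.0:
            raise ReproductionError("mean pair contribution is zero")
        f2 = (pair_w.ravel() / mbar) @ BETA16
        for flip, rate in self.mut:
            f2 = (1.0 - rate) * f2 + rate * f2[flip]
        f2 = np.clip(f2, 0.0, None)
        return f2 / f2.sum()

    def iterate(self, f: np.ndarray, n: int, tol: float = 0.0
                ) -> tuple[np.ndarray, float, int]:
        """Run up to ``n`` generations; stop early once the per-generation
        L-infinity change drops below ``tol``.  Returns (state, last change,
        generations used)."""
        delta = np.inf
        for i in range(n):
            f2 = self.step(f)
            delta = float(np.max(np.abs(f2 - f)))
            f = f2
            if delta < tol:
                return f, delta, i + 1
        return f, delta, n

    def _newton_polish(self, f: np.ndarray, tol: float
                       ) -> tuple[np.ndarray, float] | None:
        """Solve step(f) = f by a damped Newton (hybr) start from ``f``.

        Accepted only if the root is a valid simplex point, lies in a small
        neighbourhood of the iterate (so we stay on the attractor reached
        by the dynamics), and passes the fixed-point criterion ``tol``.
        """
        try:
            sol = optimize.root(lambda x: self.step(x) - x, f, method="hybr",
                                options={"xtol": 1e-14})
        except (ReproductionError, FloatingPointError):
            return None
        x = sol.x
        if not sol.success or x.min() < -1e-10 or abs(x.sum() - 1.0) > 1e-6:
            return None
        if float(np.max(np.abs(x - f))) > 0.05:
            return None
        x = np.clip(x, 0.0, None)
        x = x / x.sum()
        delta = float(np.max(np.abs(self.step(x) - x)))
        if delta >= tol:
            return None
        return x, delta

    def equilibrate(self, f0: np.ndarray, tol: float = 1e-12,
                    max_generations: int = 2_000_000,
                    ) -> tuple[np.ndarray, int, bool, float]:
        """Iterate to the resident equilibrium.

        Plain iteration with periodic Newton polishing; the returned state
        always satisfies (or reports failing) the fixed-point criterion
        "one further generation changes no frequency by more than ``tol``".
        Returns (state, generations used, converged flag, residual change).
        """
        f = np.asarray(f0, dtype=float).copy()
        total = 0
        delta = np.inf
        chunk = 2_000
        while total < max_generations:
            f, delta, used = self.iterate(f, min(chunk, max_generations - total), tol)
            total += used
            if delta < tol:
                return f, total, True, delta
            polished = self._newton_polish(f, tol)
            if polished is not None:
                f, delta = polished
                return f, total, True, delta
            chunk = 20_000
        return f, total, False, delta


class InvasionEngine:
    """Full 32-genotype life cycle with resident and mutant weighting alleles.

    ``mode`` restricts where the mutant's gamma (as opposed to the
    resident's) enters the mutant females' fitness:

    * ``"full"``      — everywhere (the actual model dynamics);
    * ``"choice"``    — only in the conspecific mate-identity kernel
      Phi(j,k) (which male she mates with, given a conspecific mating);
    * ``"share"``     — only in R = T/(T+Tri), the conspecific share of
      matings (the heterospecific-exposure pathway);
    * ``"retention"`` — only in Q = (T+Tri)/(c+(1-c)(T+Tri)), the
      probability of ever mating (the cost-of-choosiness pathway).

    Resident (M = 0) females always express gamma_r in every slot.
    """

    def __init__(self, params: ModelParams, gamma_r: float, gamma_m: float,
                 mode: str = "full"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}; got {mode!r}")
        self.params = params
        self.mode = mode
        from .core import fitness_vector  # local import avoids cycle at module load
        self.w = fitness_vector(params)
        res = PreferenceWeights(gamma_r, gamma_r)
        mut = PreferenceWeights(gamma_r, gamma_m)
        self.phi_res = acceptance_matrix(res, params)
        self.phi_mut = acceptance_matrix(mut, params)
        self.tri_res = heterospecific_acceptance_vector(res, params)
        self.tri_mut = heterospecific_acceptance_vector(mut, params)
        self.mut_rates = [(FLIP32[name], u) for name, u in
                          (("T1", params.u_t1), ("T2", params.u_t2),
                           ("P1", params.u_p1), ("P2", params.u_p2)) if u > 0.0]

    def select(self, f: np.ndarray) -> np.ndarray:
        wf = self.w * f
        return wf / wf.sum()

    def reproduce(self, fs: np.ndarray) -> np.ndarray:
        p = self.params
        mutant_aware = self.mode in ("full", "choice")
        phi_choice = self.phi_mut if mutant_aware else self.phi_res
        t_res = p.share_a * (self.phi_res @ fs)
        t_mut = p.share_a * (self.phi_mut @ fs)
        if self.mode in ("full", "share"):
            t_r, tri_r = t_mut, self.tri_mut
        else:
            t_r, tri_r = t_res, self.tri_res
        if self.mode in ("full", "retention"):
            t_q, tri_q = t_mut, self.tri_mut
        else:
            t_q, tri_q = t_res, self.tri_res
        tot_r = t_r + tri_r
        share = _safe_div(t_r, tot_r)
        tot_q = t_q + tri_q
        denom_q = p.c + (1.0 - p.c) * tot_q
        retention = _safe_div(tot_q, denom_q)
        pmate = retention * share
        d = phi_choice @ fs
        u = _safe_div(fs * pmate, d)
        pair_w = (u[:, None] * fs[None, :]) * phi_choice
        mbar = pair_w.sum()
        if mbar <= 0.0:
            raise ReproductionError("mean pair contribution is zero")
        return (pair_w.ravel() / mbar) @ BETA32

    def mutate(self, f: np.ndarray) -> np.ndarray:
        for flip, rate in self.mut_rates:
            f = (1.0 - rate) * f + rate * f[flip]
        f = np.clip(f, 0.0, None)
        return f / f.sum()

    def step(self, f: np.ndarray) -> np.ndarray:
        return self.mutate(self.reproduce(self.select(f)))

    def step_stages(self, f: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """One generation, returning the state after each life-cycle stage
        (selection, reproduction, mutation)."""
        fs = self.select(f)
        fr = self.reproduce(fs)
        return fs, fr, self.mutate(fr)
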