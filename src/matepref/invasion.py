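"""Adaptive dynamics of the relative preference weighting gamma.

A rare mutant allele at locus M changes a female's weighting from
``gamma_r`` to ``gamma_m``.  Its per-generation frequency change after a
short burn-in (genetic associations equilibrate quickly relative to allele
frequencies) defines the selection gradient

    S = dPM / (PM (1 - PM) dgamma),

positive when selection pushes preference toward the neutral-side trait T2
(gamma increases).  The gradient is decomposed into four selective forces
(offspring survival, offspring reproductive success, reproductive
interference, cost of choosiness) by pathway-restricted mutant runs, and
gamma* — the continuously stable weighting reached from the ancestral
``gamma_t0`` — is found by following the sign of S.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Sequence

import numpy as np

from ._engine import InvasionEngine, project_to_resident
from ._tables import BITS, LIFT, LOCI
from .dynamics import (CONVERGENCE_TOL, MAX_GENERATIONS, ConvergenceError,
                       ResidentEquilibrium, find_resident_equilibrium)
from .params import ModelParams

#: tolerance on |Sos + Sor + Sri + Sc - S| relative to max(1, |S|)
DECOMPOSITION_TOL = 1e-6

Kind = Literal["css", "repeller", "branching", "boundary", "inconclusive"]


@dataclasses.dataclass(frozen=True)
class GradientSettings:
    """Numerical settings of the invasion analyses.

    ``delta_gamma``: mutant effect size for the central-difference
    gradient; ``mutant_freq``: introduction frequency of the mutant allele;
    ``burn_in``: generations run before the gradient is read off (lets the
    M-locus genetic associations reach their quasi-equilibrium);
    ``flow_step``: gamma step of the gradient flow toward gamma*;
    ``root_tol``: bisection tolerance on singular points; ``zero_tol``:
    |S| below this is treated as zero; ``classify_offset``/``es_offset``:
    gamma offsets used for convergence- and evolutionary-stability tests;
    ``growth_tol``: per-generation relative mutant growth below this is
    treated as neutral.
    """

    delta_gamma: float = 1e-3
    mutant_freq: float = 1e-4
    burn_in: int = 50
    flow_step: float = 0.01
    root_tol: float = 1e-4
    zero_tol: float = 1e-9
    classify_offset: float = 0.01
    es_offset: float = 0.02
    growth_tol: float = 1e-12
    equilibrium_tol: float = CONVERGENCE_TOL
    max_generations: int = MAX_GENERATIONS
    max_flow_steps: int = 1000


DEFAULT_SETTINGS = GradientSettings()


@dataclasses.dataclass(frozen=True)
class InvasionOutcome:
    """Fate of a rare weighting mutant in an equilibrated resident population."""

    gamma_r: float
    gamma_m: float
    delta_p_m: float
    invades: bool


@dataclasses.dataclass(frozen=True)
class GradientDecomposition:
    """Selection gradient and its four components (their sum equals S).

    ``s_os``: offspring survival (transmission of viability alleles at the
    trait loci); ``s_or``: offspring reproductive success ("sexy sons");
    ``s_ri``: reproductive interference (heterospecific-mating exposure);
    ``s_c``: cost of choosiness (probability of never mating).
    """

    s_total: float
    s_os: float
    s_or: float
    s_ri: float
    s_c: float
    residual: float


@dataclasses.dataclass(frozen=True)
class SingularPoint:
    """A weighting where the selection gradient vanishes (or a boundary
    attractor, where S points outward)."""

    gamma_value: float
    kind: Kind


def mutant_frequency(dist: np.ndarray) -> float:
    """Frequency of the mutant allele (allele 1 at locus M)."""
    return float(np.asarray(dist, dtype=float) @ BITS[:, LOCI.index("M")])


def introduce_mutant(eq: ResidentEquilibrium | np.ndarray, gamma_m: float | None = None,
                     p0: float = 1e-4) -> np.ndarray:
    """Place the mutant M allele at frequency ``p0`` in linkage equilibrium
    with the resident background.

    ``gamma_m`` is carried by the returned state only implicitly (the
    weighting expressed by M-carriers is set when the dynamics are run);
    it is accepted here for interface completeness and unused.
    """
    if not 0.0 < p0 <= 0.01:
        raise ValueError(f"mutant introduction frequency must be in (0, 0.01]; got {p0}")
    dist = eq.dist if isinstance(eq, ResidentEquilibrium) else np.asarray(eq, float)
    background = dist[LIFT] + dist[LIFT + 1]
    out = np.zeros_like(dist)
    out[LIFT] = (1.0 - p0) * background
    out[LIFT + 1] = p0 * background
    return out


def _growth_stages(params: ModelParams, gamma_r: float, gamma_m: float,
                   eq_dist: np.ndarray, settings: GradientSettings,
                   mode: str) -> tuple[float, float, float]:
    """Mutant frequency (before selection, after selection, after
    reproduction) in the generation following the association burn-in."""
    engine = InvasionEngine(params, gamma_r, gamma_m, mode=mode)
    f = introduce_mutant(eq_dist, p0=settings.mutant_freq)
    for _ in range(settings.burn_in):
        f = engine.step(f)
    p_before = mutant_frequency(f)
    fs, fr, _ = engine.step_stages(f)
    return p_before, mutant_frequency(fs), mutant_frequency(fr)


def _require_converged(eq: ResidentEquilibrium) -> ResidentEquilibrium:
    if not eq.converged:
        raise ConvergenceError(
            f"resident equilibrium at gamma_r={eq.gamma_r} did not converge "
            f"(residual {eq.residual:.3e} after {eq.iterations} generations)")
    return eq


def _sides(gamma_r: float, delta_gamma: float) -> list[float]:
    """Mutant offsets for the central difference; one-sided at the boundaries."""
    sides = [d for d in (delta_gamma, -delta_gamma)
             if 0.0 <= gamma_r + d <= 1.0]
    if not sides:
        raise ValueError(f"delta_gamma={delta_gamma} leaves no admissible mutant "
                         f"around gamma_r={gamma_r}")
    return sides


def selection_gradient(params: ModelParams, gamma_r: float,
                       settings: GradientSettings = DEFAULT_SETTINGS,
                       equilibrium: ResidentEquilibrium | None = None) -> float:
    """Selection gradient S on the weighting at resident value ``gamma_r``.

    Central difference over mutants at ``gamma_r +/- delta_gamma`` (one-
    sided at the boundaries), each assessed from the per-generation change
    of a rare mutant after the association burn-in.
    """
    eq = _require_converged(equilibrium if equilibrium is not None else
                            find_resident_equilibrium(
                                params, gamma_r, tol=settings.equilibrium_tol,
                                max_generations=settings.max_generations))
    estimates = []
    for delta in _sides(gamma_r, settings.delta_gamma):
        p0, _, p2 = _growth_stages(params, gamma_r, gamma_r + delta, eq.dist,
                                   settings, "full")
        estimates.append((p2 - p0) / (p0 * (1.0 - p0) * delta))
    return float(np.mean(estimates))


def decompose_gradient(params: ModelParams, gamma_r: float,
                       settings: GradientSettings = DEFAULT_SETTINGS,
                       equilibrium: ResidentEquilibrium | None = None
                       ) -> GradientDecomposition:
    """Four-way decomposition of the selection gradient.

    Each component is the gradient measured when the mutant's gamma
    deviation enters only the corresponding pathway (the mutant is the
    resident everywhere else):

    * mate-identity pathway, split by life-cycle stage into the viability-
      selection step (``s_os``, offspring survival) and the reproduction
      step (``s_or``, offspring mating success through sexy sons);
    * conspecific share of matings R (``s_ri``, heterospecific exposure);
    * probability of ever mating Q (``s_c``, cost of choosiness).

    ``s_ri`` is identically 0 when ``cri = 0`` (then Tri == 0 so R == 1)
    and ``s_c`` identically 0 when ``c = 0`` (then Q == 1): the restricted
    mutant is then exactly the resident.  The components are checked to sum
    to the independently measured total gradient.
    """
    eq = _require_converged(equilibrium if equilibrium is not None else
                            find_resident_equilibrium(
                                params, gamma_r, tol=settings.equilibrium_tol,
                                max_generations=settings.max_generations))
    totals, s_os, s_or, s_ri, s_c = [], [], [], [], []
    for delta in _sides(gamma_r, settings.delta_gamma):
        gm = gamma_r + delta

        p0, _, p2 = _growth_stages(params, gamma_r, gm, eq.dist, settings, "full")
        denom = p0 * (1.0 - p0) * delta
        totals.append((p2 - p0) / denom)

        p0, ps, p2 = _growth_stages(params, gamma_r, gm, eq.dist, settings, "choice")
        denom = p0 * (1.0 - p0) * delta
        s_os.append((ps - p0) / denom)
        s_or.append((p2 - ps) / denom)

        if params.cri == 0.0:
            s_ri.append(0.0)  # Tri == 0 => R == 1: pathway provably inert
        else:
            p0, _, p2 = _growth_stages(params, gamma_r, gm, eq.dist, settings, "share")
            s_ri.append((p2 - p0) / (p0 * (1.0 - p0) * delta))

        if params.c == 0.0:
            s_c.append(0.0)  # c == 0 => Q == 1: pathway provably inert
        else:
            p0, _, p2 = _growth_stages(params, gamma_r, gm, eq.dist, settings,
                                       "retention")
            s_c.append((p2 - p0) / (p0 * (1.0 - p0) * delta))

    dec = GradientDecomposition(
        s_total=float(np.mean(totals)), s_os=float(np.mean(s_os)),
        s_or=float(np.mean(s_or)), s_ri=float(np.mean(s_ri)),
        s_c=float(np.mean(s_c)), residual=0.0)
    residual = abs(dec.s_os + dec.s_or + dec.s_ri + dec.s_c - dec.s_total)
    if residual > DECOMPOSITION_TOL * max(1.0, abs(dec.s_total)):
        raise ArithmeticError(
            f"gradient decomposition violates the sum constraint: "
            f"|Sos+Sor+Sri+Sc - S| = {residual:.3e} at gamma_r={gamma_r}")
    return dataclasses.replace(dec, residual=residual)


def invasion_outcome(params: ModelParams, gamma_r: float, gamma_m: float,
                     settings: GradientSettings = DEFAULT_SETTINGS,
                     equilibrium: ResidentEquilibrium | None = None
                     ) -> InvasionOutcome:
    """Fate of a rare mutant ``gamma_m`` in a ``gamma_r`` resident population."""
    eq = _require_converged(equilibrium if equilibrium is not None else
                            find_resident_equilibrium(
                                params, gamma_r, tol=settings.equilibrium_tol,
                                max_generations=settings.max_generations))
    p0, _, p2 = _growth_stages(params, gamma_r, gamma_m, eq.dist, settings, "full")
    delta_p = p2 - p0
    return InvasionOutcome(gamma_r=gamma_r, gamma_m=gamma_m, delta_p_m=delta_p,
                           invades=bool(delta_p / p0 > settings.growth_tol))


class _GradientEvaluator:
    """Warm-started S(gamma_r) evaluations along a gamma path."""

    def __init__(self, params: ModelParams, settings: GradientSettings):
        self.params = params
        self.settings = settings
        self._last_state: np.ndarray | None = None
        self.equilibria: dict[float, ResidentEquilibrium] = {}

    def equilibrium(self, gamma_r: float) -> ResidentEquilibrium:
        eq = self.equilibria.get(gamma_r)
        if eq is None:
            eq = find_resident_equilibrium(
                self.params, gamma_r, init_freqs=self._last_state,
                tol=self.settings.equilibrium_tol,
                max_generations=self.settings.max_generations)
            _require_converged(eq)
            self._last_state = project_to_resident(eq.dist)
            self.equilibria[gamma_r] = eq
        return eq

    def gradient(self, gamma_r: float) -> float:
        return selection_gradient(self.params, gamma_r, self.settings,
                                  equilibrium=self.equilibrium(gamma_r))


def _bisect_root(ev: _GradientEvaluator, lo: float, s_lo: float,
                 hi: float, s_hi: float) -> float:
    """Refine a sign change of S to within ``root_tol`` by bisection."""
    settings = ev.settings
    while hi - lo > settings.root_tol:
        mid = 0.5 * (lo + hi)
        s_mid = ev.gradient(mid)
        if abs(s_mid) <= settings.zero_tol:
            return mid
        if (s_mid > 0) == (s_lo > 0):
            lo, s_lo = mid, s_mid
        else:
            hi, s_hi = mid, s_mid
    return 0.5 * (lo + hi)


def classify_singular_point(params: ModelParams, gamma_s: float,
                            settings: GradientSettings = DEFAULT_SETTINGS) -> Kind:
    """Classify a singular weighting.

    Convergence stability from the sign of S on either side of the root;
    evolutionary stability from the invasion of mutants at
    ``gamma_s +/- es_offset`` into the ``gamma_s`` resident.  Convergent
    and uninvadable -> ``"css"``; non-convergent -> ``"repeller"``;
    convergent but invadable -> ``"branching"``.  A slope below numerical
    resolution is reported as ``"inconclusive"``.
    """
    ev = _GradientEvaluator(params, settings)
    h = settings.classify_offset
    lo = max(gamma_s - h, 0.0)
    hi = min(gamma_s + h, 1.0)
    s_lo = ev.gradient(lo) if lo < gamma_s else math.inf
    s_hi = ev.gradient(hi) if hi > gamma_s else -math.inf
    if abs(s_hi - s_lo) < settings.zero_tol:
        return "inconclusive"
    convergent = s_hi < s_lo
    if not convergent:
        return "repeller"
    eq = ev.equilibrium(gamma_s)
    invadable = False
    for off in (settings.es_offset, -settings.es_offset):
        gm = gamma_s + off
        if not 0.0 <= gm <= 1.0:
            continue
        out = invasion_outcome(params, gamma_s, gm, settings, equilibrium=eq)
        invadable = invadable or out.invades
    return "branching" if invadable else "css"


def find_singular_points(params: ModelParams,
                         gamma_grid: Sequence[float] | None = None,
                         settings: GradientSettings = DEFAULT_SETTINGS
                         ) -> list[SingularPoint]:
    """Locate and classify all singular weightings on a gamma grid.

    Sign changes of S between grid points are refined by bisection; grid
    points where |S| is already below ``zero_tol`` count as roots.
    Boundary attractors (gamma = 0 with S < 0, gamma = 1 with S > 0) are
    included with kind ``"boundary"``.  An empty interior list is valid
    (S of constant sign: evolution runs to a boundary).
    """
    grid = np.asarray(gamma_grid if gamma_grid is not None
                      else np.linspace(0.0, 1.0, 21), dtype=float)
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("gamma grid must lie within [0, 1]")
    grid = np.unique(grid)
    ev = _GradientEvaluator(params, settings)
    s_vals = np.array([ev.gradient(g) for g in grid])

    roots: list[float] = []
    for g, s in zip(grid, s_vals):
        if abs(s) <= settings.zero_tol and 0.0 < g < 1.0:
            roots.append(float(g))
    for i in range(len(grid) - 1):
        s_a, s_b = s_vals[i], s_vals[i + 1]
        if abs(s_a) <= settings.zero_tol or abs(s_b) <= settings.zero_tol:
            continue
        if (s_a > 0) != (s_b > 0):
            roots.append(_bisect_root(ev, float(grid[i]), float(s_a),
                                      float(grid[i + 1]), float(s_b)))

    points = [SingularPoint(gamma_value=r,
                            kind=classify_singular_point(params, r, settings))
              for r in sorted(roots)]
    if s_vals[0] < -settings.zero_tol and grid[0] == 0.0:
        points.insert(0, SingularPoint(gamma_value=0.0, kind="boundary"))
    if s_vals[-1] > settings.zero_tol and grid[-1] == 1.0:
        points.append(SingularPoint(gamma_value=1.0, kind="boundary"))
    return points


def equilibrium_weighting(params: ModelParams, gamma_t0: float = 0.5,
                          settings: GradientSettings = DEFAULT_SETTINGS) -> float:
    """The equilibrium weighting gamma* reached from the ancestral ``gamma_t0``.

    Follows the sign of the selection gradient in steps of ``flow_step``
    (the gradient flow of recurrent small-effect mutant fixations) until a
    sign change (refined to a singular point by bisection), a vanishing
    gradient, or a boundary with outward-pointing S is reached.

    If S already vanishes at ``gamma_t0`` (for example under the exact
    T1<->T2 symmetry) the deterministic flow cannot leave it and
    ``gamma_t0`` is returned.
    """
    if not 0.0 <= gamma_t0 <= 1.0:
        raise ValueError(f"gamma_t0 must be in [0, 1]; got {gamma_t0}")
    ev = _GradientEvaluator(params, settings)
    g = float(gamma_t0)
    s = ev.gradient(g)
    if abs(s) <= settings.zero_tol:
        return g
    for _ in range(settings.max_flow_steps):
        step = math.copysign(settings.flow_step, s)
        g_new = min(max(g + step, 0.0), 1.0)
        if g_new == g:  # at a boundary with S pointing outward
            return g
        s_new = ev.gradient(g_new)
        if abs(s_new) <= settings.zero_tol:
            return g_new
        if (s_new > 0) != (s > 0):
            if g < g_new:
                return _bisect_root(ev, g, s, g_new, s_new)
            return _bisect_root(ev, g_new, s_new, g, s)
        g, s = g_new, s_new
    raise ConvergenceError(
        f"gamma flow did not settle within {settings.max_flow_steps} steps "
        f"(last gamma={g}, S={s:.3e}); oscillation or runaway suspected")


def pairwise_invasibility(params: ModelParams,
                          grid: Sequence[float] | None = None,
                          settings: GradientSettings = DEFAULT_SETTINGS
                          ) -> np.ndarray:
    """Pairwise invasibility plot: sign of invasion fitness on a (resident,
    mutant) gamma grid.

    Entry ``[i, j]`` is +1/-1/0 for mutant ``grid[j]`` invading, failing
    to invade, or being neutral in resident ``grid[i]``; the diagonal is 0.
    """
    gammas = np.asarray(grid if grid is not None else np.linspace(0.0, 1.0, 21),
                        dtype=float)
    if gammas.min() < 0 or gammas.max() > 1:
        raise ValueError("gamma grid must lie within [0, 1]")
    ev = _GradientEvaluator(params, settings)
    out = np.zeros((len(gammas), len(gammas)), dtype=int)
    for i, gr in enumerate(gammas):
        eq = ev.equilibrium(float(gr))
        for j, gm in enumerate(gammas):
            if gm == gr:
                continue
            res = invasion_outcome(params, float(gr), float(gm), settings,
                                   equilibrium=eq)
            growth = res.delta_p_m / settings.mutant_freq
            if abs(growth) <= settings.growth_tol:
                out[i, j] = 0
            else:
                out[i, j] = 1 if growth > 0 else -1
    return out
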