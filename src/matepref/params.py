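"""Model parameters.

All parameters of one model instance: viability selection on the two
displayed traits, preference strength, cost of choosiness, reproductive
interference, species densities and per-locus mutation rates.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Any


@dataclasses.dataclass(frozen=True)
class ModelParams:
    """Fixed parameters of the two-species mate-preference model.

    Attributes
    ----------
    s1, s2 : float
        Selective advantage of allele 1 at trait loci T1 and T2
        (``>= 0``: natural selection increases similarity with species B,
        where allele 1 is fixed at both trait loci).
    rho : float
        Strength of female preference in ``[0, 1]``; a female rejects a
        male mismatching her preferred value at a trait with probability
        ``rho`` times her attention on that trait.
    c : float
        Cost of choosiness in ``[0, 1]``: probability that a female who
        rejects a male never encounters another one.
    cri : float
        Reproductive-interference strength in ``[0, 1]``: scales the
        probability of accepting a heterospecific male (whose matings are
        sterile).
    a : float
        Shape of the attention trade-off ``f(x) = x**a``; ``a < 1`` weak
        (concave) trade-off, ``a = 1`` linear, ``a > 1`` strong (convex).
    n_a, n_b : float
        Densities of species A and B; only the encounter shares
        ``n_a/(n_a+n_b)`` and ``n_b/(n_a+n_b)`` enter the model.
    u_t1, u_t2, u_p1, u_p2 : float
        Per-generation symmetric mutation probabilities at T1, T2, P1, P2.
        The weighting locus M never mutates during resident dynamics.
    """

    s1: float = 0.0
    s2: float = 0.0
    rho: float = 0.01
    c: float = 0.0
    cri: float = 0.0
    a: float = math.exp(-1)
    n_a: float = 10.0
    n_b: float = 10.0
    u_t1: float = 0.002
    u_t2: float = 0.002
    u_p1: float = 2e-5
    u_p2: float = 2e-5

    def __post_init__(self) -> None:
        for name in ("s1", "s2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (selection increases similarity "
                                 f"with species B); got {getattr(self, name)}")
        for name in ("rho", "c", "cri"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]; got {v}")
        if self.a < 0:
            raise ValueError(f"a must be >= 0; got {self.a}")
        if self.n_a <= 0:
            raise ValueError(f"n_a must be > 0; got {self.n_a}")
        if self.n_b < 0:
            raise ValueError(f"n_b must be >= 0; got {self.n_b}")
        for name in ("u_t1", "u_t2", "u_p1", "u_p2"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must be in [0, 1); got {v}")

    @property
    def share_a(self) -> float:
        """Probability that a randomly encountered male is conspecific."""
        return self.n_a / (self.n_a + self.n_b)

    @property
    def share_b(self) -> float:
        """Probability that a randomly encountered male is heterospecific."""
        return self.n_b / (self.n_a + self.n_b)

    def replace(self, **changes: Any) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def swap_traits(self) -> "ModelParams":
        """Parameters under the T1<->T2, P1<->P2 relabeling symmetry."""
        return self.replace(s1=self.s2, s2=self.s1,
                            u_t1=self.u_t2, u_t2=self.u_t1,
                            u_p1=self.u_p2, u_p2=self.u_p1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_params() -> ModelParams:
    """The model's default parameter set (all dataclass defaults)."""
    return ModelParams()
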