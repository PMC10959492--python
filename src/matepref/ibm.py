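"""Stochastic individual-based realisation of the identical life cycle.

A finite Wright-Fisher-style population of haploid five-locus genotypes:
binomial viability survival, per-female sequential mate encounters
(conspecific with probability N/(N+Ntilde), otherwise a species B male
displaying traits (1,1)), acceptance by the same preference function phi
(scaled by cri for heterospecifics), give-up probability c after each
rejection, sterile heterospecific matings, Mendelian free recombination,
symmetric mutation, and multinomial regulation back to constant size.

This module exists as a brute-force verification oracle for the
deterministic recursion; drift-driven phenomena are not science output.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from ._tables import SHIFTS
from .core import distribution_from_allele_freqs
from .mating import (PreferenceWeights, acceptance_matrix,
                     heterospecific_acceptance_vector)
from .params import ModelParams

#: cap on mate-search attempts per female per generation (numerical guard;
#: the probability of reaching it is negligible in tested regimes)
MAX_ATTEMPTS = 10_000


class ExtinctionError(RuntimeError):
    """No reproducing pair was formed in some generation."""


@dataclasses.dataclass(frozen=True)
class IbmConfig:
    """Configuration of one individual-based run."""

    pop_size: int
    generations: int
    seed: int
    params: ModelParams
    weights: PreferenceWeights
    init_freqs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise ValueError(f"pop_size must be >= 2; got {self.pop_size}")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def _allele_freqs(genomes: np.ndarray) -> dict[str, float]:
    return {name: float(((genomes >> shift) & 1).mean())
            for name, shift in SHIFTS.items()}


def simulate_ibm(config: IbmConfig, replicate: int = 0) -> pd.DataFrame:
    """Run one replicate; returns tidy (generation, locus, freq, replicate).

    Generation 0 is the initial population; generation ``g`` is the state
    after ``g`` full life cycles, matching the deterministic recursion's
    bookkeeping.  The trajectory is a deterministic function of the seed.

    Besides the five locus rows, each generation ``g >= 1`` carries a
    ``locus == "mated"`` row: the realized fraction of adult females that
    mated with a conspecific (the stochastic counterpart of the mean
    mating probability ``sum_j f'_j P(j)``).
    """
    params, weights = config.params, config.weights
    rng = np.random.default_rng(config.seed)
    n = config.pop_size

    init = config.init_freqs or {"T1": 0.5, "T2": 0.5, "P1": 0.5, "P2": 0.5}
    f0 = distribution_from_allele_freqs(init)
    genomes = rng.choice(32, size=n, p=f0)

    phi = acceptance_matrix(weights, params)
    phi_het = heterospecific_acceptance_vector(weights, params)
    # per-encounter heterospecific acceptance cri*phi(j,(1,1)); strip the
    # encounter-share prefactor baked into the Tri vector
    het_accept = np.divide(phi_het, params.share_b,
                           out=np.zeros_like(phi_het), where=params.share_b > 0)
    w = (1.0 + ((np.arange(32) >> 4) & 1) * params.s1) \
        * (1.0 + ((np.arange(32) >> 3) & 1) * params.s2)
    w_max = w.max()
    mut_rates = [(SHIFTS[name], u) for name, u in
                 (("T1", params.u_t1), ("T2", params.u_t2),
                  ("P1", params.u_p1), ("P2", params.u_p2)) if u > 0.0]

    records = [{"generation": 0, "locus": name, "freq": p, "replicate": replicate}
               for name, p in _allele_freqs(genomes).items()]

    for gen in range(1, config.generations + 1):
        # viability selection: binomial survival proportional to w
        survive = rng.random(n) < w[genomes] / w_max
        adults = genomes[survive]
        if adults.size == 0:
            raise ExtinctionError(f"no survivors in generation {gen}")

        # sequential mate search, all females advanced one encounter at a time
        females = adults
        active = np.arange(females.size)
        mothers: list[np.ndarray] = []
        fathers: list[np.ndarray] = []
        for _ in range(MAX_ATTEMPTS):
            if active.size == 0:
                break
            k = active.size
            consp = rng.random(k) < params.share_a
            male_idx = rng.integers(0, adults.size, size=k)
            fg = females[active]
            p_accept = np.where(consp, phi[fg, adults[male_idx]],
                                het_accept[fg])
            accepted = rng.random(k) < p_accept
            mated_consp = accepted & consp
            mothers.append(fg[mated_consp])
            fathers.append(adults[male_idx[mated_consp]])
            # heterospecific matings are sterile and terminal (monandry)
            rejected = ~accepted
            if params.c > 0.0:
                retry = rng.random(k) < 1.0 - params.c
            else:
                retry = np.ones(k, dtype=bool)
            active = active[rejected & retry]

        mom = np.concatenate(mothers) if mothers else np.empty(0, dtype=int)
        dad = np.concatenate(fathers) if fathers else np.empty(0, dtype=int)
        if mom.size == 0:
            raise ExtinctionError(f"no reproducing pair in generation {gen}")

        # offspring: uniform resampling of mated pairs, Mendelian inheritance
        pick = rng.integers(0, mom.size, size=n)
        inherit = rng.integers(0, 32, size=n)  # 5 random bits, one per locus
        child = (mom[pick] & inherit) | (dad[pick] & ~inherit & 31)
        for shift, u in mut_rates:
            flips = rng.random(n) < u
            child = np.where(flips, child ^ (1 << shift), child)
        genomes = child

        records.extend({"generation": gen, "locus": name, "freq": p,
                        "replicate": replicate}
                       for name, p in _allele_freqs(genomes).items())
        records.append({"generation": gen, "locus": "mated",
                        "freq": mom.size / females.size,
                        "replicate": replicate})

    return pd.DataFrame.from_records(records)


def simulate_replicates(config: IbmConfig, n_replicates: int) -> pd.DataFrame:
    """Independent replicates seeded ``seed, seed+1, ...``; tidy concatenation."""
    frames = []
    for r in range(n_replicates):
        cfg = dataclasses.replace(config, seed=config.seed + r)
        frames.append(simulate_ibm(cfg, replicate=r))
    return pd.concat(frames, ignore_index=True)


def write_trajectories(df: pd.DataFrame, path) -> None:
    """Write trajectories as TSV (generation, locus, freq, replicate)."""
    df.to_csv(path, sep="\t", index=False)
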