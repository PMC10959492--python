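"""Precomputed index tables for the five-locus genotype space.

Genotypes are encoded as integers with locus order (T1, T2, P1, P2, M),
T1 being the most significant bit: index = 16*t1 + 8*t2 + 4*p1 + 2*p2 + m.
The resident system (allele 0 fixed at the preference-weighting locus M)
lives on the 16-genotype subspace over (T1, T2, P1, P2), encoded with the
same order, T1 most significant: index16 = index32 >> 1.
"""

from __future__ import annotations

import numpy as np

LOCI = ("T1", "T2", "P1", "P2", "M")
N_LOCI = 5
N_GENOTYPES = 32

#: loci of the resident (M = 0) subspace, in encoding order
RESIDENT_LOCI = ("T1", "T2", "P1", "P2")
N_RESIDENT_GENOTYPES = 16

#: bit shift of each locus in the 32-genotype encoding
SHIFTS = {"T1": 4, "T2": 3, "P1": 2, "P2": 1, "M": 0}
#: bit shift of each locus in the 16-genotype (resident) encoding
SHIFTS16 = {"T1": 3, "T2": 2, "P1": 1, "P2": 0}


def _bit_table(n_loci: int) -> np.ndarray:
    """(2**n_loci, n_loci) array of alleles; column 0 is the most significant locus."""
    idx = np.arange(1 << n_loci)
    shifts = np.arange(n_loci - 1, -1, -1)
    return (idx[:, None] >> shifts[None, :]) & 1


#: BITS[i, l] = allele of genotype i at locus l, columns ordered (T1,T2,P1,P2,M)
BITS = _bit_table(N_LOCI)
#: same for the resident subspace, columns (T1,T2,P1,P2)
BITS16 = _bit_table(4)


def _segregation_kernel(n_loci: int) -> np.ndarray:
    """Mendelian segregation kernel for free recombination.

    Returns the kernel flattened to shape (G*G, G) with
    out[j*G + k, i] = beta(i, j, k), the probability that a mother of
    genotype j and a father of genotype k produce an offspring of genotype
    i.  At each locus the offspring inherits the shared allele when the
    parents agree, or either allele with probability 1/2 when they differ.
    """
    bits = _bit_table(n_loci)
    g = 1 << n_loci
    beta = np.ones((g, g, g))  # (i, j, k)
    for locus in range(n_loci):
        ib = bits[:, locus][:, None, None]
        jb = bits[:, locus][None, :, None]
        kb = bits[:, locus][None, None, :]
        term = np.where(jb == kb, (ib == jb).astype(float), 0.5)
        beta *= term
    return np.ascontiguousarray(beta.transpose(1, 2, 0).reshape(g * g, g))


#: beta(i,j,k) over the full 32-genotype space, flattened to (1024, 32)
BETA32 = _segregation_kernel(5)
#: beta over the 16-genotype resident subspace, flattened to (256, 16)
BETA16 = _segregation_kernel(4)

#: index permutations flipping one locus (used by the mutation operator)
FLIP32 = {name: np.arange(N_GENOTYPES) ^ (1 << shift) for name, shift in SHIFTS.items()}
FLIP16 = {name: np.arange(16) ^ (1 << shift) for name, shift in SHIFTS16.items()}


def _relabel_perm(n_loci: int) -> np.ndarray:
    """Index permutation implementing the T1<->T2, P1<->P2 relabeling."""
    bits = _bit_table(n_loci)
    cols = [1, 0, 3, 2] + ([4] if n_loci == 5 else [])
    swapped = bits[:, cols]
    shifts = np.arange(n_loci - 1, -1, -1)
    return (swapped << shifts[None, :]).sum(axis=1)


#: genotype-index permutation for the trait/preference relabeling symmetry
RELABEL32 = _relabel_perm(5)
RELABEL16 = _relabel_perm(4)

#: lift/project between resident (16) and full (32) encodings
LIFT = np.arange(16) * 2          # index32 of each resident genotype (M = 0)
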