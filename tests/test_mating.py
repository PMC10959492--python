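"""Female preference, the mating process, and the offspring recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import matepref as mp
from matepref.core import relabel_distribution
from matepref.mating import acceptance_matrix, mating_stats

from conftest import random_params


class TestAttentionWeights:
    @pytest.mark.parametrize("gamma,a,expected", [
        (0.5, 1.0, (0.5, 0.5)),
        (0.5, 2.0, (0.25, 0.25)),
        (1.0, 0.5, (0.0, 1.0)),   # choice relies on a single trait at the extremes
        (1.0, 3.0, (0.0, 1.0)),
        (0.0, 0.5, (1.0, 0.0)),
    ])
    def test_examples(self, gamma, a, expected):
        assert mp.attention_weights(gamma, a) == pytest.approx(expected)

    def test_a_zero_edge_keeps_f0_zero(self):
        # convention 0**0 = 0 so the extremes stay single-trait
        assert mp.attention_weights(0.0, 0.0) == (1.0, 0.0)
        assert mp.attention_weights(1.0, 0.0) == (0.0, 1.0)
        assert mp.attention_weights(0.3, 0.0) == (1.0, 1.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            mp.attention_weights(1.2, 1.0)


class TestAcceptanceProbability:
    def test_matching_male_always_accepted(self):
        female = mp.Genotype(0, 0, 1, 0, 0)
        w = mp.PreferenceWeights(0.3)
        p = mp.ModelParams(rho=1.0)
        assert mp.acceptance_probability(female, (1, 0), w, p) == 1.0

    def test_double_mismatch_hand_value(self):
        # (1 - 0.01*0.5)^2 with gamma=0.5, a=1, rho=0.01
        female = mp.Genotype(0, 0, 0, 0, 0)
        w = mp.PreferenceWeights(0.5)
        p = mp.ModelParams(rho=0.01, a=1.0)
        assert mp.acceptance_probability(female, (1, 1), w, p) == \
            pytest.approx(0.990025, abs=1e-12)

    def test_ignored_trait_mismatch_is_free(self):
        # all attention on T2: mismatch at T1 does not matter
        female = mp.Genotype(0, 0, 0, 1, 0)
        w = mp.PreferenceWeights(1.0)
        p = mp.ModelParams(rho=0.5, a=0.7)
        assert mp.acceptance_probability(female, (1, 1), w, p) == 1.0

    def test_mutant_female_uses_gamma_m(self):
        female = mp.Genotype(0, 0, 0, 0, 1)  # carries the mutant M allele
        w = mp.PreferenceWeights(gamma_r=0.0, gamma_m=1.0)
        p = mp.ModelParams(rho=0.5, a=1.0)
        # gamma_m = 1: only T2 matters
        assert mp.acceptance_probability(female, (1, 0), w, p) == 1.0
        assert mp.acceptance_probability(female, (0, 1), w, p) == 0.5


class TestRealizedAcceptances:
    def test_random_preference_gives_encounter_share(self, random_simplex):
        p = mp.ModelParams(rho=0.0)
        w = mp.PreferenceWeights(0.4)
        for idx in (0, 13, 31):
            t = mp.conspecific_acceptance(mp.Genotype.from_index(idx),
                                          random_simplex, w, p)
            assert t == pytest.approx(p.share_a)

    def test_all_males_match(self):
        # monomorphic males displaying the female's preferred traits
        f = np.zeros(32)
        f[mp.Genotype(1, 1, 0, 0, 0).index] = 1.0
        female = mp.Genotype(0, 0, 1, 1, 0)
        t = mp.conspecific_acceptance(female, f, mp.PreferenceWeights(0.5),
                                      mp.ModelParams(rho=0.8))
        assert t == pytest.approx(0.5)  # N = Ntilde
        t_alone = mp.conspecific_acceptance(
            female, f, mp.PreferenceWeights(0.5),
            mp.ModelParams(rho=0.8, n_b=0.0))
        assert t_alone == pytest.approx(1.0)

    def test_heterospecific_examples(self):
        pool = mp.HeterospecificPool()
        w = mp.PreferenceWeights(0.5)
        female_00 = mp.Genotype(0, 0, 0, 0, 0)
        assert mp.heterospecific_acceptance(
            female_00, pool, w, mp.ModelParams(cri=0.0)) == 0.0
        # female preferring (0,0): Tri = 0.5 * cri * (1-0.005)^2
        got = mp.heterospecific_acceptance(
            female_00, pool, w, mp.ModelParams(cri=0.0025, rho=0.01, a=1.0))
        assert got == pytest.approx(0.5 * 0.0025 * 0.990025, rel=1e-12)
        # female preferring (1,1) accepts species B males freely
        female_11 = mp.Genotype(0, 0, 1, 1, 0)
        got = mp.heterospecific_acceptance(
            female_11, pool, w, mp.ModelParams(cri=0.0025, rho=0.9))
        assert got == pytest.approx(0.5 * 0.0025, rel=1e-12)

    def test_divergent_preference_reduces_heterospecific_mating(self):
        """Females preferring (0,0) accept heterospecifics strictly less than
        females preferring (1,1) whenever cri > 0 and attention is split."""
        p = mp.ModelParams(cri=0.01, rho=0.5)
        w = mp.PreferenceWeights(0.5)
        pool = mp.HeterospecificPool()
        tri_00 = mp.heterospecific_acceptance(mp.Genotype(0, 0, 0, 0, 0), pool, w, p)
        tri_11 = mp.heterospecific_acceptance(mp.Genotype(0, 0, 1, 1, 0), pool, w, p)
        assert tri_00 < tri_11


class TestMatingProbability:
    def test_single_encounter_limit(self):
        assert mp.conspecific_mating_probability(0.3, 0.2, c=1.0) == \
            pytest.approx(0.3)

    def test_geometric_series_value(self):
        assert mp.conspecific_mating_probability(0.5, 0.25, c=0.0) == \
            pytest.approx(2 / 3)

    def test_degenerate_case(self):
        assert mp.conspecific_mating_probability(0.0, 0.0, c=0.0) == 0.0

    def test_monotonicity(self):
        """P increases with conspecific acceptance, decreases with
        heterospecific acceptance."""
        ts = np.linspace(0.01, 0.6, 25)
        for c in (0.0, 0.1, 0.9):
            p_t = mp.conspecific_mating_probability(ts, 0.2, c)
            assert np.all(np.diff(p_t) >= 0)
            tris = np.linspace(0.0, 0.4, 25)
            p_tri = mp.conspecific_mating_probability(0.5, tris, c)
            assert np.all(np.diff(p_tri) <= 0)

    def test_rejects_invalid_inputs(self):
        with pytest.raises(ValueError):
            mp.conspecific_mating_probability(0.8, 0.4, 0.0)
        with pytest.raises(ValueError):
            mp.conspecific_mating_probability(0.3, 0.1, 1.5)


def brute_force_reproduce(f, weights, params):
    """Literal evaluation of the pair-contribution recursion, independent of
    the vectorised implementation: per-female acceptances by explicit sums,
    pair weights m_jk, mean contribution, and offspring via
    segregation_probability."""
    G = [mp.Genotype.from_index(i) for i in range(32)]
    pool = mp.HeterospecificPool()
    phi = [[mp.acceptance_probability(j, (k.t1, k.t2), weights, params)
            for k in G] for j in G]
    t = [params.share_a * sum(f[k] * phi[j][k] for k in range(32))
         for j in range(32)]
    tri = [mp.heterospecific_acceptance(j, pool, weights, params) for j in G]
    m = np.zeros((32, 32))
    for j in range(32):
        denom = params.c + (1 - params.c) * (t[j] + tri[j])
        pj = t[j] / denom if denom > 0 else 0.0
        norm = sum(f[l] * phi[j][l] for l in range(32))
        for k in range(32):
            m[j, k] = pj * phi[j][k] / norm if norm > 0 else 0.0
    mbar = sum(f[j] * f[k] * m[j, k] for j in range(32) for k in range(32))
    out = np.zeros(32)
    for i in range(32):
        out[i] = sum(f[j] * f[k] * m[j, k] / mbar
                     * mp.segregation_probability(G[i], G[j], G[k])
                     for j in range(32) for k in range(32))
    return out


class TestReproduce:
    def test_monomorphic_population_breeds_true(self):
        f = np.zeros(32)
        f[mp.Genotype(1, 0, 1, 1, 0).index] = 1.0
        out = mp.reproduce(f, None, mp.PreferenceWeights(0.3),
                           mp.ModelParams(rho=0.5, cri=0.01, c=0.1))
        np.testing.assert_allclose(out, f, atol=1e-15)

    def test_random_mating_preserves_allele_frequencies(self, random_simplex):
        p = mp.ModelParams(rho=0.0, cri=0.0)
        out = mp.reproduce(random_simplex, None, mp.PreferenceWeights(0.5), p)
        for locus in ("T1", "T2", "P1", "P2", "M"):
            assert mp.allele_frequency(out, locus) == pytest.approx(
                mp.allele_frequency(random_simplex, locus), abs=1e-13)

    def test_uniform_acceptance_cancels(self, rng):
        """If every female accepts every male alive (preferred trait values
        fixed in the male population), preference has no effect."""
        # polymorphic only at P loci and M; traits fixed at (1,1)
        f = np.zeros(32)
        for p1 in (0, 1):
            for p2 in (0, 1):
                for m in (0, 1):
                    f[mp.Genotype(1, 1, p1, p2, m).index] = rng.random()
        f /= f.sum()
        pref = mp.ModelParams(rho=0.9, cri=0.0)
        rand = mp.ModelParams(rho=0.0, cri=0.0)
        # all females with P=(1,1) would accept everyone; those preferring 0
        # reject uniformly -> identical conditional mate distribution
        w = mp.PreferenceWeights(0.5)
        out_pref = mp.reproduce(f, None, w, pref)
        out_rand = mp.reproduce(f, None, w, rand)
        # with c = 0 and cri = 0 every female still mates: same offspring pool
        np.testing.assert_allclose(out_pref, out_rand, atol=1e-13)

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_recursion(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.dirichlet(np.ones(32))
        params = random_params(rng)
        weights = mp.PreferenceWeights(float(rng.uniform(0, 1)),
                                       float(rng.uniform(0, 1)))
        expected = brute_force_reproduce(f, weights, params)
        got = mp.reproduce(f, None, weights, params)
        np.testing.assert_allclose(got, expected, atol=1e-13)
        assert got.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_reproduce_outputs_simplex(seed):
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.ones(32) * rng.uniform(0.3, 3.0))
    params = random_params(rng)
    w = mp.PreferenceWeights(float(rng.uniform(0, 1)), float(rng.uniform(0, 1)))
    out = mp.reproduce(f, None, w, params)
    assert np.all(out >= -1e-15)
    assert out.sum() == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_reproduce_relabeling_symmetry(seed):
    """The full mating recursion commutes with T1<->T2, P1<->P2 and
    gamma -> 1 - gamma."""
    rng = np.random.default_rng(seed)
    f = rng.dirichlet(np.ones(32))
    params = random_params(rng)
    gr, gm = float(rng.uniform(0, 1)), float(rng.uniform(0, 1))
    direct = relabel_distribution(
        mp.reproduce(f, None, mp.PreferenceWeights(gr, gm), params))
    swapped = mp.reproduce(relabel_distribution(f), None,
                           mp.PreferenceWeights(1 - gr, 1 - gm),
                           params.swap_traits())
    np.testing.assert_allclose(swapped, direct, atol=1e-13)


def test_mating_stats_consistency(random_simplex):
    """mating_stats agrees with the per-female scalar operations."""
    params = mp.ModelParams(rho=0.05, cri=0.003, c=0.01)
    w = mp.PreferenceWeights(0.7)
    stats = mating_stats(random_simplex, w, params)
    assert np.all(stats.t_acc + stats.tri_acc <= 1.0 + 1e-12)
    assert np.all((stats.p_mate >= 0) & (stats.p_mate <= 1))
    pool = mp.HeterospecificPool()
    for idx in (0, 9, 22, 31):
        g = mp.Genotype.from_index(idx)
        assert stats.t_acc[idx] == pytest.approx(
            mp.conspecific_acceptance(g, random_simplex, w, params))
        assert stats.tri_acc[idx] == pytest.approx(
            mp.heterospecific_acceptance(g, pool, w, params))
        assert stats.p_mate[idx] == pytest.approx(
            mp.conspecific_mating_probability(stats.t_acc[idx],
                                              stats.tri_acc[idx], params.c))


def test_acceptance_matrix_matches_scalar():
    params = mp.ModelParams(rho=0.3, a=0.8)
    w = mp.PreferenceWeights(0.2, 0.9)
    phi = acceptance_matrix(w, params)
    for j in (0, 5, 17, 31):
        female = mp.Genotype.from_index(j)
        for k in (0, 12, 24, 31):
            male = mp.Genotype.from_index(k)
            assert phi[j, k] == pytest.approx(mp.acceptance_probability(
                female, (male.t1, male.t2), w, params), rel=1e-14)
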