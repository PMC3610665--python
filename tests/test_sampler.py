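"""Backward sampler: posterior correctness and mirror subtraction."""

import numpy as np
import pytest

import mirrorphase as mp
from mirrorphase.sampler import sample_paths
from conftest import make_view, paired_mate_map, random_instance
from oracles import pair_likelihood_and_posteriors


class TestMirrorAdjust:
    def test_equal_mirror_mass_gives_uniform_floor(self):
        """A pair whose mirror carries the same weight holds no phase
        information: everything collapses to the epsilon floor, i.e. uniform."""
        w = np.array([[0.3, 0.2], [0.2, 0.3]])
        out = mp.mirror_adjust(w, paired_mate_map(2), 1e-10)
        np.testing.assert_allclose(out, 0.25)

    def test_zero_mirror_mass_passes_through(self):
        w = np.array([[0.0, 0.8], [0.2, 0.0]])
        # mirror of (0,1) is (1,0) and vice versa -> subtract the transpose
        out = mp.mirror_adjust(w, paired_mate_map(2), 1e-12)
        expected = np.array([[0.0, 0.6], [0.0, 0.0]])
        expected[0, 0] = expected[1, 1] = 1e-12  # floored diagonal
        np.testing.assert_allclose(out, expected / expected.sum(), atol=1e-11)

    def test_unmated_pairs_unchanged(self):
        w = np.array([[0.4, 0.1], [0.2, 0.3]])
        out = mp.mirror_adjust(w, np.array([-1, -1]), 1e-10)
        np.testing.assert_allclose(out, w / w.sum())

    def test_mated_block_subtraction(self):
        """Elementwise max(w - w_mirror, eps) on a fully mated 2x2 block."""
        w = np.array([[0.4, 0.1], [0.2, 0.3]])
        eps = 1e-10 * w.sum()
        out = mp.mirror_adjust(w, paired_mate_map(2), 1e-10)
        pre = np.array([[0.4 - 0.3, eps], [0.2 - 0.1, eps]])
        np.testing.assert_allclose(out, pre / pre.sum(), rtol=1e-8)

    def test_all_zero_rejected(self):
        with pytest.raises(mp.InputError):
            mp.mirror_adjust(np.zeros((2, 2)), paired_mate_map(2), 1e-10)

    def test_normalized_and_floored(self, rng):
        for _ in range(20):
            k = int(rng.integers(2, 6)) * 2
            w = rng.random((k, k))
            out = mp.mirror_adjust(w, paired_mate_map(k), 1e-10)
            assert out.sum() == pytest.approx(1.0)
            assert np.all(out > 0)  # numerical, never logical, exclusion


class TestBackwardSample:
    def test_degenerate_posterior_returns_unique_pair(self, rng):
        """theta=0, e=0, exactly one consistent template pair."""
        alleles = np.array([[0, 1, 0], [1, 0, 1], [0, 0, 0]], dtype=np.int8)
        g = np.array([1, 1, 1], dtype=np.int8)  # only (0,1)/(1,0) fit
        view = make_view(alleles)
        params = mp.HMMParams(np.zeros(2), 0.0)
        fwd = mp.forward(g, view, params)
        for mode in ("original", "mirror"):
            path = mp.backward_sample(fwd, view, params, mode,
                                      np.random.default_rng(0))
            assert set(map(tuple, path.states)) <= {(0, 1), (1, 0)}
            assert len(set(map(tuple, path.states))) == 1

    def test_marginals_match_posteriors(self, rng):
        """Empirical per-marker state frequencies track the forward-backward
        posterior (total variation < 0.01 at 200k draws)."""
        alleles, g, theta, e = random_instance(rng, k_max=3, m_max=4,
                                               e_choices=(0.02,))
        view = make_view(alleles)
        params = mp.HMMParams(theta, e)
        fwd = mp.forward(g, view, params)
        post = mp.forward_backward_posteriors(fwd, view, params, g)
        paths = sample_paths(fwd, view, params, "original",
                             np.random.default_rng(11), 200_000)
        k = view.K
        for m in range(len(g)):
            emp = np.zeros((k, k))
            np.add.at(emp, (paths[:, m, 0], paths[:, m, 1]), 1.0)
            emp /= emp.sum()
            assert 0.5 * np.abs(emp - post[m]).sum() < 0.01

    def test_mirror_suppresses_copy_pairs(self, rng):
        """Duplicate-individual construction: the adjusted weight of a copy
        pair is at most ~100 epsilon_rel of its unadjusted weight, and the
        sampler essentially never visits copy pairs in mirror mode."""
        m = 10
        h1 = rng.integers(0, 2, m).astype(np.int8)  # target's true haplotypes
        h2 = rng.integers(0, 2, m).astype(np.int8)
        g = (h1 + h2).astype(np.int8)
        # B duplicates the target's genotypes with a random phase resolution
        coin = rng.integers(0, 2, m).astype(np.int8)
        b1 = np.where(coin == 1, h1, h2).astype(np.int8)
        b2 = np.where(coin == 1, h2, h1).astype(np.int8)
        # C shares h1 only, D shares h2 only: single-haplotype sharers whose
        # mirror pairs are genuinely poor matches
        c = np.stack([h1, rng.integers(0, 2, m).astype(np.int8)])
        d = np.stack([h2, rng.integers(0, 2, m).astype(np.int8)])
        alleles = np.vstack([b1[None], b2[None], c, d])
        mate = paired_mate_map(6)
        view = make_view(alleles, mate)
        eps_rel = 1e-10
        params = mp.HMMParams.uniform(m, 0.01, 0.005, epsilon_rel=eps_rel)
        fwd = mp.forward(g, view, params)
        mid = fwd.F[m // 2]
        adjusted = mp.mirror_adjust(mid, mate, eps_rel)
        for pair in ((0, 1), (1, 0)):
            assert mid[pair] > 0.1  # dominates unadjusted
            # only the genuine (tiny) asymmetry between the copy pair and its
            # mirror survives the subtraction
            assert adjusted[pair] / (mid[pair] / mid.sum()) < 1e-6
        paths = sample_paths(fwd, view, params, "mirror",
                             np.random.default_rng(5), 4000)
        copy = (paths[..., 0] < 2) & (paths[..., 1] < 2)
        assert copy.mean() < 0.01

    def test_empty_mate_map_mirror_equals_original(self, rng):
        """With no mates defined, mirror mode is original mode draw-for-draw
        under a shared random stream."""
        alleles, g, theta, e = random_instance(rng, e_choices=(0.01,))
        view = make_view(alleles)  # mate map all -1
        params = mp.HMMParams(theta, e)
        fwd = mp.forward(g, view, params)
        a = sample_paths(fwd, view, params, "original",
                         np.random.default_rng(3), 50)
        b = sample_paths(fwd, view, params, "mirror",
                         np.random.default_rng(3), 50)
        np.testing.assert_array_equal(a, b)

    def test_unknown_mode_rejected(self, rng):
        alleles, g, theta, e = random_instance(rng)
        view = make_view(alleles)
        params = mp.HMMParams(theta, e)
        fwd = mp.forward(g, view, params)
        with pytest.raises(mp.InputError):
            mp.backward_sample(fwd, view, params, "both", rng)


class TestSamplerGoodnessOfFit:
    def test_joint_path_frequencies(self, rng):
        """Original-mode sampling is a correct joint posterior path sampler
        (chi-square on the full path distribution, 200k draws)."""
        from scipy import stats

        alleles = rng.integers(0, 2, (3, 3)).astype(np.int8)
        g = rng.integers(0, 3, 3).astype(np.int8)
        theta = np.array([0.2, 0.35])
        params = mp.HMMParams(theta, 0.05)
        view = make_view(alleles)
        fwd = mp.forward(g, view, params)
        from oracles import pair_path_distribution

        digits, probs = pair_path_distribution(alleles, g, theta, 0.05)
        paths = sample_paths(fwd, view, params, "original",
                             np.random.default_rng(17), 200_000)
        s = view.K * view.K
        codes = (paths[:, :, 0] * view.K + paths[:, :, 1])
        flat = codes[:, 0]
        for m in range(1, 3):
            flat = flat * s + codes[:, m]
        observed = np.bincount(flat, minlength=s ** 3).astype(float)
        keep = probs * len(paths) >= 5  # chi-square validity
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(probs[keep], probs[~keep].sum()) * len(paths)
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p = stats.chi2.sf(chi2, len(obs) - 1)
        assert p > 0.001


class TestHaplotypesFromPath:
    def _path(self, states):
        return mp.StatePath(states=np.asarray(states, dtype=np.int64))

    def test_homozygous_sites_forced(self, rng):
        alleles = np.array([[1, 1, 0], [0, 0, 1]], dtype=np.int8)
        g = np.array([0, 2, 0], dtype=np.int8)
        view = make_view(alleles)
        sh = mp.haplotypes_from_path(self._path([(0, 1)] * 3), view, g, rng)
        np.testing.assert_array_equal(sh.hap1, [0, 1, 0])
        np.testing.assert_array_equal(sh.hap2, [0, 1, 0])
        # templates disagreed with the genotype at (0:1 vs 0), (1:0 vs 1), (2:1 vs 0)
        assert sh.mismatch_count == 3

    def test_consistent_path_copies_templates_exactly(self, rng):
        alleles = np.array([[0, 1, 1, 0], [1, 0, 1, 1]], dtype=np.int8)
        g = (alleles[0] + alleles[1]).astype(np.int8)
        view = make_view(alleles)
        sh = mp.haplotypes_from_path(self._path([(0, 1)] * 4), view, g, rng)
        assert sh.mismatch_count == 0
        np.testing.assert_array_equal(sh.hap1, alleles[0])
        np.testing.assert_array_equal(sh.hap2, alleles[1])

    def test_switch_counting_per_interval(self, rng):
        alleles = np.zeros((3, 4), dtype=np.int8)
        g = np.zeros(4, dtype=np.int8)
        view = make_view(alleles)
        sh = mp.haplotypes_from_path(
            self._path([(0, 2), (0, 2), (1, 2), (1, 2)]), view, g, rng)
        np.testing.assert_array_equal(sh.switch_count_per_interval, [0, 1, 0])

    def test_genotype_consistency_invariant(self, rng):
        for _ in range(20):
            alleles, g, theta, e = random_instance(rng, e_choices=(0.05,))
            view = make_view(alleles)
            params = mp.HMMParams(theta, e)
            fwd = mp.forward(g, view, params)
            path = mp.backward_sample(fwd, view, params, "original", rng)
            sh = mp.haplotypes_from_path(path, view, g, rng)
            typed = g != mp.MISSING
            np.testing.assert_array_equal((sh.hap1 + sh.hap2)[typed], g[typed])
            assert sh.mismatch_count <= 2 * len(g)
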