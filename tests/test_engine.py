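"""The block search: scores, selection steps, residual masking,
convergence and sequential extraction."""

import numpy as np
import pytest
from scipy.stats import pearsonr

from epiblock import (
    EngineConfig,
    HomologyMap,
    LFB,
    MethylationDataset,
    SearchFailure,
    ThresholdPair,
    block_means,
    condition_step,
    homology_similarity,
    jaccard,
    run,
    search_lfb,
    site_step,
    subtract_lfbs,
)
from epiblock.synthetic import planted_dataset, PlantedBlock


def _dataset(p, w=None, site_groups=None, cond_groups=None):
    p = np.asarray(p, dtype=float)
    m, n = p.shape
    sids = tuple(f"s{i}" for i in range(m))
    cids = tuple(f"c{j}" for j in range(n))
    if w is None:
        w = np.full((m, n), 0.5)
    if site_groups is None and cond_groups is None:
        hom = HomologyMap.singleton(sids, cids)
    else:
        hom = HomologyMap(site_groups or {s: frozenset([s]) for s in sids},
                          cond_groups or {c: frozenset([c]) for c in cids})
    return MethylationDataset(p, np.asarray(w, dtype=float), sids, cids, hom)


class TestPrimitives:
    @pytest.mark.parametrize("a, b, expected", [
        ({1, 2, 3}, {1, 2, 3}, 1.0),
        ({1, 2}, {3, 4}, 0.0),
        ({1, 2}, {2, 3}, 1 / 3),
        (set(), set(), 0.0),
        (set(), {1}, 0.0),
    ])
    def test_jaccard(self, a, b, expected):
        assert jaccard(a, b) == pytest.approx(expected)

    def test_block_means(self, tiny_dataset):
        mu_p, mu_w = block_means(tiny_dataset, {"s0", "s1", "s2"},
                                 {"c0", "c1"})
        assert mu_p == pytest.approx(0.9)
        full_p, full_w = block_means(tiny_dataset, tiny_dataset.site_ids,
                                     tiny_dataset.condition_ids)
        assert full_p == pytest.approx(tiny_dataset.p_t.mean())
        assert full_w == pytest.approx(tiny_dataset.w_t.mean())
        ds = _dataset([[0.2, 0.4], [0.6, 0.8]])
        assert block_means(ds, {"s0", "s1"}, {"c0", "c1"})[0] == \
            pytest.approx(0.5)
        with pytest.raises(ValueError):
            block_means(ds, set(), {"c0"})

    def test_homology_similarity(self):
        profiles = np.array([[1.0, 2, 3], [3.0, 6, 11]])
        # singleton: perfect self-correlation
        assert homology_similarity(profiles, 0, np.array([0])) == \
            pytest.approx(1.0)
        # group mean of rows 0 and 1 is (2, 4, 7); oracle = scipy pearson
        expected = abs(pearsonr([1, 2, 3], [2, 4, 7]).statistic)
        got = homology_similarity(profiles, 0, np.array([0, 1]))
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.9933992678, abs=1e-9)
        # perfect anti-correlation scores 1 in absolute value
        anti = np.array([[1.0, 2, 3], [-3.0, -6, -9.0]])
        assert homology_similarity(anti, 0, np.array([1])) == \
            pytest.approx(1.0)
        # zero variance or too-short profiles: no homologous evidence
        assert homology_similarity(np.array([[1.0, 1, 1], [1, 2, 3]]),
                                   0, np.array([0, 1])) == 0.0
        assert homology_similarity(np.array([[1.0], [2.0]]),
                                   0, np.array([0, 1])) == 0.0


class TestResiduals:
    def test_empty_found_is_identity(self, tiny_dataset):
        state = subtract_lfbs(tiny_dataset, [])
        np.testing.assert_array_equal(state.p_resid, tiny_dataset.p_t)
        np.testing.assert_array_equal(state.w_resid, tiny_dataset.w_t)

    def test_whole_matrix_lfb_centers_everything(self, tiny_dataset):
        mu_p, mu_w = block_means(tiny_dataset, tiny_dataset.site_ids,
                                 tiny_dataset.condition_ids)
        lfb = LFB(frozenset(tiny_dataset.site_ids),
                  frozenset(tiny_dataset.condition_ids),
                  mu_p, mu_w, 1, True, (1.0,))
        state = subtract_lfbs(tiny_dataset, [lfb])
        np.testing.assert_allclose(state.p_resid,
                                   tiny_dataset.p_t - mu_p, atol=1e-15)

    def test_residual_block_mean_is_zero(self, tiny_dataset):
        """After masking a block, the residual mean over that block
        vanishes to numerical precision."""
        sites = {"s0", "s1", "s2"}
        conds = {"c0", "c1"}
        mu_p, mu_w = block_means(tiny_dataset, sites, conds)
        lfb = LFB(frozenset(sites), frozenset(conds), mu_p, mu_w,
                  1, True, (1.0,))
        state = subtract_lfbs(tiny_dataset, [lfb])
        rows = [int(s[1:]) for s in sites]
        cols = [int(c[1:]) for c in conds]
        assert abs(state.p_resid[np.ix_(rows, cols)].mean()) < 1e-12
        assert abs(state.w_resid[np.ix_(rows, cols)].mean()) < 1e-12

    def test_row_col_norms_span_unit(self, tiny_dataset):
        state = subtract_lfbs(tiny_dataset, [])
        np.testing.assert_allclose(state.p_row_norm.min(axis=1), 0,
                                   atol=1e-15)
        np.testing.assert_allclose(state.p_row_norm.max(axis=1), 1,
                                   atol=1e-15)
        np.testing.assert_allclose(state.p_col_norm.min(axis=0), 0,
                                   atol=1e-15)


class TestSelectionSteps:
    def _state_for(self, ds, p_row_norm=None, p_col_norm=None,
                   w_resid=None):
        state = subtract_lfbs(ds, [])
        if p_row_norm is not None:
            state.p_row_norm = np.asarray(p_row_norm, dtype=float)
        if p_col_norm is not None:
            state.p_col_norm = np.asarray(p_col_norm, dtype=float)
        if w_resid is not None:
            state.w_resid = np.asarray(w_resid, dtype=float)
        return state

    def test_condition_step_sigma_rule(self):
        """Brute-force check: combined scores (1, 1, .2, .2, .2, .2) with
        T_C = 1 keep exactly the two outliers above one population sigma."""
        rng = np.random.default_rng(0)
        ds = _dataset(rng.uniform(0.1, 0.9, (4, 6)),
                      w=np.ones((4, 6)))
        prow = np.tile([1.0, 1.0, 0.2, 0.2, 0.2, 0.2], (4, 1))
        state = self._state_for(ds, p_row_norm=prow,
                                w_resid=np.ones((4, 6)))
        state.current_sites = set(ds.site_ids)
        cfg = EngineConfig(deviation_mode="absolute")
        scores, kept = condition_step(state, ds, ThresholdPair(1.0, 1.0),
                                      cfg)
        combined = np.array([scores.combined[c] for c in ds.condition_ids])
        np.testing.assert_allclose(combined,
                                   [1, 1, 0.2, 0.2, 0.2, 0.2], atol=1e-12)
        # mean 0.4667, sigma 0.37712: only the deviations 0.5333 exceed it
        assert scores.threshold_value == pytest.approx(0.3771236166,
                                                       abs=1e-9)
        assert kept == {"c0", "c1"}

    def test_uniform_scores_select_nothing(self):
        ds = _dataset(np.tile(np.linspace(0.1, 0.9, 5)[:, None], (1, 4)),
                      w=np.ones((5, 4)))
        state = self._state_for(ds, p_row_norm=np.full((5, 4), 0.7),
                                w_resid=np.ones((5, 4)))
        state.current_sites = set(ds.site_ids)
        _, kept = condition_step(state, ds, ThresholdPair(1.0, 1.0),
                                 EngineConfig())
        assert kept == set()

    def test_signed_zero_threshold_is_mean_cut(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng.uniform(0.1, 0.9, (4, 6)), w=np.ones((4, 6)))
        prow = np.tile([0.9, 0.5, 0.4, 0.3, 0.2, 0.1], (4, 1))
        state = self._state_for(ds, p_row_norm=prow,
                                w_resid=np.ones((4, 6)))
        state.current_sites = set(ds.site_ids)
        cfg = EngineConfig(deviation_mode="signed")
        scores, kept = condition_step(state, ds, ThresholdPair(0.0, 0.0),
                                      cfg)
        combined = {c: scores.combined[c] for c in ds.condition_ids}
        mean = np.mean(list(combined.values()))
        assert kept == {c for c, v in combined.items() if v > mean}

    def test_site_step_recovers_planted_rows(self):
        """3x2 high block in an 8x4 matrix: the site step at T_R = 1
        keeps exactly the planted sites (brute-force verified).  With
        exactly half the rows planted the deviations equal sigma and the
        strict inequality keeps nothing, so the planted minority must be
        a proper minority."""
        p = np.full((8, 4), 0.1)
        p[:3, :2] = 0.9
        ds = _dataset(p, w=np.ones((8, 4)))
        state = subtract_lfbs(ds, [])
        state.current_conditions = {"c0", "c1"}
        cfg = EngineConfig(deviation_mode="absolute",
                           homology_weighting=False)
        scores, kept = site_step(state, ds, ThresholdPair(1.0, 1.0), cfg)
        e = np.array([scores.e_scores[s] for s in ds.site_ids])
        # brute force: e_u = mean over V' of w * col-min-max residual
        expected_e = state.p_col_norm[:, :2].mean(axis=1)
        np.testing.assert_allclose(e, expected_e, atol=1e-12)
        dev = np.abs(e - e.mean())
        assert kept == {ds.site_ids[i] for i in range(8)
                        if dev[i] > e.std()}
        assert kept == {"s0", "s1", "s2"}

    def test_transpose_symmetry(self):
        """site_step on the transposed problem equals condition_step."""
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, (6, 5))
        w = rng.uniform(0.3, 0.7, (6, 5))
        ds = _dataset(p, w)
        state = subtract_lfbs(ds, [])
        state.current_sites = {"s0", "s2", "s4"}
        cfg = EngineConfig(deviation_mode="signed")
        sc_c, kept_c = condition_step(state, ds, ThresholdPair(0.7, 0.7),
                                      cfg)
        # transpose everything; site ids of the transposed problem are
        # the condition ids of the original
        cids = tuple(f"s{j}" for j in range(5))
        sids_t = tuple(f"c{i}" for i in range(6))
        ds_t = MethylationDataset(p.T, w.T, cids, sids_t,
                                  HomologyMap.singleton(cids, sids_t))
        # rename: original conditions c0..c4 -> transposed sites s0..s4
        state_t = subtract_lfbs(ds_t, [])
        state_t.current_conditions = {"c0", "c2", "c4"}
        sc_s, kept_s = site_step(state_t, ds_t, ThresholdPair(0.7, 0.7),
                                 cfg)
        got = {f"c{int(s[1:])}" for s in kept_s}
        assert got == kept_c
        for j in range(5):
            assert sc_s.combined[f"s{j}"] == pytest.approx(
                sc_c.combined[f"c{j}"], rel=1e-12)

    def test_homology_weighting_off_gives_unit_t(self, tiny_dataset):
        state = subtract_lfbs(tiny_dataset, [])
        state.current_sites = set(tiny_dataset.site_ids)
        cfg = EngineConfig(homology_weighting=False)
        scores, _ = condition_step(state, tiny_dataset,
                                   ThresholdPair(1, 1), cfg)
        assert all(v == 1.0 for v in scores.t_scores.values())

    def test_t_scores_bounded(self, tiny_dataset):
        state = subtract_lfbs(tiny_dataset, [])
        state.current_sites = set(tiny_dataset.site_ids)
        scores, _ = condition_step(state, tiny_dataset,
                                   ThresholdPair(1, 1), EngineConfig())
        assert all(0 <= v <= 1 for v in scores.t_scores.values())


class TestSearch:
    def test_planted_block_recovered_exactly(self):
        ds, truth = planted_dataset(n_sites=120, n_conditions=12,
                                    blocks=[PlantedBlock(
                                        frozenset(range(20)),
                                        frozenset(range(4)))],
                                    seed=3)
        out = search_lfb(ds, [], ThresholdPair(1, 1), EngineConfig(seed=5))
        assert isinstance(out, LFB)
        ts, tc = truth.block_ids(0)
        assert out.sites == ts
        assert out.conditions == tc
        assert out.converged
        assert out.mu_p == pytest.approx(0.9, abs=1e-9)

    def test_determinism(self):
        ds, _ = planted_dataset(n_sites=100, n_conditions=10,
                                noise_sd=0.05, seed=8)
        a = run(ds, ThresholdPair(1, 1), EngineConfig(seed=13))
        b = run(ds, ThresholdPair(1, 1), EngineConfig(seed=13))
        assert [x.to_dict() for x in a] == [y.to_dict() for y in b]

    def test_loose_epsilon_converges_quickly(self):
        ds, _ = planted_dataset(n_sites=120, n_conditions=12,
                                blocks=[PlantedBlock(frozenset(range(20)),
                                                     frozenset(range(4)))],
                                seed=3)
        out = search_lfb(ds, [], ThresholdPair(1, 1),
                         EngineConfig(seed=5, epsilon=1e-6))
        assert isinstance(out, LFB)
        assert out.iterations_used <= 2

    def test_two_disjoint_blocks_found_then_stop(self):
        blocks = [PlantedBlock(frozenset(range(30)), frozenset(range(4))),
                  PlantedBlock(frozenset(range(100, 140)),
                               frozenset(range(10, 15)))]
        ds, truth = planted_dataset(n_sites=200, n_conditions=20,
                                    blocks=blocks, seed=0)
        lfbs = run(ds, ThresholdPair(1, 1), EngineConfig(seed=1))
        assert len(lfbs) == 2
        found = {(b.sites, b.conditions) for b in lfbs}
        assert found == {truth.block_ids(0), truth.block_ids(1)}

    def test_max_lfbs_cap(self):
        blocks = [PlantedBlock(frozenset(range(30)), frozenset(range(4))),
                  PlantedBlock(frozenset(range(100, 140)),
                               frozenset(range(10, 15)))]
        ds, _ = planted_dataset(n_sites=200, n_conditions=20,
                                blocks=blocks, seed=0)
        lfbs = run(ds, ThresholdPair(1, 1),
                   EngineConfig(seed=1, max_lfbs=1))
        assert len(lfbs) == 1

    def test_pure_noise_strict_thresholds_find_nothing(self):
        rng = np.random.default_rng(0)
        for seed in range(3):
            p = np.clip(np.random.default_rng(seed).normal(
                0.3, 0.05, (150, 15)), 0, 1)
            w = rng.uniform(0.4, 0.6, (150, 15))
            ds = _dataset(p, w)
            lfbs = run(ds, ThresholdPair(3, 3), EngineConfig(seed=seed))
            assert lfbs == []

    def test_failure_is_typed_not_raised(self):
        ds = _dataset(np.full((10, 5), 0.5)
                      + np.random.default_rng(0).normal(0, 1e-3, (10, 5)))
        out = search_lfb(ds, [], ThresholdPair(5, 5), EngineConfig(seed=0))
        assert isinstance(out, SearchFailure)
        assert out.reason
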