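"""Group-level inference: t maps, the inverted-U contrast, FDR, clusters,
span correlations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from midbrainfc import (
    CohortDesign,
    ConnectivityMap,
    ContrastSpec,
    ThresholdSpec,
    VoxelSet,
    assign_span_groups,
    bh_fdr,
    cluster_filter,
    compare_correlations,
    correlate_with_span,
    interaction_contrast_map,
    one_sample_t_map,
    small_volume_threshold,
)
from midbrainfc.group_stats import StatMap


def zmap(z, **labels):
    z = np.asarray(z, dtype=float)
    return ConnectivityMap(z=z, valid=np.ones(z.shape, bool), **labels)


def four_by_four_design():
    ids = tuple(f"sub-{i:02d}" for i in range(1, 9))
    scores = {s: (2.0 if i < 4 else 4.0) for i, s in enumerate(ids)}
    sessions = {s: {"ses-1": "placebo", "ses-2": "bromocriptine"} for s in ids}
    return CohortDesign(subject_ids=ids, span_scores=scores, drug_by_session=sessions)


def maps_with_cell_values(design, values, shape=(2, 2, 1), noise=0.0, rng=None):
    """One constant map per subject-session, set to the value of its design cell."""
    from midbrainfc import cell_index

    maps = []
    for sid, session, drug in design.iter_runs():
        c = cell_index(design.span_group(sid), drug)
        z = np.full(shape, float(values[c]))
        if noise and rng is not None:
            z = z + noise * rng.normal(size=shape)
        maps.append(zmap(z, subject_id=sid, session=session, drug=drug))
    return maps


class TestOneSampleTMap:
    def test_identical_constant_maps_marked_degenerate(self):
        maps = [zmap(np.full((2, 2, 1), 0.4), subject_id=f"s{i}") for i in range(5)]
        out = one_sample_t_map(maps)
        assert not out.valid.any()

    def test_matches_scipy_ttest(self, rng):
        maps = [zmap(rng.normal(size=(3, 3, 2)), subject_id=f"s{i}") for i in range(12)]
        out = one_sample_t_map(maps)
        z = np.stack([m.z for m in maps])
        ref = stats.ttest_1samp(z, 0.0, axis=0)
        assert np.allclose(out.stat[out.valid], ref.statistic[out.valid], atol=1e-10)
        assert np.allclose(out.p[out.valid], ref.pvalue[out.valid], atol=1e-12)
        assert out.df == 11

    def test_planted_signal_peaks_at_planted_voxels(self, rng):
        base = np.zeros((4, 4, 2))
        base[1, 1, 0] = base[2, 2, 1] = 2.0
        maps = [zmap(base + 0.05 * rng.normal(size=base.shape), subject_id=f"s{i}")
                for i in range(10)]
        out = one_sample_t_map(maps)
        top2 = np.argsort(out.stat.ravel())[-2:]
        assert set(top2) == {np.ravel_multi_index((1, 1, 0), base.shape),
                             np.ravel_multi_index((2, 2, 1), base.shape)}

    def test_null_rejection_rate_within_binomial_ci(self, rng):
        n_vox, m = 5000, 32
        maps = [zmap(rng.normal(size=(n_vox, 1, 1)), subject_id=f"s{i}")
                for i in range(m)]
        out = one_sample_t_map(maps)
        rate = float((out.p[out.valid] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_vox)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_fewer_than_three_maps_raises(self, rng):
        maps = [zmap(rng.normal(size=(2, 2, 1)), subject_id=f"s{i}") for i in range(2)]
        with pytest.raises(ValueError, match="at least 3"):
            one_sample_t_map(maps)


class TestInteractionContrast:
    def test_equal_cells_give_zero_estimate(self, rng):
        design = four_by_four_design()
        maps = maps_with_cell_values(design, [0.4] * 4, noise=0.01, rng=rng)
        out = interaction_contrast_map(maps, design)
        assert np.allclose(out.effect, 0.0, atol=0.05)

    def test_cell_mean_contrast_estimate(self):
        design = four_by_four_design()
        maps = maps_with_cell_values(design, [0.2, 0.5, 0.5, 0.2])
        out = interaction_contrast_map(maps, design)
        assert np.allclose(out.effect, 0.3, atol=1e-12)

    def test_matches_paired_difference_loop_oracle(self, rng):
        """t equals an explicit-loop two-sample t on per-subject session differences."""
        design = four_by_four_design()
        maps = maps_with_cell_values(design, [0.1, 0.5, 0.5, 0.1], shape=(4, 4, 2),
                                     noise=0.3, rng=rng)
        out = interaction_contrast_map(maps, design)
        by_subj = {}
        for m in maps:
            by_subj.setdefault(m.subject_id, {})[m.drug] = m.z
        for idx in np.ndindex(4, 4, 2):
            d_low, d_high = [], []
            for sid in design.subject_ids:
                d = by_subj[sid]["bromocriptine"][idx] - by_subj[sid]["placebo"][idx]
                (d_low if design.span_group(sid) == "low" else d_high).append(d)
            t_ref = stats.ttest_ind(d_low, d_high, equal_var=True).statistic
            assert out.stat[idx] == pytest.approx(t_ref, abs=1e-10)
        assert out.df == len(design.subject_ids) - 2

    def test_positive_sign_means_inverted_u(self):
        design = four_by_four_design()
        maps = maps_with_cell_values(design, [0.1, 0.5, 0.5, 0.1], noise=0.05,
                                     rng=np.random.default_rng(0))
        out = interaction_contrast_map(maps, design)
        assert np.all(out.stat[out.valid] > 0)

    def test_missing_session_raises_with_subject_name(self):
        design = four_by_four_design()
        maps = maps_with_cell_values(design, [0.1, 0.5, 0.5, 0.1])
        maps = [m for m in maps if not (m.subject_id == "sub-03" and m.drug == "placebo")]
        with pytest.raises(ValueError, match="sub-03"):
            interaction_contrast_map(maps, design)

    def test_small_span_group_raises(self):
        ids = ("a", "b", "c")
        design = CohortDesign(
            subject_ids=ids,
            span_scores={"a": 2.0, "b": 4.0, "c": 4.5},
            drug_by_session={s: {"ses-1": "placebo", "ses-2": "bromocriptine"}
                             for s in ids})
        maps = maps_with_cell_values(design, [0.1, 0.5, 0.5, 0.1])
        with pytest.raises(ValueError, match="fewer than 2"):
            interaction_contrast_map(maps, design)

    def test_null_type1_rate_within_binomial_ci(self, rng):
        design = four_by_four_design()
        n_vox = 2000
        maps = maps_with_cell_values(design, [0.0] * 4, shape=(n_vox, 1, 1),
                                     noise=1.0, rng=rng)
        out = interaction_contrast_map(maps, design)
        rate = float((out.p[out.valid] < 0.05).mean())
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_vox)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_contrast_weights_must_sum_to_zero(self):
        with pytest.raises(ValueError, match="sum to 0"):
            ContrastSpec(weights=(0.5, 0.5, 0.5, -0.5))


class TestBhFdr:
    def test_step_up_by_hand(self):
        rejected, threshold = bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert sorted(rejected) == [0, 1, 2, 3]
        assert threshold == 0.04

    def test_all_ones_rejects_nothing(self):
        rejected, threshold = bh_fdr([1.0, 1.0, 1.0], q=0.05)
        assert rejected.size == 0 and threshold is None

    def test_matches_exhaustive_enumeration(self, rng):
        """Exhaustive step-up: largest k whose k-th smallest p <= k q / m."""
        for _ in range(200):
            m = rng.integers(1, 11)
            p = np.round(rng.uniform(size=m), 3)
            rejected, _ = bh_fdr(p, q=0.1)
            sorted_p = np.sort(p)
            best_k = 0
            for k in range(1, m + 1):
                if sorted_p[k - 1] <= k * 0.1 / m:
                    best_k = k
            expected = set(np.flatnonzero(p <= sorted_p[best_k - 1])) if best_k else set()
            assert set(rejected) == expected

    def test_matches_statsmodels(self, rng):
        multipletests = pytest.importorskip("statsmodels.stats.multitest").multipletests
        p = rng.uniform(size=500) ** 2
        rejected, _ = bh_fdr(p, q=0.05)
        ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        mask = np.zeros(p.size, bool)
        mask[rejected] = True
        assert np.array_equal(mask, ref)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30), st.integers(0, 1000))
    def test_invariant_under_permutation(self, p, perm_seed):
        p = np.asarray(p)
        perm = np.random.default_rng(perm_seed).permutation(p.size)
        r1, t1 = bh_fdr(p, q=0.05)
        r2, t2 = bh_fdr(p[perm], q=0.05)
        assert t1 == t2
        assert np.array_equal(np.sort(perm[r2]), np.sort(r1))

    def test_fdr_controlled_under_global_null(self, rng):
        """False-discovery proportion averages at most q for uniform p-values."""
        fdp = []
        for _ in range(400):
            p = rng.uniform(size=100)
            rejected, _ = bh_fdr(p, q=0.05)
            fdp.append(1.0 if rejected.size else 0.0)
        assert np.mean(fdp) <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 400)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError, match="at least one"):
            bh_fdr([], q=0.05)


class TestSmallVolumeThreshold:
    @staticmethod
    def _stat_map(p, valid=None):
        p = np.asarray(p, dtype=float)
        valid = np.ones(p.shape, bool) if valid is None else valid
        return StatMap(stat=np.where(p < 1, 1.0, 0.0), p=p, df=10, valid=valid)

    def test_no_subthreshold_voxels_gives_empty_set(self):
        sm = self._stat_map(np.full((4, 4, 2), 0.9))
        out = small_volume_threshold(sm, ThresholdSpec(q=0.05, min_cluster=1))
        assert len(out) == 0

    def test_small_volume_restriction_rejects_superset_on_mask(self, rng):
        """BH with fewer (large) competitors rejects at least as much on the mask."""
        p = rng.uniform(0.5, 1.0, size=(6, 6, 2))
        mask = np.zeros((6, 6, 2), bool)
        mask[:3] = True
        p[mask] = rng.uniform(0.0, 0.2, size=int(mask.sum()))
        sm = self._stat_map(p)
        whole = small_volume_threshold(sm, ThresholdSpec(q=0.2, min_cluster=1))
        restricted = small_volume_threshold(
            sm, ThresholdSpec(q=0.2, min_cluster=1, small_volume_mask=mask))
        whole_on_mask = {tuple(v) for v in whole.voxels} & {tuple(np.argwhere(mask)[i])
                                                            for i in range(int(mask.sum()))}
        assert whole_on_mask <= {tuple(v) for v in restricted.voxels}

    def test_planted_cluster_recovered_and_stragglers_removed(self, rng):
        p = rng.uniform(0.3, 1.0, size=(8, 8, 4))
        p[1:6, 1:6, 1] = 1e-6  # 25-voxel planted cluster
        p[7, 7, 3] = 1e-6      # isolated false positive
        sm = self._stat_map(p)
        out = small_volume_threshold(sm, ThresholdSpec(q=0.05, min_cluster=20))
        mask = out.to_mask()
        assert mask[1:6, 1:6, 1].all()
        assert not mask[7, 7, 3]

    def test_disjoint_mask_raises(self):
        sm = self._stat_map(np.full((2, 2, 2), 0.5),
                            valid=np.zeros((2, 2, 2), bool))
        with pytest.raises(ValueError, match="disjoint|no valid"):
            small_volume_threshold(sm, ThresholdSpec(q=0.05))


class TestClusterFilter:
    def test_isolated_voxel_removed(self):
        vs = VoxelSet(voxels=[[3, 3, 3]], shape=(8, 8, 8))
        assert len(cluster_filter(vs, min_cluster=20)) == 0

    def test_solid_block_kept(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:5, 2:5, 2:5] = True
        vs = VoxelSet.from_mask(mask)
        out = cluster_filter(vs, min_cluster=20, connectivity=6)
        assert len(out) == 27

    def test_corner_sharing_voxels_by_connectivity(self):
        vs = VoxelSet(voxels=[[1, 1, 1], [2, 2, 2]], shape=(4, 4, 4))
        assert len(cluster_filter(vs, min_cluster=2, connectivity=6)) == 0
        assert len(cluster_filter(vs, min_cluster=2, connectivity=26)) == 2

    def test_unknown_connectivity_raises(self):
        vs = VoxelSet(voxels=[[1, 1, 1]], shape=(4, 4, 4))
        with pytest.raises(ValueError, match="connectivity"):
            cluster_filter(vs, min_cluster=2, connectivity=10)


class TestCorrelateWithSpan:
    def test_perfect_correlation_hits_machine_floor(self):
        scores = [1.0, 2.0, 3.0, 4.0, 5.0]
        r, p, n = correlate_with_span(scores, scores)
        assert r == pytest.approx(1.0)
        assert p == 0.0
        assert n == 5

    def test_r_066_n_16(self):
        """Frozen t/df oracle: t = 3.287, two-tailed p = 0.0054."""
        rng = np.random.default_rng(0)
        # construct vectors with an exact sample correlation of 0.66
        x = rng.normal(size=16)
        e = rng.normal(size=16)
        xs = (x - x.mean()) / x.std()
        es = e - e.mean()
        es -= (es @ xs) / (xs @ xs) * xs
        es /= es.std()
        target = 0.66
        y = target * xs + np.sqrt(1 - target ** 2) * es
        r, p, n = correlate_with_span(y, xs)
        assert r == pytest.approx(0.66, abs=1e-12)
        t = r * np.sqrt(14) / np.sqrt(1 - r * r)
        assert t == pytest.approx(3.287, abs=1e-3)
        assert p == pytest.approx(0.0054, abs=5e-5)

    def test_null_p_values_uniform(self, rng):
        scores = rng.normal(size=16)
        n_reps = 10_000
        values = rng.normal(size=(n_reps, 16))
        ps = np.array([correlate_with_span(v, scores)[1] for v in values])
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.03

    def test_constant_scores_raise(self):
        with pytest.raises(ValueError, match="constant"):
            correlate_with_span([1.0, 2.0, 3.0, 4.0], [2.0] * 4)


class TestCompareCorrelations:
    def test_equal_correlations_give_zero(self):
        z, p = compare_correlations(0.4, 20, 0.4, 30)
        assert z == 0.0 and p == 1.0

    def test_placebo_vs_drug_example(self):
        z, _ = compare_correlations(0.66, 16, -0.69, 16)
        assert z == pytest.approx(4.183, abs=1e-3)

    def test_half_vs_zero_example(self):
        z, _ = compare_correlations(0.5, 19, 0.0, 19)
        assert z == pytest.approx(1.554, abs=1e-3)

    def test_small_n_raises(self):
        with pytest.raises(ValueError, match="n > 3"):
            compare_correlations(0.5, 3, 0.2, 20)


class TestAssignSpanGroups:
    def test_cutoff_is_inclusive(self):
        assert assign_span_groups([3.5])[0] == "high"
        assert assign_span_groups([3.49])[0] == "low"

    def test_median_split_eight_eight(self):
        scores = [2.0, 2.5, 3.0, 3.4, 1.5, 2.2, 3.1, 2.8,
                  3.5, 4.0, 4.5, 5.0, 3.6, 3.9, 4.2, 5.5]
        groups = assign_span_groups(scores)
        assert groups.count("high") == 8 and groups.count("low") == 8
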