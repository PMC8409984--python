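import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regatlas.exprio import GeneList, RegionProfile, average_replicates
from regatlas.frequency import (
    FrequencyTable,
    bky_adjust,
    frequency_table,
    list_summary,
    pairwise_region_tests,
    peak_region,
    top_contributors,
)
from regatlas.synthetic import AtlasConfig, ListSpec, generate_atlas, generate_gene_lists


def _profile(values, gene_ids, regions):
    return RegionProfile(np.asarray(values, float), gene_ids, regions)


class TestFrequencyTable:
    def test_simple_percentages(self):
        prof = _profile([[10, 30, 60]], ["g1"], ["A", "B", "C"])
        freq = frequency_table(prof)
        np.testing.assert_allclose(freq.values.loc["g1"], [10.0, 30.0, 60.0])

    def test_single_region_gene(self):
        prof = _profile([[0, 7, 0]], ["g1"], ["A", "B", "C"])
        freq = frequency_table(prof)
        np.testing.assert_allclose(freq.values.loc["g1"], [0.0, 100.0, 0.0])

    def test_uniform_gene(self):
        prof = _profile([[4, 4, 4, 4]], ["g1"], list("ABCD"))
        freq = frequency_table(prof)
        np.testing.assert_allclose(freq.values.loc["g1"], [25.0] * 4)

    def test_zero_total_gene_dropped_and_reported(self):
        prof = _profile([[1, 1], [0, 0]], ["g1", "gz"], ["A", "B"])
        freq = frequency_table(prof)
        assert "gz" not in freq.values.index
        assert freq.dropped_zero_total == ("gz",)

    def test_empty_include_rejected(self):
        prof = _profile([[1, 1]], ["g1"], ["A", "B"])
        with pytest.raises(ValueError, match="non-empty"):
            frequency_table(prof, include=[])

    def test_rows_sum_to_100(self, default_profile):
        freq = frequency_table(default_profile)
        np.testing.assert_allclose(freq.values.sum(axis=1), 100.0, atol=1e-9)

    def test_global_scale_covariance(self, default_profile):
        # multiplying ALL columns by one constant leaves the table unchanged
        scaled = RegionProfile(
            default_profile.values * 3.7,
            default_profile.gene_ids,
            default_profile.regions,
        )
        a = frequency_table(default_profile).values
        b = frequency_table(scaled).values
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


class TestListSummary:
    def test_single_gene_list_sem_zero(self):
        prof = _profile([[20, 80]], ["g1"], ["A", "B"])
        freq = frequency_table(prof)
        summ = list_summary(freq, GeneList("l", "c", ("g1",)))
        np.testing.assert_allclose(summ.table["mean"], [20.0, 80.0])
        assert (summ.table["sem"] == 0).all()
        assert summ.sem_convention_applied

    def test_two_gene_mean_and_sem(self):
        prof = _profile([[10, 90], [30, 70]], ["g1", "g2"], ["A", "B"])
        freq = frequency_table(prof)
        summ = list_summary(freq, GeneList("l", "c", ("g1", "g2")))
        assert summ.table.loc["A", "mean"] == pytest.approx(20.0)
        # SEM = sample SD / sqrt(n) = (sd of 10,30)/sqrt(2) = 10
        assert summ.table.loc["A", "sem"] == pytest.approx(10.0)

    def test_means_recombine_to_100(self, default_profile):
        freq = frequency_table(default_profile)
        gl = GeneList("l", "c", tuple(freq.gene_ids[:25]))
        summ = list_summary(freq, gl)
        assert summ.table["mean"].sum() == pytest.approx(100.0, abs=1e-9)
        assert summ.table["mean"].between(0, 100).all()

    def test_no_retained_genes_is_error(self, default_profile):
        freq = frequency_table(default_profile)
        with pytest.raises(ValueError, match="no genes"):
            list_summary(freq, GeneList("l", "c", ("nope",)))

    def test_planted_list_peaks_in_target_group(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = AtlasConfig(noise_sd=0.1, seed=seed)
            matrix, truth = generate_atlas(cfg)
            (gl,) = generate_gene_lists(
                truth, [ListSpec("L", 20, "reward", strength=1.0)], seed=seed
            )
            prof = average_replicates(matrix)
            freq = frequency_table(prof)
            summ = list_summary(freq, gl)
            top_region = summ.table["mean"].idxmax()
            hits += truth.region_groups[top_region] == "reward"
        assert hits >= 0.95 * n_seeds


class TestTopContributors:
    def test_full_list_order_and_other_zero(self):
        prof = _profile([[50], [30], [20]], ["a", "b", "c"], ["A"])
        freq = frequency_table(prof)
        # single-region profile: every gene is 100% in A; use raw values via
        # a two-region layout instead
        prof = _profile([[50, 50], [30, 70], [20, 80]], ["a", "b", "c"], ["A", "B"])
        freq = frequency_table(prof)
        out = top_contributors(freq, GeneList("l", "c", ("a", "b", "c")), "A", k=3)
        assert [g for g, _ in out] == ["a", "b", "c", "other"]
        assert out[-1][1] == 0.0

    def test_k_clamped_to_list_size(self):
        prof = _profile([[10, 90], [60, 40]], ["a", "b"], ["A", "B"])
        freq = frequency_table(prof)
        out = top_contributors(freq, GeneList("l", "c", ("a", "b")), "A", k=10)
        assert len(out) == 3  # both genes + "other"

    def test_ties_break_lexicographically(self):
        prof = _profile([[30, 70], [30, 70], [40, 60]], ["b", "a", "c"], ["A", "B"])
        freq = frequency_table(prof)
        out = top_contributors(freq, GeneList("l", "c", ("a", "b", "c")), "A", k=2)
        assert [g for g, _ in out[:2]] == ["c", "a"]

    def test_conservation_over_random_fixtures(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            values = rng.gamma(2.0, 5.0, size=(12, 5)) + 1e-6
            prof = _profile(values, [f"g{i}" for i in range(12)],
                            [f"R{j}" for j in range(5)])
            freq = frequency_table(prof)
            gl = GeneList("l", "c", tuple(f"g{i}" for i in range(0, 12, 2)))
            k = int(rng.integers(1, 7))
            out = top_contributors(freq, gl, "R2", k=k)
            total = freq.values.loc[list(gl.genes), "R2"].sum()
            assert sum(v for _, v in out) == pytest.approx(total, abs=1e-9)

    def test_missing_region_rejected(self, default_profile):
        freq = frequency_table(default_profile)
        gl = GeneList("l", "c", tuple(freq.gene_ids[:3]))
        with pytest.raises(ValueError, match="nowhere"):
            top_contributors(freq, gl, "nowhere", k=1)


class TestPeakRegion:
    def test_tie_breaks_to_first_region_id(self):
        prof = _profile([[5, 5, 1]], ["g1"], ["B", "A", "C"])
        assert peak_region(prof, "g1") == "A"

    def test_all_zero_gene_rejected(self):
        prof = _profile([[0, 0]], ["g1"], ["A", "B"])
        with pytest.raises(ValueError, match="zero"):
            peak_region(prof, "g1")

    def test_marker_recovery_default_noise(self, default_atlas):
        matrix, truth = default_atlas
        prof = average_replicates(matrix)
        hits = sum(
            peak_region(prof, g) == r for g, r in truth.marker_of.items()
        )
        assert hits >= 0.9 * len(truth.marker_of)


def bky_oracle(pvals, q):
    """Literal transcription of the two-stage step-up procedure."""
    m = len(pvals)
    q1 = q / (1 + q)

    def bh(pv, level):
        order = sorted(range(len(pv)), key=lambda i: pv[i])
        n_rej = 0
        for rank, i in enumerate(order, start=1):
            if pv[i] <= rank * level / len(pv):
                n_rej = rank
        return {order[i] for i in range(n_rej)}

    r1 = len(bh(pvals, q1))
    if r1 == 0:
        return [False] * m
    if r1 == m:
        return [True] * m
    m0 = m - r1
    stage2_level = q1 * m / m0
    rejected = bh(pvals, stage2_level)
    return [i in rejected for i in range(m)]


def bh_flags(pvals, q):
    order = sorted(range(len(pvals)), key=lambda i: pvals[i])
    n_rej = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= rank * q / len(pvals):
            n_rej = rank
    rejected = {order[i] for i in range(n_rej)}
    return [i in rejected for i in range(len(pvals))]


class TestBkyAdjust:
    def test_all_tiny_p_rejected(self):
        reject, _ = bky_adjust([1e-6] * 10, q=0.05)
        assert reject.all()

    def test_all_large_p_kept(self):
        reject, _ = bky_adjust([0.9] * 10, q=0.05)
        assert not reject.any()

    def test_empty_input(self):
        reject, adjusted = bky_adjust([], q=0.05)
        assert reject.size == 0 and adjusted.size == 0

    def test_matches_literal_oracle_25_mixed(self):
        rng = np.random.default_rng(42)
        p = np.concatenate([rng.uniform(0, 0.01, 8), rng.uniform(0, 1, 17)])
        rng.shuffle(p)
        reject, _ = bky_adjust(p, q=0.05)
        assert list(reject) == bky_oracle(list(p), 0.05)

    @pytest.mark.parametrize("q", [0.01, 0.05, 0.1, 0.25])
    def test_matches_oracle_random_vectors(self, q):
        rng = np.random.default_rng(hash(q) % 2**32)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            mix = rng.uniform(size=m)
            signal = rng.uniform(0, 0.02, size=m)
            p = np.where(rng.uniform(size=m) < 0.3, signal, mix)
            reject, adjusted = bky_adjust(p, q=q)
            assert list(reject) == bky_oracle(list(p), q)
            # adjusted values reproduce the flags at this q
            assert list(adjusted <= q) == list(reject)

    def test_dominates_bh_at_corrected_level(self):
        # the provable superset property: BKY stage 2 runs BH at a level
        # >= the stage-1 level q/(1+q), so it rejects a superset of BH at
        # q/(1+q).  (Dominance over BH at raw q is false in general: for
        # m=1, p=0.048, q=0.05 BH rejects but BKY does not.)
        rng = np.random.default_rng(7)
        q = 0.05
        for _ in range(100):
            m = int(rng.integers(2, 30))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            reject, _ = bky_adjust(p, q=q)
            bh = bh_flags(list(p), q / (1 + q))
            assert all(b <= r for b, r in zip(bh, reject))

    def test_raw_bh_dominance_counterexample(self):
        q = 0.05
        p = [0.048]
        assert bh_flags(p, q) == [True]
        reject, _ = bky_adjust(p, q=q)
        assert not reject.any()

    @given(
        st.lists(st.floats(0, 1), min_size=2, max_size=20),
        st.integers(0, 19),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_lowering_p_keeps_rejections(self, pvals, idx):
        idx = idx % len(pvals)
        before, _ = bky_adjust(pvals, q=0.05)
        lowered = list(pvals)
        lowered[idx] = lowered[idx] / 2
        after, _ = bky_adjust(lowered, q=0.05)
        for i, was in enumerate(before):
            if i != idx and was:
                assert after[i]


class TestPairwiseRegionTests:
    def test_identical_regions_f_zero(self):
        prof = _profile([[10, 10], [40, 40]], ["g1", "g2"], ["A", "B"])
        freq = frequency_table(prof)
        gl = GeneList("l", "c", ("g1", "g2"))
        f_stat, _, tests = pairwise_region_tests(freq, gl)
        assert f_stat == pytest.approx(0.0)
        assert not any(t.significant for t in tests)

    def test_record_count_is_r_choose_2(self, default_profile):
        freq = frequency_table(default_profile)
        gl = GeneList("l", "c", tuple(freq.gene_ids[:10]))
        _, _, tests = pairwise_region_tests(freq, gl)
        r = len(freq.regions)
        assert len(tests) == r * (r - 1) // 2

    def test_planted_enrichment_dominates_significant_pairs(self):
        matrix, truth = generate_atlas(AtlasConfig(noise_sd=0.1, seed=2))
        (gl,) = generate_gene_lists(
            truth, [ListSpec("L", 25, "cerebellum", strength=1.0)], seed=2
        )
        prof = average_replicates(matrix)
        freq = frequency_table(prof)
        _, _, tests = pairwise_region_tests(freq, gl, q=0.05)
        sig = [t for t in tests if t.significant]
        assert sig
        stem = {r for r, g in truth.region_groups.items() if g == "cerebellum"}
        involving = [t for t in sig if t.region_a in stem or t.region_b in stem]
        assert len(involving) >= 0.5 * len(sig)

    def test_requires_two_genes(self, default_profile):
        freq = frequency_table(default_profile)
        with pytest.raises(ValueError, match="2 list genes"):
            pairwise_region_tests(freq, GeneList("l", "c", (freq.gene_ids[0],)))

    def test_degenerate_layout_flagged(self):
        prof = _profile([[10, 30], [10, 30]], ["g1", "g2"], ["A", "B"])
        freq = frequency_table(prof)
        gl = GeneList("l", "c", ("g1", "g2"))
        _, _, tests = pairwise_region_tests(freq, gl)
        assert all(t.degenerate for t in tests)
        assert all(np.isnan(t.p_value) for t in tests)
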