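"""Plate normalization, z-score hit calling, fingerprint clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import moanet.screen as screen
import moanet.synthetic as synthetic


def plate_frame(rows):
    return pd.DataFrame(
        rows, columns=["plate_id", "well_id", "compound_id", "replicate", "signal"]
    )


def simple_plate(neg=(90.0, 100.0, 110.0), samples=((u"C1", 50.0),)):
    rows = [("P1", f"N{i}", screen.NEG, 1, s) for i, s in enumerate(neg)]
    rows += [("P1", f"S{i}", cid, 1, s) for i, (cid, s) in enumerate(samples)]
    return plate_frame(rows)


class TestNormalizePlate:
    def test_sample_relative_to_negative_median(self):
        norm = screen.normalize_plate(simple_plate())
        sample = norm.loc[norm["compound_id"] == "C1", "normalized"]
        assert sample.iloc[0] == pytest.approx(0.5)

    def test_negative_controls_map_near_one(self):
        norm = screen.normalize_plate(simple_plate())
        negs = norm.loc[norm["compound_id"] == screen.NEG, "normalized"]
        assert negs.median() == pytest.approx(1.0)

    def test_scale_invariance(self):
        base = simple_plate()
        doubled = base.assign(signal=base["signal"] * 2)
        a = screen.normalize_plate(base)["normalized"]
        b = screen.normalize_plate(doubled)["normalized"]
        assert np.allclose(a, b)

    def test_missing_negative_controls_raise(self):
        rows = plate_frame([("P1", "W0", "C1", 1, 100.0)])
        with pytest.raises(ValueError):
            screen.normalize_plate(rows)


class TestZscoreHits:
    def _screen(self, compound_signals, neg_mu=100.0, neg_sd=5.0, n_neg=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = [
            ("P1", f"N{i}", screen.NEG, 1, rng.normal(neg_mu, neg_sd))
            for i in range(n_neg)
        ]
        rows += [
            ("P1", f"S{i}", cid, 1, sig)
            for i, (cid, sig) in enumerate(compound_signals)
        ]
        return plate_frame(rows)

    def test_compound_at_negative_mean_is_not_hit(self):
        plates = self._screen([("C1", 100.0)])
        hits = screen.zscore_hits(plates)
        assert abs(hits.loc["C1", "z_score"]) < 0.5
        assert not hits.loc["C1", "is_hit"]

    def test_compound_three_sigma_below_is_hit(self):
        plates = self._screen([("C1", 100.0 - 3 * 5.0)])
        hits = screen.zscore_hits(plates)
        assert hits.loc["C1", "z_score"] < -2.12
        assert bool(hits.loc["C1", "is_hit"])

    def test_zero_negative_variance_raises(self):
        rows = plate_frame(
            [("P1", f"N{i}", screen.NEG, 1, 100.0) for i in range(4)]
            + [("P1", "S0", "C1", 1, 50.0)]
        )
        with pytest.raises(ValueError):
            screen.zscore_hits(rows)

    def test_invariant_to_per_plate_scaling(self):
        plates, _ = synthetic.gen_screen(
            n_plates=2, wells_per_plate=96, hit_fraction=0.05, rng_seed=3
        )
        scaled = plates.copy()
        for i, pid in enumerate(scaled["plate_id"].unique()):
            scaled.loc[scaled["plate_id"] == pid, "signal"] *= 1.0 + i
        a = screen.zscore_hits(plates)
        b = screen.zscore_hits(scaled)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_strong_hits_recovered(self):
        plates, truth = synthetic.gen_screen(
            n_plates=4, wells_per_plate=96, hit_fraction=0.05, hit_effect=6.0, rng_seed=1
        )
        hits = screen.zscore_hits(plates)
        called = set(hits.index[hits["is_hit"]])
        assert truth.true_hits <= called

    def test_control_separation_reported(self):
        plates, _ = synthetic.gen_screen(n_plates=2, wells_per_plate=96, rng_seed=2)
        z_prime = screen.control_separation(plates)
        assert 0 < z_prime <= 1


class TestJaccard:
    def test_identical_fingerprints(self):
        fp = np.array([1, 0, 1, 1])
        assert screen.jaccard_similarity(fp, fp) == 1.0

    def test_disjoint_fingerprints(self):
        assert screen.jaccard_similarity([1, 1, 0, 0], [0, 0, 1, 1]) == 0.0

    def test_forced_arithmetic(self):
        assert screen.jaccard_similarity([1, 1, 0, 0], [1, 0, 1, 0]) == pytest.approx(1 / 3)

    def test_both_empty_raise(self):
        with pytest.raises(ValueError):
            screen.jaccard_similarity([0, 0], [0, 0])

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            screen.jaccard_similarity([1, 0], [1, 0, 1])

    @given(
        st.lists(
            st.tuples(st.booleans(), st.booleans(), st.booleans()),
            min_size=8, max_size=8,
        )
    )
    def test_distance_triangle_inequality(self, bits):
        a, b, c = (np.array([t[i] for t in bits], dtype=bool) for i in range(3))
        if not (a.any() or b.any() or c.any()):
            return
        a[0] = b[1] = c[2] = True  # keep all three non-empty
        d_ab = screen.jaccard_distance(a, b)
        d_bc = screen.jaccard_distance(b, c)
        d_ac = screen.jaccard_distance(a, c)
        assert d_ac <= d_ab + d_bc + 1e-12


class TestClusterHits:
    def test_zero_cut_all_distinct_gives_singletons(self):
        fps = pd.DataFrame(np.eye(4, dtype=int), index=list("abcd"))
        result = screen.cluster_hits(fps, cut_distance=0.0)
        assert result.families == []
        assert sorted(result.singletons) == list("abcd")

    def test_cut_at_one_gives_single_cluster(self):
        fps, _ = synthetic.gen_fingerprints(10, n_bits=32, n_clusters=3, rng_seed=4)
        result = screen.cluster_hits(fps, cut_distance=1.0)
        assert len(result.families) == 1
        assert len(result.families[0]) == 10

    def test_planted_clusters_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        fps, truth = synthetic.gen_fingerprints(
            104, n_bits=128, n_clusters=8, flip_prob=0.05, rng_seed=5
        )
        result = screen.cluster_hits(fps, cut_distance=0.5)
        truth_labels = [truth.true_clusters[c] for c in result.labels.index]
        assert adjusted_rand_score(truth_labels, result.labels) > 0.5

    def test_fewer_than_two_compounds_raise(self):
        fps = pd.DataFrame([[1, 0]], index=["only"])
        with pytest.raises(ValueError):
            screen.cluster_hits(fps, cut_distance=0.5)

    def test_partition_invariant_to_input_order(self):
        fps, _ = synthetic.gen_fingerprints(30, n_bits=64, n_clusters=4, rng_seed=6)
        shuffled = fps.sample(frac=1.0, random_state=1)
        a = screen.cluster_hits(fps, cut_distance=0.4).labels
        b = screen.cluster_hits(shuffled, cut_distance=0.4).labels
        # same partition regardless of row order (labels may be renumbered)
        grouping_a = {c: frozenset(a.index[a == a[c]]) for c in a.index}
        grouping_b = {c: frozenset(b.index[b == b[c]]) for c in b.index}
        assert grouping_a == grouping_b


class TestGenScreen:
    def test_no_hit_fraction_gives_empty_truth(self):
        _, truth = synthetic.gen_screen(n_plates=1, wells_per_plate=96, hit_fraction=0.0, rng_seed=7)
        assert truth.true_hits == set()

    def test_every_plate_has_control_wells(self):
        plates, _ = synthetic.gen_screen(
            n_plates=3, wells_per_plate=96, n_pos_ctrl=4, n_neg_ctrl=8, rng_seed=8
        )
        for _, group in plates.groupby("plate_id"):
            assert (group["compound_id"] == screen.POS).sum() == 4
            assert (group["compound_id"] == screen.NEG).sum() == 8

    def test_compounds_appear_on_two_replicate_plates(self):
        plates, _ = synthetic.gen_screen(n_plates=2, wells_per_plate=96, rng_seed=9)
        samples = plates[~plates["compound_id"].isin([screen.NEG, screen.POS])]
        assert (samples.groupby("compound_id")["replicate"].nunique() == 2).all()


class TestGenFingerprints:
    def test_no_flips_means_identical_within_cluster(self):
        fps, truth = synthetic.gen_fingerprints(12, n_bits=32, n_clusters=3, flip_prob=0.0, rng_seed=10)
        for cid, other in zip(list(fps.index), list(fps.index)[1:]):
            if truth.true_clusters[cid] == truth.true_clusters[other]:
                sim = screen.jaccard_similarity(fps.loc[cid], fps.loc[other])
                assert sim == 1.0

    def test_single_cluster_partition(self):
        _, truth = synthetic.gen_fingerprints(8, n_clusters=1, rng_seed=11)
        assert set(truth.true_clusters.values()) == {0}

    def test_within_cluster_similarity_exceeds_between(self):
        fps, truth = synthetic.gen_fingerprints(
            104, n_bits=128, n_clusters=8, flip_prob=0.05, rng_seed=12
        )
        matrix = fps.to_numpy(bool)
        labels = np.array([truth.true_clusters[c] for c in fps.index])
        within, between = [], []
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                sim = screen.jaccard_similarity(matrix[i], matrix[j])
                (within if labels[i] == labels[j] else between).append(sim)
        assert np.mean(within) > np.mean(between)

    def test_truth_is_a_partition_with_nonempty_fingerprints(self):
        fps, truth = synthetic.gen_fingerprints(20, n_bits=16, n_clusters=5, flip_prob=0.3, rng_seed=13)
        assert set(truth.true_clusters) == set(fps.index)
        assert fps.to_numpy().any(axis=1).all()
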