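"""Probability profiles, confidence bands, group comparison, subsampling."""

import numpy as np
import pandas as pd
import pytest

from cnaprofiles import (
    GeneratorFunction,
    compare_groups,
    estimate_profile,
    harmonize_profiles,
    matrix_to_segments,
    partition_segments,
    sample_cohort,
    stratified_subsample,
)
from cnaprofiles.profile import proportion_ci, subsample_sizes
from cnaprofiles.simulate import SimulatedCohort
from conftest import PATIENT_VECTORS, segments_frame


def profile_from_matrix(matrix, region_size=1000):
    gen = GeneratorFunction(probs=(0.0,) * matrix.shape[1], region_size=region_size)
    cohort = SimulatedCohort(np.asarray(matrix), gen, seed=0)
    segments = matrix_to_segments(cohort)
    regions = partition_segments(segments, matrix.shape[0])
    return estimate_profile(regions, matrix.shape[0])


class TestEstimateProfile:
    def test_five_patient_example_phat(self):
        """Column means of the five example patient vectors: an unaltered
        region estimates 0, a universally altered one estimates 1."""
        profile = profile_from_matrix(PATIENT_VECTORS)
        # regions 1, 7-10 have no alterations and are absent from the
        # partition; map the emitted regions back to grid indices
        by_index = {
            int(row.start) // 1000: row.phat for row in profile.table.itertuples()
        }
        full = [by_index.get(r, 0.0) for r in range(10)]
        assert full == [0.0, 0.6, 0.6, 1.0, 0.6, 0.2, 0.0, 0.0, 0.0, 0.0]

    def test_phat_is_exact_ratio(self):
        profile = profile_from_matrix(PATIENT_VECTORS)
        counts = profile.table["n_occurrences"]
        assert (profile.table["phat"] == counts / 5).all()

    def test_ci_brackets_phat(self):
        profile = profile_from_matrix(PATIENT_VECTORS)
        t = profile.table
        assert ((0 <= t["ci_low"]) & (t["ci_low"] <= t["phat"])).all()
        assert ((t["phat"] <= t["ci_high"]) & (t["ci_high"] <= 1)).all()

    def test_zero_subjects_rejected(self):
        regions = partition_segments(segments_frame([("A", 0, 10)]), 1)
        with pytest.raises(ValueError, match="n_subjects"):
            estimate_profile(regions, 0)

    def test_count_exceeding_cohort_rejected(self):
        regions = partition_segments(
            segments_frame([("A", 0, 10), ("B", 0, 10)]), 2
        )
        with pytest.raises(ValueError, match="exceeds"):
            estimate_profile(regions, 1)


class TestConfidenceIntervals:
    def test_width_shrinks_with_cohort_size(self):
        """At a fixed frequency of 0.3 the band narrows as cohorts grow."""
        widths = []
        for n in (50, 100, 200):
            low, high = proportion_ci([int(0.3 * n)], n)
            widths.append(float(high[0] - low[0]))
        assert widths[0] > widths[1] > widths[2]

    def test_wilson_coverage_near_nominal(self):
        """Empirical 95% coverage at p=0.3, n=200 over 1,000 replicates."""
        rng = np.random.default_rng(20200910)
        counts = rng.binomial(200, 0.3, size=1000)
        low, high = proportion_ci(counts, 200)
        coverage = float(np.mean((low <= 0.3) & (0.3 <= high)))
        assert 0.93 <= coverage <= 0.97

    def test_selectable_methods(self):
        for method in ("wilson", "wald", "clopper-pearson"):
            low, high = proportion_ci([3], 10, method=method)
            assert 0 <= low[0] <= 0.3 <= high[0] <= 1
        with pytest.raises(ValueError, match="unknown CI method"):
            proportion_ci([3], 10, method="bootstrap")


class TestHarmonizeProfiles:
    def test_shared_boundaries_from_pooled_partition(self):
        seg_a = segments_frame([("A1", 0, 100)])
        seg_b = segments_frame([("B1", 50, 150)])
        prof_a, prof_b = harmonize_profiles(seg_a, seg_b)
        bounds = [(r.start, r.end) for r in prof_a.table.itertuples()]
        assert bounds == [(0, 50), (50, 100), (100, 150)]
        assert list(prof_a.phat) == [1.0, 1.0, 0.0]
        assert list(prof_b.phat) == [0.0, 1.0, 1.0]

    def test_identical_groups_have_zero_distance(self):
        seg = segments_frame([("A1", 0, 100), ("A2", 50, 150)])
        seg_b = seg.copy()
        prof_a, prof_b = harmonize_profiles(seg, seg_b)
        cmp = compare_groups(prof_a, prof_b)
        assert cmp.distance == 0.0
        assert cmp.n_differential == 0

    def test_group_counts_conserve_partition_mass(self):
        gen = GeneratorFunction(probs=(0.3, 0.6, 0.1, 0.8), region_size=100)
        seg_a = matrix_to_segments(sample_cohort(gen, 12, seed=1))
        seg_b = matrix_to_segments(sample_cohort(gen, 15, seed=2))
        seg_b["sample_id"] = "B" + seg_b["sample_id"]
        prof_a, prof_b = harmonize_profiles(seg_a, seg_b, 12, 15)
        own_a = partition_segments(seg_a, 12)
        lengths = (prof_a.table["end"] - prof_a.table["start"]).to_numpy()
        mass_shared = int((prof_a.table["n_occurrences"] * lengths).sum())
        own_lengths = (own_a["end"] - own_a["start"]).to_numpy()
        assert mass_shared == int((own_a["n_occurrences"] * own_lengths).sum())

    def test_empty_group_named_in_error(self):
        with pytest.raises(ValueError, match="B"):
            harmonize_profiles(
                segments_frame([("A1", 0, 10)]), segments_frame([]), labels=("A", "B")
            )


class TestCompareGroups:
    def test_disjoint_bands_flag_differential(self):
        seg_a = segments_frame([(f"A{i}", 0, 100) for i in range(30)])
        seg_b = segments_frame([("B1", 0, 100)] + [(f"B{i}", 200, 300) for i in range(2, 31)])
        prof_a, prof_b = harmonize_profiles(seg_a, seg_b, 30, 30)
        cmp = compare_groups(prof_a, prof_b)
        # region (0,100): 30/30 vs 1/30 -> clearly disjoint bands
        assert any(r.start == 0 for r in cmp.differential.itertuples())

    def test_distance_is_length_weighted(self):
        seg_a = segments_frame([("A1", 0, 100)])
        seg_b = segments_frame([("B1", 50, 150)])
        prof_a, prof_b = harmonize_profiles(seg_a, seg_b)
        cmp = compare_groups(prof_a, prof_b)
        # |1-0|*50 + |1-1|*50 + |0-1|*50 over 150 bases
        assert cmp.distance == pytest.approx(100 / 150)

    def test_distance_pseudometric_on_random_triples(self):
        gen = GeneratorFunction(probs=(0.2, 0.5, 0.8, 0.4), region_size=100)
        segs = [
            matrix_to_segments(sample_cohort(gen, 20, seed=s)) for s in (1, 2, 3)
        ]
        for i, s in enumerate(segs):
            s["sample_id"] = f"G{i}" + s["sample_id"]

        def dist(x, y):
            a, b = harmonize_profiles(x, y, 20, 20)
            return compare_groups(a, b).distance

        d01, d12, d02 = dist(segs[0], segs[1]), dist(segs[1], segs[2]), dist(segs[0], segs[2])
        d10 = dist(segs[1], segs[0])
        assert d01 == pytest.approx(d10)
        assert d02 <= d01 + d12 + 1e-12
        assert min(d01, d12, d02) >= 0

    def test_mismatched_region_sets_rejected(self):
        prof_a = profile_from_matrix(PATIENT_VECTORS)
        prof_b = profile_from_matrix(PATIENT_VECTORS[:, :5])
        with pytest.raises(ValueError, match="region set"):
            compare_groups(prof_a, prof_b)

    def test_null_groups_rarely_differ(self):
        """Two groups drawn from one generator should flag (almost) no
        differential regions at n=200 per group."""
        gen = GeneratorFunction(probs=(0.1, 0.3, 0.5, 0.7, 0.9), region_size=100)
        fractions = []
        for s in range(5):
            seg_a = matrix_to_segments(sample_cohort(gen, 200, seed=100 + s))
            seg_b = matrix_to_segments(sample_cohort(gen, 200, seed=200 + s))
            seg_b["sample_id"] = "B" + seg_b["sample_id"]
            a, b = harmonize_profiles(seg_a, seg_b, 200, 200)
            cmp = compare_groups(a, b)
            fractions.append(cmp.n_differential / len(a))
        assert np.mean(fractions) <= 0.1


class TestStratifiedSubsample:
    @staticmethod
    def cohort(n_a=423, n_b=99):
        ids = [f"H{i}" for i in range(n_a)] + [f"P{i}" for i in range(n_b)]
        labels = pd.Series(
            ["neg"] * n_a + ["pos"] * n_b, index=pd.Index(ids, name="sample_id")
        )
        segments = segments_frame([(sid, 0, 100) for sid in ids])
        return segments, labels

    def test_largest_remainder_class_sizes(self):
        """Drawing 200 of 522 subjects split 423/99 keeps 162/38."""
        assert subsample_sizes({"neg": 423, "pos": 99}, 200) == {"neg": 162, "pos": 38}
        segments, labels = self.cohort()
        sub = stratified_subsample(segments, labels, 200, seed=0)
        drawn = labels[sub["sample_id"].unique()]
        assert drawn.value_counts().to_dict() == {"neg": 162, "pos": 38}

    def test_full_draw_is_identity(self):
        segments, labels = self.cohort(10, 5)
        sub = stratified_subsample(segments, labels, 15, seed=0)
        assert set(sub["sample_id"]) == set(labels.index)

    def test_same_seed_reproduces(self):
        segments, labels = self.cohort(30, 10)
        a = stratified_subsample(segments, labels, 20, seed=42)
        b = stratified_subsample(segments, labels, 20, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_overdraw_rejected(self):
        segments, labels = self.cohort(5, 5)
        with pytest.raises(ValueError, match="cannot draw"):
            stratified_subsample(segments, labels, 11, seed=0)
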