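"""Probability-of-alteration profiles with proportion confidence bands.

For each common region r a Bernoulli experiment is assumed: a subject is
altered there with unknown probability Phi(r), the population's genomic
signature ("generator function").  The cohort estimate is the exact ratio

    phat(r) = n_occurrences(r) / N_subjects,

with a proportion confidence interval per region (Wilson score by
default, which behaves well at phat = 0 and 1).  Two groups are compared
region-by-region on a shared partition: regions whose confidence bands do
not overlap are flagged as differential, and a region-length-weighted L1
distance summarises how far apart the two profiles are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .partition import build_incidence, partition_segments, REGION_COLUMNS

_CI_METHODS = {
    "wilson": "wilson",
    "wald": "normal",
    "clopper-pearson": "beta",
}

#: Columns of a profile table written as TSV.
PROFILE_COLUMNS = [
    "chromosome", "start", "end", "call",
    "n_occurrences", "n_subjects", "phat", "ci_low", "ci_high", "group",
]


@dataclass
class ProbabilityProfile:
    """Estimated generator function for one group and call direction.

    ``table`` holds one row per common region with columns
    ``chromosome, start, end, call, n_occurrences, n_subjects, phat,
    ci_low, ci_high, group``; ``phat`` is exactly
    ``n_occurrences / n_subjects``.
    """

    table: pd.DataFrame
    n_subjects: int
    confidence_level: float = 0.95
    group_label: str = ""

    @property
    def phat(self) -> np.ndarray:
        return self.table["phat"].to_numpy()

    @property
    def ci_low(self) -> np.ndarray:
        return self.table["ci_low"].to_numpy()

    @property
    def ci_high(self) -> np.ndarray:
        return self.table["ci_high"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table[PROFILE_COLUMNS].to_csv(str(path), sep="\t", index=False)


@dataclass
class GroupComparison:
    """Region-wise comparison of two harmonized profiles."""

    profile_a: ProbabilityProfile
    profile_b: ProbabilityProfile
    differential: pd.DataFrame = field(repr=False)
    distance: float = 0.0

    @property
    def n_differential(self) -> int:
        return len(self.differential)


def proportion_ci(
    counts, n_subjects: int, confidence_level: float = 0.95, method: str = "wilson"
):
    """Per-region proportion confidence bounds, clipped to [0, 1]."""
    if method not in _CI_METHODS:
        raise ValueError(
            f"unknown CI method {method!r}; choose from {sorted(_CI_METHODS)}"
        )
    low, high = proportion_confint(
        np.asarray(counts), n_subjects, alpha=1 - confidence_level,
        method=_CI_METHODS[method],
    )
    return np.clip(low, 0.0, 1.0), np.clip(high, 0.0, 1.0)


def estimate_profile(
    regions: pd.DataFrame,
    n_subjects: int,
    confidence_level: float = 0.95,
    ci_method: str = "wilson",
    group_label: str = "",
) -> ProbabilityProfile:
    """Estimate phat with confidence bands over a common-region table.

    ``regions`` must carry ``n_occurrences`` (from the partition sweep);
    ``n_subjects`` is the cohort roster size.
    """
    if n_subjects <= 0:
        raise ValueError(f"n_subjects must be positive, got {n_subjects}")
    if not 0 < confidence_level < 1:
        raise ValueError(f"confidence_level must lie in (0, 1), got {confidence_level}")
    counts = regions["n_occurrences"].to_numpy()
    if len(counts) and counts.max() > n_subjects:
        raise ValueError(
            f"region count {int(counts.max())} exceeds cohort size {n_subjects}"
        )
    # exact integer ratio; no float path touches the counts
    phat = counts / n_subjects
    ci_low, ci_high = proportion_ci(counts, n_subjects, confidence_level, ci_method)
    table = regions[REGION_COLUMNS].copy()
    table["n_subjects"] = n_subjects
    table["phat"] = phat
    table["ci_low"] = np.minimum(ci_low, phat)
    table["ci_high"] = np.maximum(ci_high, phat)
    table["group"] = group_label
    return ProbabilityProfile(
        table=table.reset_index(drop=True),
        n_subjects=n_subjects,
        confidence_level=confidence_level,
        group_label=group_label,
    )


def harmonize_profiles(
    segments_a: pd.DataFrame,
    segments_b: pd.DataFrame,
    n_subjects_a: int | None = None,
    n_subjects_b: int | None = None,
    confidence_level: float = 0.95,
    ci_method: str = "wilson",
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[ProbabilityProfile, ProbabilityProfile]:
    """Estimate two groups' profiles on one shared region set.

    The partition is computed on the pooled segments of both groups so the
    two profiles are comparable region by region; each group's occurrence
    counts and phat are then computed against its own cohort size on those
    shared boundaries.  Cohort sizes default to the number of distinct
    subjects per group.
    """
    for name, seg in zip(labels, (segments_a, segments_b)):
        if seg.empty:
            raise ValueError(f"group {name!r} has no altered segments")
    if n_subjects_a is None:
        n_subjects_a = segments_a["sample_id"].nunique()
    if n_subjects_b is None:
        n_subjects_b = segments_b["sample_id"].nunique()
    pooled = pd.concat([segments_a, segments_b], ignore_index=True)
    shared = partition_segments(pooled, n_subjects_a + n_subjects_b)

    profiles = []
    for seg, n, label in (
        (segments_a, n_subjects_a, labels[0]),
        (segments_b, n_subjects_b, labels[1]),
    ):
        regions = shared.copy()
        regions["n_occurrences"] = _group_counts(seg, shared)
        profiles.append(
            estimate_profile(regions, n, confidence_level, ci_method, label)
        )
    return profiles[0], profiles[1]


def _group_counts(segments: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    """Occurrence counts of one group's subjects on shared-region boundaries."""
    counts = np.zeros(len(regions), dtype=np.int64)
    for (chrom, call), group in segments.groupby(["chromosome", "call"], sort=False):
        mask = (regions["chromosome"] == chrom) & (regions["call"] == call)
        if not mask.any():
            continue
        inc = build_incidence(group, regions[mask], validate=False)
        counts[mask.to_numpy()] = inc.to_numpy().sum(axis=0)
    return counts


def compare_groups(
    a: ProbabilityProfile, b: ProbabilityProfile
) -> GroupComparison:
    """Flag differential regions and compute the profile distance.

    A region is differential iff the two confidence bands are disjoint.
    The distance is Sum_r |phat_a - phat_b| * len(r) / Sum_r len(r): a
    length-weighted mean absolute difference, so large regions weigh more
    than focal ones.  Band non-overlap is a descriptive screen, not a
    calibrated hypothesis test; no multiplicity correction is applied.
    """
    key_cols = ["chromosome", "start", "end", "call"]
    ta, tb = a.table, b.table
    if len(ta) != len(tb) or not ta[key_cols].reset_index(drop=True).equals(
        tb[key_cols].reset_index(drop=True)
    ):
        raise ValueError("profiles are not on the same region set; harmonize first")
    disjoint = (ta["ci_low"].to_numpy() > tb["ci_high"].to_numpy()) | (
        tb["ci_low"].to_numpy() > ta["ci_high"].to_numpy()
    )
    lengths = (ta["end"] - ta["start"]).to_numpy(dtype=float)
    diff = np.abs(ta["phat"].to_numpy() - tb["phat"].to_numpy())
    distance = float((diff * lengths).sum() / lengths.sum()) if lengths.sum() else 0.0
    differential = ta[key_cols].copy()
    differential["phat_a"] = ta["phat"].to_numpy()
    differential["phat_b"] = tb["phat"].to_numpy()
    differential = differential[disjoint].reset_index(drop=True)
    return GroupComparison(
        profile_a=a, profile_b=b, differential=differential, distance=distance
    )


def stratified_subsample(
    segments: pd.DataFrame,
    group_labels: pd.Series,
    n: int,
    seed: int,
) -> pd.DataFrame:
    """Draw ``n`` subjects without replacement, preserving class proportions.

    Per-class draw sizes follow largest-remainder rounding of the class
    proportions times ``n`` so they sum exactly to ``n``.  ``group_labels``
    maps sample ID to class label for the whole cohort roster (subjects
    without altered segments included).  Returns the altered-segment rows
    of the drawn subjects; the draw is reproducible for a fixed seed.
    """
    roster = group_labels.index.to_numpy()
    if n > len(roster):
        raise ValueError(f"cannot draw {n} subjects from a cohort of {len(roster)}")
    classes = group_labels.groupby(group_labels).groups
    sizes = {}
    quotas = {
        label: n * len(members) / len(roster) for label, members in classes.items()
    }
    for label, quota in quotas.items():
        sizes[label] = int(np.floor(quota))
    shortfall = n - sum(sizes.values())
    by_remainder = sorted(
        quotas, key=lambda lbl: (quotas[lbl] - np.floor(quotas[lbl]), str(lbl)),
        reverse=True,
    )
    for label in by_remainder[:shortfall]:
        sizes[label] += 1

    rng = np.random.default_rng(seed)
    chosen: list = []
    for label in sorted(classes, key=str):
        members = np.asarray(sorted(classes[label]))
        chosen.extend(rng.choice(members, size=sizes[label], replace=False))
    chosen_set = set(chosen)
    return segments[segments["sample_id"].isin(chosen_set)].reset_index(drop=True)


def subsample_sizes(class_counts: dict, n: int) -> dict:
    """Largest-remainder per-class draw sizes for a stratified subsample."""
    total = sum(class_counts.values())
    if n > total:
        raise ValueError(f"cannot draw {n} subjects from a cohort of {total}")
    quotas = {label: n * c / total for label, c in class_counts.items()}
    sizes = {label: int(np.floor(q)) for label, q in quotas.items()}
    shortfall = n - sum(sizes.values())
    by_remainder = sorted(
        quotas, key=lambda lbl: (quotas[lbl] - np.floor(quotas[lbl]), str(lbl)),
        reverse=True,
    )
    for label in by_remainder[:shortfall]:
        sizes[label] += 1
    return sizes
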