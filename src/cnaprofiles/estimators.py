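"""Scikit-learn-style estimators over the partition/profile pipeline.

`CommonRegionPartitioner` is a transformer: fitting on an altered-segment
table learns the common regions of alteration (``regions_``) and
transforming yields the binary subjects x regions incidence matrix.
`AlterationProfiler` fits the full probability profile with confidence
bands.  Both follow the sklearn contract (``get_params``/``set_params``,
fitted attributes with trailing underscores), so they compose with
pipelines and ``clone``.
"""

from __future__ import annotations

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.exceptions import NotFittedError

from .partition import build_incidence, partition_segments
from .profile import ProbabilityProfile, estimate_profile

_SEGMENT_COLUMNS = ("sample_id", "chromosome", "start", "end", "call")


def _validate_segments(X) -> pd.DataFrame:
    if not isinstance(X, pd.DataFrame):
        raise TypeError(
            "expected an altered-segment DataFrame with columns "
            f"{_SEGMENT_COLUMNS}, got {type(X).__name__}"
        )
    missing = [c for c in _SEGMENT_COLUMNS if c not in X.columns]
    if missing:
        raise ValueError(f"segment table is missing columns {missing}")
    if len(X) and (X["start"] >= X["end"]).any():
        raise ValueError("segment table contains start >= end")
    return X


class CommonRegionPartitioner(TransformerMixin, BaseEstimator):
    """Partition cohort segments into common regions of alteration.

    Parameters
    ----------
    n_subjects : int or None
        Cohort roster size.  ``None`` infers it as the number of distinct
        sample IDs in the fitted segments (which undercounts if some
        subjects carry no alteration — pass the roster size if known).

    Attributes
    ----------
    regions_ : DataFrame
        Common regions (chromosome, start, end, call, n_occurrences),
        sorted by chromosome then start.
    subjects_ : list of str
        Ordered sample IDs seen at fit time.
    n_subjects_ : int
        Cohort size actually used.
    """

    def __init__(self, n_subjects: int | None = None):
        self.n_subjects = n_subjects

    def fit(self, X, y=None):
        X = _validate_segments(X)
        self.subjects_ = sorted(X["sample_id"].unique())
        self.n_subjects_ = (
            self.n_subjects if self.n_subjects is not None else len(self.subjects_)
        )
        self.regions_ = partition_segments(X, self.n_subjects_)
        return self

    def transform(self, X) -> pd.DataFrame:
        """Incidence matrix of ``X``'s subjects over the fitted regions."""
        if not hasattr(self, "regions_"):
            raise NotFittedError("CommonRegionPartitioner is not fitted yet")
        X = _validate_segments(X)
        subjects = sorted(X["sample_id"].unique())
        pieces = []
        for (chrom, call), reg in self.regions_.groupby(
            ["chromosome", "call"], sort=False
        ):
            seg = X[(X["chromosome"] == chrom) & (X["call"] == call)]
            pieces.append(build_incidence(seg, reg, subjects=subjects, validate=False))
        if not pieces:
            return pd.DataFrame(index=pd.Index(subjects, name="sample_id"))
        return pd.concat(pieces, axis=1)

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "regions_")


class AlterationProfiler(BaseEstimator):
    """Estimate the probability-of-alteration profile of a cohort.

    Fitting partitions the segments and computes, per common region, the
    exact alteration frequency phat = n_occurrences / n_subjects with a
    proportion confidence interval.

    Parameters
    ----------
    confidence_level : float
        Two-sided band level (default 0.95).
    ci_method : {"wilson", "wald", "clopper-pearson"}
        Proportion-interval method; Wilson is well-behaved at phat of 0/1.
    n_subjects : int or None
        Cohort roster size; ``None`` infers from distinct sample IDs.
    group_label : str
        Label carried into the profile table.

    Attributes
    ----------
    profile_ : ProbabilityProfile
    regions_ : DataFrame
    phat_, ci_low_, ci_high_ : ndarray
    """

    def __init__(
        self,
        confidence_level: float = 0.95,
        ci_method: str = "wilson",
        n_subjects: int | None = None,
        group_label: str = "",
    ):
        self.confidence_level = confidence_level
        self.ci_method = ci_method
        self.n_subjects = n_subjects
        self.group_label = group_label

    def fit(self, X, y=None):
        X = _validate_segments(X)
        n = self.n_subjects if self.n_subjects is not None else X["sample_id"].nunique()
        regions = partition_segments(X, n)
        self.profile_ = estimate_profile(
            regions,
            n,
            confidence_level=self.confidence_level,
            ci_method=self.ci_method,
            group_label=self.group_label,
        )
        self.regions_ = regions
        self.n_subjects_ = n
        self.phat_ = self.profile_.phat
        self.ci_low_ = self.profile_.ci_low
        self.ci_high_ = self.profile_.ci_high
        return self

    def fit_profile(self, X) -> ProbabilityProfile:
        """Fit and return the profile in one call."""
        return self.fit(X).profile_

    def __sklearn_is_fitted__(self) -> bool:
        return hasattr(self, "profile_")
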