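"""Sweep-line partition of pooled segment breakpoints into common regions.

Every segment contributes a start breakpoint (identifier 1) and an end
breakpoint (identifier 0).  Merging all subjects' breakpoints on a
chromosome into one ascending sequence and sweeping a counter across it
(+1 at each start, -1 at each end) partitions the altered portion of the
chromosome into maximal intervals of constant subject count — the common
regions of alteration.  The subjects x regions incidence matrix records,
for each subject, which common regions its alterations cover; coverage of
a common region by one subject is all-or-none by construction, because
region boundaries include every subject's breakpoints.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Columns of a breakpoint table.
BREAKPOINT_COLUMNS = ["position", "kind", "sample_id"]

#: Columns of a common-region table.
REGION_COLUMNS = ["chromosome", "start", "end", "call", "n_occurrences"]


def collect_breakpoints(segments: pd.DataFrame) -> pd.DataFrame:
    """Merge segment starts and ends into one sorted breakpoint sequence.

    Each segment yields a start breakpoint (kind=1) and an end breakpoint
    (kind=0).  Sorted ascending by position; at equal positions ends come
    before starts (so a shared boundary closes one region before opening
    the next), and ties beyond that break by sample ID for determinism.
    Input segments must all lie on one chromosome.
    """
    if segments.empty:
        return pd.DataFrame(columns=BREAKPOINT_COLUMNS)
    if segments["chromosome"].nunique() > 1:
        raise ValueError("collect_breakpoints requires a single chromosome")
    starts = pd.DataFrame(
        {"position": segments["start"], "kind": 1, "sample_id": segments["sample_id"]}
    )
    ends = pd.DataFrame(
        {"position": segments["end"], "kind": 0, "sample_id": segments["sample_id"]}
    )
    bp = pd.concat([starts, ends], ignore_index=True)
    bp = bp.sort_values(["position", "kind", "sample_id"], kind="mergesort")
    return bp[BREAKPOINT_COLUMNS].reset_index(drop=True)


def find_common_regions(
    breakpoints: pd.DataFrame,
    n_subjects: int,
    chromosome: str = "",
    call: str = "",
) -> pd.DataFrame:
    """Sweep the breakpoint sequence into common regions with subject counts.

    Adjacent distinct breakpoint positions bound one region; the counter
    value between them is the region's ``n_occurrences``.  Zero-coverage
    gaps are not emitted.  Breakpoints falling on the same locus collapse
    to a single boundary.

    Parameters
    ----------
    breakpoints : DataFrame
        Sorted as produced by :func:`collect_breakpoints`.
    n_subjects : int
        Cohort size; every emitted count must stay within it.
    chromosome, call : str
        Labels copied onto the output rows.

    Raises
    ------
    ValueError
        If the counter goes negative (unbalanced starts/ends), reported
        with the offending position.
    """
    rows = []
    counter = 0
    prev_pos = None
    for position, kind in zip(breakpoints["position"], breakpoints["kind"]):
        if prev_pos is not None and position > prev_pos and counter > 0:
            rows.append((chromosome, prev_pos, position, call, counter))
        counter += 1 if kind == 1 else -1
        if counter < 0:
            raise ValueError(
                f"unbalanced breakpoints: counter negative at position {position}"
            )
        prev_pos = position
    if counter != 0:
        raise ValueError(f"unbalanced breakpoints: counter {counter} after sweep")
    regions = pd.DataFrame(rows, columns=REGION_COLUMNS)
    if not regions.empty and int(regions["n_occurrences"].max()) > n_subjects:
        raise ValueError(
            "region subject count exceeds cohort size "
            f"({int(regions['n_occurrences'].max())} > {n_subjects})"
        )
    return regions


def region_labels(regions: pd.DataFrame) -> list[str]:
    """``chrom:start-end`` labels for incidence-matrix columns."""
    return [
        f"{c}:{s}-{e}"
        for c, s, e in zip(regions["chromosome"], regions["start"], regions["end"])
    ]


def build_incidence(
    segments: pd.DataFrame,
    regions: pd.DataFrame,
    subjects: list[str] | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Build the binary subjects x common-regions incidence matrix.

    Cell (s, r) is 1 iff subject *s* has a segment covering every base of
    region *r*.  When the regions were derived from these same segments,
    column sums equal each region's ``n_occurrences``; a mismatch raises a
    consistency error (``validate=False`` skips the check, e.g. for
    regions from a pooled two-group partition).
    """
    if subjects is None:
        subjects = sorted(segments["sample_id"].unique())
    mat = np.zeros((len(subjects), len(regions)), dtype=np.int8)
    if len(regions):
        r_start = regions["start"].to_numpy()
        r_end = regions["end"].to_numpy()
        index = {s: i for i, s in enumerate(subjects)}
        for sample_id, start, end in zip(
            segments["sample_id"], segments["start"], segments["end"]
        ):
            covered = (r_start >= start) & (r_end <= end)
            mat[index[sample_id], covered] = 1
    out = pd.DataFrame(mat, index=pd.Index(subjects, name="sample_id"),
                       columns=region_labels(regions))
    if validate and len(regions):
        expected = regions["n_occurrences"].to_numpy()
        got = mat.sum(axis=0)
        if not np.array_equal(got, expected):
            raise ValueError(
                "incidence column sums do not match region occurrence counts; "
                "regions were not derived from these segments"
            )
    return out


def partition_segments(segments: pd.DataFrame, n_subjects: int) -> pd.DataFrame:
    """Partition a cohort's altered segments into common regions.

    Runs the breakpoint sweep independently per (chromosome, call) group
    and concatenates the results sorted by chromosome (numeric order) then
    start.  ``n_subjects`` is the cohort roster size, which may exceed the
    number of subjects with alterations.
    """
    if segments.empty:
        return pd.DataFrame(columns=REGION_COLUMNS)
    pieces = []
    for (chrom, call), group in segments.groupby(["chromosome", "call"], sort=False):
        bp = collect_breakpoints(group)
        pieces.append(find_common_regions(bp, n_subjects, chromosome=chrom, call=call))
    regions = pd.concat(pieces, ignore_index=True)
    key = regions["chromosome"].map(_chrom_order)
    regions = (
        regions.assign(_key=key)
        .sort_values(["_key", "start", "call"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return regions


def _chrom_order(label: str) -> int:
    try:
        return int(label)
    except ValueError:
        return 1000 + hash(label) % 1000
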