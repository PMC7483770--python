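"""SEG-format I/O and segment calling.

Reads tab-delimited segmented copy-number tables (Broad/Firehose SEG
dialect: one row per sample x segment with sample ID, chromosome, start,
end, probe count and log2 segment mean), calls gains and losses by
threshold, and unions per-subject overlapping intervals.

Coordinate conventions
----------------------
SEG files carry 1-based inclusive coordinates.  Internally every interval
is 0-based half-open ``[start, end)``, the BED convention, so book-ended
segments (one ending where the next starts) are non-overlapping by
construction.  :func:`write_seg` converts back on the way out.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

#: Canonical internal column order for segment records.
SEG_COLUMNS = ["sample_id", "chromosome", "start", "end", "num_probes", "seg_mean"]

#: Columns of a called altered-segment table.
CALL_COLUMNS = ["sample_id", "chromosome", "start", "end", "call"]

AUTOSOMES = {str(c) for c in range(1, 23)}
SEX_CHROMOSOMES = {"X", "Y", "23", "24"}

# Case-insensitive header aliases, keyed by internal name.
_ALIASES = {
    "sample_id": ("sample", "id", "sample_id", "sampleid", "sample.id"),
    "chromosome": ("chromosome", "chrom", "chr"),
    "start": ("start", "loc.start", "start_position", "loc_start"),
    "end": ("end", "loc.end", "end_position", "loc_end"),
    "num_probes": ("num_probes", "num_markers", "num.mark", "num_mark", "nummark"),
    "seg_mean": ("segment_mean", "seg.mean", "seg_mean", "segmean"),
}

GAIN = "GAIN"
LOSS = "LOSS"
ALTERED = "ALTERED"

MODE_SEPARATE = "SEPARATE"
MODE_COMBINED = "COMBINED"


@dataclass(frozen=True)
class FilterConfig:
    """Probe-count and log2-ratio thresholds for calling altered segments.

    Segments with fewer than ``min_probes`` probes are dropped; the rest
    are called GAIN when ``seg_mean >= gain_threshold`` and LOSS when
    ``seg_mean <= loss_threshold`` (closed comparisons: a segment exactly
    at a threshold is called).  In COMBINED mode gains and losses are
    relabelled ALTERED so they partition together.

    The defaults (10 probes, +/-0.2) are conventional SNP-array calling
    cut-offs, not derived from any particular study.
    """

    min_probes: int = 10
    gain_threshold: float = 0.2
    loss_threshold: float = -0.2
    mode: str = MODE_SEPARATE

    def __post_init__(self) -> None:
        if not (self.loss_threshold < 0 < self.gain_threshold):
            raise ValueError(
                "thresholds must satisfy loss_threshold < 0 < gain_threshold; "
                f"got loss={self.loss_threshold}, gain={self.gain_threshold}"
            )
        if self.min_probes < 1:
            raise ValueError(f"min_probes must be >= 1, got {self.min_probes}")
        if self.mode not in (MODE_SEPARATE, MODE_COMBINED):
            raise ValueError(f"mode must be SEPARATE or COMBINED, got {self.mode!r}")


def _resolve_columns(header: list[str], path: str) -> dict[str, str]:
    lowered = {col.strip().lower(): col for col in header}
    mapping: dict[str, str] = {}
    for internal, aliases in _ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[internal] = lowered[alias]
                break
        else:
            raise ValueError(
                f"{path}: missing mandatory column {internal!r} "
                f"(accepted headers: {', '.join(aliases)})"
            )
    return mapping


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file into a segment table with internal coordinates.

    Returns a DataFrame with columns ``sample_id, chromosome, start, end,
    num_probes, seg_mean`` in file order.  1-based inclusive coordinates
    become 0-based half-open; ``chr`` prefixes are stripped.

    Raises
    ------
    ValueError
        If a mandatory column cannot be resolved (named in the message) or
        a coordinate fails to parse (reported with its line number).
    """
    path = str(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    mapping = _resolve_columns(list(raw.columns), path)
    df = pd.DataFrame({internal: raw[src] for internal, src in mapping.items()})

    for col in ("start", "end", "num_probes"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based line numbering
            line = int(bad.idxmax()) + 2
            raise ValueError(
                f"{path}:{line}: non-numeric value {df[col][bad.idxmax()]!r} "
                f"in column {col!r}"
            )
        df[col] = numeric.astype("int64")
    df["seg_mean"] = pd.to_numeric(df["seg_mean"])
    df["sample_id"] = df["sample_id"].astype(str)
    df["chromosome"] = (
        df["chromosome"].astype(str).str.strip().str.replace(r"^chr", "", regex=True)
    )
    df["start"] = df["start"] - 1  # 1-based inclusive -> 0-based half-open
    if (df["start"] >= df["end"]).any():
        row = df.index[df["start"] >= df["end"]][0]
        raise ValueError(f"{path}:{int(row) + 2}: segment start >= end")
    if (df["num_probes"] < 0).any():
        row = df.index[df["num_probes"] < 0][0]
        raise ValueError(f"{path}:{int(row) + 2}: negative num_probes")
    return df[SEG_COLUMNS]


def write_seg(records: pd.DataFrame, path) -> None:
    """Write a segment table as canonical Firehose SEG (1-based inclusive)."""
    out = records[SEG_COLUMNS].copy()
    out["start"] = out["start"] + 1
    out.columns = ["Sample", "Chromosome", "Start", "End", "Num_Probes", "Segment_Mean"]
    out.to_csv(str(path), sep="\t", index=False)


def write_bed(segments: pd.DataFrame, path) -> None:
    """Write called segments as BED3+ (chrom, start, end, sample_id, call)."""
    cols = ["chromosome", "start", "end", "sample_id", "call"]
    segments[cols].to_csv(str(path), sep="\t", index=False, header=False)


def filter_and_call(records: pd.DataFrame, cfg: FilterConfig) -> pd.DataFrame:
    """Filter segments by probe count and call gains/losses by threshold.

    Sex-chromosome records are dropped here (the analysis covers autosomes
    only); in COMBINED mode both call directions are relabelled ALTERED.
    Returns an altered-segment table (``CALL_COLUMNS``); an empty result is
    not an error.
    """
    df = records[records["num_probes"] >= cfg.min_probes]
    df = df[df["chromosome"].isin(AUTOSOMES)]
    is_gain = df["seg_mean"] >= cfg.gain_threshold
    is_loss = df["seg_mean"] <= cfg.loss_threshold
    df = df[is_gain | is_loss].copy()
    df["call"] = GAIN
    df.loc[df["seg_mean"] <= cfg.loss_threshold, "call"] = LOSS
    if cfg.mode == MODE_COMBINED:
        df["call"] = ALTERED
    return df[CALL_COLUMNS].reset_index(drop=True)


def merge_subject_segments(segments: pd.DataFrame) -> pd.DataFrame:
    """Union each subject's overlapping or book-ended segments.

    All input rows must share one chromosome and one call type; the cohort
    pipeline applies this per (chromosome, call) group.  Output is sorted
    by subject then start, and no subject covers any base pair twice —
    overlapping same-subject intervals would otherwise be double-counted
    by the sweep.
    """
    if segments.empty:
        return segments.reset_index(drop=True)
    if segments["chromosome"].nunique() > 1:
        raise ValueError("merge_subject_segments requires a single chromosome")
    if segments["call"].nunique() > 1:
        raise ValueError("merge_subject_segments requires a single call type")

    merged_rows = []
    chrom = segments["chromosome"].iloc[0]
    call = segments["call"].iloc[0]
    for sample_id, group in segments.sort_values(["sample_id", "start"]).groupby(
        "sample_id", sort=True
    ):
        cur_start = cur_end = None
        for start, end in zip(group["start"], group["end"]):
            if cur_start is None:
                cur_start, cur_end = start, end
            elif start <= cur_end:  # overlap or book-ended: union
                cur_end = max(cur_end, end)
            else:
                merged_rows.append((sample_id, chrom, cur_start, cur_end, call))
                cur_start, cur_end = start, end
        merged_rows.append((sample_id, chrom, cur_start, cur_end, call))
    return pd.DataFrame(merged_rows, columns=CALL_COLUMNS)
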