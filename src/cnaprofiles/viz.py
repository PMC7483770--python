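"""Genome-wide and per-chromosome profile plots with confidence bands.

Each profile is drawn as a step trace of phat over genomic position with
its confidence band shaded in the same colour.  In GENOME scope the
autosomes are concatenated on one axis with boundary ticks; the COMBINED
layout overlays gains above and losses below a symmetric zero axis.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .segments import LOSS

SCOPE_GENOME = "GENOME"
LAYOUT_GAINS_ONLY = "GAINS_ONLY"
LAYOUT_LOSSES_ONLY = "LOSSES_ONLY"
LAYOUT_COMBINED = "COMBINED"

_COLORS = ("tab:blue", "tab:orange", "tab:green", "tab:red")


def _chrom_sort_key(label: str):
    try:
        return (0, int(label))
    except ValueError:
        return (1, label)


def _chromosome_offsets(tables) -> dict[str, int]:
    """Cumulative offset per chromosome so the genome lies on one axis."""
    spans: dict[str, int] = {}
    for table in tables:
        for chrom, group in table.groupby("chromosome"):
            spans[chrom] = max(spans.get(chrom, 0), int(group["end"].max()))
    offsets, cursor = {}, 0
    for chrom in sorted(spans, key=_chrom_sort_key):
        offsets[chrom] = cursor
        cursor += spans[chrom]
    return offsets


def _draw(ax, table, offsets, color, label, sign=1.0, band_alpha=0.3):
    first = True
    for chrom, group in table.groupby("chromosome"):
        off = offsets[chrom]
        for _, row in group.iterrows():
            x = (off + row["start"], off + row["end"])
            ax.step(
                x,
                (sign * row["phat"],) * 2,
                where="post",
                color=color,
                label=label if first else None,
            )
            ax.fill_between(
                x,
                (sign * row["ci_low"],) * 2,
                (sign * row["ci_high"],) * 2,
                color=color,
                alpha=band_alpha,
                linewidth=0,
            )
            first = False


def plot_profile(
    profiles,
    out_path,
    scope: str = SCOPE_GENOME,
    layout: str = LAYOUT_GAINS_ONLY,
    band_alpha: float = 0.3,
    title: str | None = None,
):
    """Plot one or more probability profiles to an image file.

    Parameters
    ----------
    profiles : sequence of ProbabilityProfile
        Groups to overlay; harmonize them first if they are compared.
    out_path : path
        Destination image (extension picks the format, e.g. .png/.svg).
    scope : "GENOME" or a chromosome label
        Genome-wide concatenation or a single chromosome.
    layout : {"GAINS_ONLY", "LOSSES_ONLY", "COMBINED"}
        COMBINED renders losses as negative phat on a symmetric axis.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile to plot")
    if layout not in (LAYOUT_GAINS_ONLY, LAYOUT_LOSSES_ONLY, LAYOUT_COMBINED):
        raise ValueError(f"unknown layout {layout!r}")

    tables = []
    for p in profiles:
        t = p.table
        if scope != SCOPE_GENOME:
            t = t[t["chromosome"] == scope]
        tables.append(t)

    fig, ax = plt.subplots(figsize=(12, 4))
    offsets = _chromosome_offsets(tables)

    for p, t, color in zip(profiles, tables, _COLORS):
        label = p.group_label or None
        if layout == LAYOUT_COMBINED:
            _draw(ax, t[t["call"] != LOSS], offsets, color, label, 1.0, band_alpha)
            _draw(ax, t[t["call"] == LOSS], offsets, color, None, -1.0, band_alpha)
        elif layout == LAYOUT_LOSSES_ONLY:
            _draw(ax, t[t["call"] == LOSS], offsets, color, label, 1.0, band_alpha)
        else:
            _draw(ax, t[t["call"] != LOSS], offsets, color, label, 1.0, band_alpha)

    if layout == LAYOUT_COMBINED:
        ax.set_ylim(-1.05, 1.05)
        ax.axhline(0.0, color="black", linewidth=0.5)
    else:
        ax.set_ylim(0, 1.05)
    if scope == SCOPE_GENOME and len(offsets) > 1:
        for chrom, off in offsets.items():
            if off:
                ax.axvline(off, color="grey", linewidth=0.4, linestyle=":")
        ax.set_xticks(list(offsets.values()))
        ax.set_xticklabels(list(offsets.keys()), fontsize=7)
        ax.set_xlabel("chromosome")
    else:
        ax.set_xlabel(f"position on chromosome {scope}" if scope != SCOPE_GENOME else "position (bp)")
    ax.set_ylabel("probability of alteration")
    if any(p.group_label for p in profiles):
        ax.legend(loc="upper right", fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(str(out_path), dpi=150)
    plt.close(fig)
    return out_path
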