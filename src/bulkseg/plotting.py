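"""Genome-wide display of the window scan, with gaps and deletions overlaid."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .types import DeletionCall, LinkageGap, LinkagePeak, WindowCount


def plot_window_counts(
    windows: Sequence[WindowCount],
    peak: LinkagePeak | None = None,
    gaps: Sequence[LinkageGap] = (),
    deletions: Sequence[DeletionCall] = (),
    path: str | None = None,
):
    """One panel per chromosome: positive-site counts per window (bars),
    the peak region shaded, gaps in blue, deletion calls as triangles."""
    chroms: list[str] = []
    for w in windows:
        if w.chrom not in chroms:
            chroms.append(w.chrom)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(10, 1.2 * len(chroms) + 1),
                             sharex=True, squeeze=False)
    by_chrom: dict[str, list[WindowCount]] = {c: [] for c in chroms}
    for w in windows:
        by_chrom[w.chrom].append(w)
    max_count = max((w.count for w in windows), default=1) or 1
    for ax, chrom in zip(axes[:, 0], chroms):
        ws = by_chrom[chrom]
        xs = [w.start / 1e6 for w in ws]
        ys = [w.count for w in ws]
        ax.fill_between(xs, ys, step="mid", color="firebrick", linewidth=0)
        ax.set_ylabel(chrom, rotation=0, ha="right", va="center", fontsize=8)
        ax.set_ylim(0, max_count * 1.1)
        if peak is not None and peak.chrom == chrom:
            ax.axvspan(peak.region_start / 1e6, peak.region_end / 1e6,
                       color="gold", alpha=0.3)
        for g in gaps:
            if g.chrom == chrom:
                ax.axvspan(g.start / 1e6, g.end / 1e6, color="steelblue", alpha=0.4)
        for d in deletions:
            if d.chrom == chrom:
                ax.plot((d.left_bp + d.right_bp) / 2e6, max_count * 1.05, "kv",
                        markersize=5)
    axes[-1, 0].set_xlabel("position (Mb)")
    fig.suptitle("positive SNP/indel counts per sliding window")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
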