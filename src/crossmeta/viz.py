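"""Plots: XY/XYZ contig scatter, triangle (barycentric) plot, cladograms.

Every plot writes a companion ``.tsv`` with the plotted coordinates so that
all displayed values are machine-checkable.  Zero counts cannot be shown on
logarithmic axes, so they are plotted at a small positive floor (0.9 by
default, visually distinct from the smallest real count of 1).
"""

from __future__ import annotations

import math
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from crossmeta.bionj import PhyloTree, TreeNode
from crossmeta.io_ace import InputError
from crossmeta.profile import CrossProfile

__all__ = ["scatter_plot", "triangle_plot", "cladogram_plot", "gnuplot_export"]

DEFAULT_LOG_FLOOR = 0.9


def _write_tsv(path: Path, header: list[str], rows: list[list]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join(str(x) for x in row))
    path.write_text("\n".join(lines) + "\n", newline="\n")


def scatter_plot(
    profile: CrossProfile,
    out: str | Path,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> Path:
    """One marker per contig at its per-sample read counts, log axes.

    Two samples give an XY-plot, three an XYZ-plot with projections of each
    marker onto the coordinate planes.  More than three samples cannot be
    shown this way; build a cladogram instead.
    """
    if log_floor <= 0:
        raise InputError("log_floor must be positive")
    n = len(profile.samples)
    if n not in (2, 3):
        raise InputError(
            "scatter plots support 2 or 3 samples; use a cladogram for more"
        )
    out = Path(out)
    counts = np.asarray(profile.counts, dtype=float)
    plotted = np.where(counts == 0, log_floor, counts)

    rows = [
        [cid] + [float(x) for x in plotted[k]]
        for k, cid in enumerate(profile.contig_ids)
    ]
    _write_tsv(out.with_suffix(out.suffix + ".tsv"),
               ["contig"] + list(profile.samples), rows)

    if n == 2:
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(plotted[:, 0], plotted[:, 1], marker="D", c="0.5",
                   edgecolors="0.3", s=25)
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel(f"reads from {profile.samples[0]}")
        ax.set_ylabel(f"reads from {profile.samples[1]}")
    else:
        fig = plt.figure(figsize=(6, 6))
        ax = fig.add_subplot(projection="3d")
        logged = np.log10(plotted)
        ax.scatter(logged[:, 0], logged[:, 1], logged[:, 2], marker="D",
                   c="0.5", s=25, depthshade=False)
        floor = math.log10(log_floor)
        # projections onto the three coordinate planes
        ax.scatter(logged[:, 0], logged[:, 1], np.full(len(logged), floor),
                   marker=".", c="k", s=4)
        ax.scatter(logged[:, 0], np.full(len(logged), floor), logged[:, 2],
                   marker=".", c="k", s=4)
        ax.scatter(np.full(len(logged), floor), logged[:, 1], logged[:, 2],
                   marker=".", c="k", s=4)
        ax.set_xlabel(f"log10 reads, {profile.samples[0]}")
        ax.set_ylabel(f"log10 reads, {profile.samples[1]}")
        ax.set_zlabel(f"log10 reads, {profile.samples[2]}")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def triangle_plot(profile: CrossProfile, out: str | Path) -> Path:
    """Contigs at barycentric coordinates of their three read counts.

    Marker area scales with the contig's total read count, so heavy contigs
    stand out; a contig fed by a single sample sits on that sample's vertex.
    """
    if len(profile.samples) != 3:
        raise InputError("triangle plot needs exactly 3 samples")
    out = Path(out)
    counts = np.asarray(profile.counts, dtype=float)
    totals = counts.sum(axis=1)
    bary = counts / totals[:, None]
    # equilateral triangle vertices
    verts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, math.sqrt(3) / 2]])
    xy = bary @ verts

    rows = [
        [cid, xy[k, 0], xy[k, 1], int(totals[k])]
        + [float(b) for b in bary[k]]
        for k, cid in enumerate(profile.contig_ids)
    ]
    _write_tsv(
        out.with_suffix(out.suffix + ".tsv"),
        ["contig", "x", "y", "total_reads"] + [f"frac_{s}" for s in profile.samples],
        rows,
    )

    fig, ax = plt.subplots(figsize=(6, 5.5))
    tri = plt.Polygon(verts, fill=False, edgecolor="k")
    ax.add_patch(tri)
    ax.scatter(xy[:, 0], xy[:, 1], s=8 + 4 * np.sqrt(totals), marker="D",
               c="0.5", edgecolors="0.3", alpha=0.8)
    for (x, y), label, (ha, va) in zip(
        verts, profile.samples, [("right", "top"), ("left", "top"), ("center", "bottom")]
    ):
        ax.annotate(label, (x, y), ha=ha, va=va)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def gnuplot_export(
    profile: CrossProfile,
    out_prefix: str | Path,
    log_floor: float = DEFAULT_LOG_FLOOR,
) -> tuple[Path, Path]:
    """Write a Gnuplot-compatible data file and driver script.

    Produces ``<prefix>.dat`` (one line per contig, per-sample counts with
    zeros replaced by ``log_floor``) and ``<prefix>.gp`` (a ``splot``/``plot``
    script on logarithmic axes), for users who prefer the classic toolchain
    over the native matplotlib output.
    """
    if log_floor <= 0:
        raise InputError("log_floor must be positive")
    n = len(profile.samples)
    if n not in (2, 3):
        raise InputError("gnuplot export supports 2 or 3 samples")
    prefix = Path(out_prefix)
    counts = np.asarray(profile.counts, dtype=float)
    plotted = np.where(counts == 0, log_floor, counts)

    dat = prefix.with_suffix(".dat")
    lines = ["# " + "\t".join(profile.samples)]
    for row in plotted:
        lines.append("\t".join(f"{x:g}" for x in row))
    dat.write_text("\n".join(lines) + "\n", newline="\n")

    gp = prefix.with_suffix(".gp")
    if n == 2:
        body = [
            "set logscale xy",
            f'set xlabel "{profile.samples[0]}"',
            f'set ylabel "{profile.samples[1]}"',
            f'plot "{dat.name}" using 1:2 with points pt 12 notitle',
        ]
    else:
        body = [
            "set logscale xyz",
            f'set xlabel "{profile.samples[0]}"',
            f'set ylabel "{profile.samples[1]}"',
            f'set zlabel "{profile.samples[2]}"',
            f'splot "{dat.name}" using 1:2:3 with points pt 12 notitle',
        ]
    gp.write_text("\n".join(body) + "\n", newline="\n")
    return dat, gp


def _equal_angle_layout(tree: PhyloTree, unit_lengths: bool) -> dict[int, tuple]:
    """Equal-angle layout of an unrooted tree; returns id(node) -> (x, y)."""
    counts: dict[int, int] = {}

    def count(node: TreeNode) -> int:
        if node.is_leaf:
            counts[id(node)] = 1
        else:
            counts[id(node)] = sum(count(c) for c, _ in node.children)
        return counts[id(node)]

    total = count(tree.root)
    pos: dict[int, tuple] = {id(tree.root): (0.0, 0.0)}

    def place(node: TreeNode, x: float, y: float, lo: float, hi: float) -> None:
        angle = lo
        for child, length in node.children:
            span = (hi - lo) * counts[id(child)] / max(counts[id(node)], 1)
            mid = angle + span / 2.0
            step = 1.0 if unit_lengths else max(length, 0.0)
            cx = x + step * math.cos(mid)
            cy = y + step * math.sin(mid)
            pos[id(child)] = (cx, cy)
            place(child, cx, cy, angle, angle + span)
            angle += span

    place(tree.root, 0.0, 0.0, 0.0, 2.0 * math.pi)
    return pos


def cladogram_plot(
    tree: PhyloTree, out: str | Path, with_branch_lengths: bool = True
) -> Path:
    """Unrooted (equal-angle) cladogram image.

    With ``with_branch_lengths=False`` every edge is drawn at unit length so
    topology stays readable when internal branches are short.
    """
    out = Path(out)
    pos = _equal_angle_layout(tree, unit_lengths=not with_branch_lengths)

    rows = []

    def collect(node: TreeNode) -> None:
        x, y = pos[id(node)]
        rows.append([node.name or "", f"{x:.6f}", f"{y:.6f}"])
        for child, _ in node.children:
            collect(child)

    collect(tree.root)
    _write_tsv(out.with_suffix(out.suffix + ".tsv"), ["label", "x", "y"], rows)

    fig, ax = plt.subplots(figsize=(6, 6))

    def draw(node: TreeNode) -> None:
        x, y = pos[id(node)]
        for child, _ in node.children:
            cx, cy = pos[id(child)]
            ax.plot([x, cx], [y, cy], color="k", lw=1)
            draw(child)
        if node.is_leaf:
            ax.annotate(node.name or "", (x, y), fontsize=9,
                        ha="center", va="bottom")

    draw(tree.root)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
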