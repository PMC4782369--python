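"""Rendering and text export: heat maps, cluster trees, circular neighbor
diagrams, and the tab-separated matrix dialect.

Heat maps use a diverging blue-white-red palette anchored at 0 (blue, no
covariation), 0.5 (white, moderate) and 1 (red, complete covariation); for
joint entropy the palette is reversed so 0 (complete joint conservation)
renders red.  Cluster-tree leaves are colored by a fixed hydropathy classing
of the query residue.  Circular diagrams are plain SVG.
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.colors import LinearSegmentedColormap

from .cluster import Dendrogram
from .covariance import MetricMatrix
from .errors import InputError, ResidueLookupError
from .msa_io import Alignment, ResidueNumbering

#: Hydropathy classes for leaf coloring (configurable module constant).
HYDROPATHY_CLASSES = {
    "hydrophobic": set("AVLIMFWC"),
    "polar": set("STNQYGPH"),
    "positive": set("KR"),
    "negative": set("DE"),
}

HYDROPATHY_COLORS = {
    "hydrophobic": "#808080",  # grey
    "polar": "#2ca02c",  # green
    "positive": "#1f77b4",  # blue
    "negative": "#d62728",  # red
    "other": "#000000",
}


def hydropathy_class(aa: str) -> str:
    for cls, members in HYDROPATHY_CLASSES.items():
        if aa.upper() in members:
            return cls
    return "other"


def heatmap_colormap(metric: str):
    """Blue->white->red anchored at 0/0.5/1; reversed for joint entropy."""
    colors = ["#0000ff", "#ffffff", "#ff0000"]
    if metric == "jentropy":
        colors = colors[::-1]
    return LinearSegmentedColormap.from_list(f"coevol_{metric}", colors)


# ---------------------------------------------------------------------------
# neighbor selection
# ---------------------------------------------------------------------------

@dataclass
class NeighborSet:
    focus: str
    cutoff: float
    members: list[tuple[str, float]]  # sorted by descending score


def select_neighbors(m: MetricMatrix, residue: str, cutoff: float = 0.3) -> NeighborSet:
    """Off-diagonal partners of ``residue`` with score >= cutoff, descending.

    The default 0.3 cutoff matches the convention used for chi-square
    cumulative probabilities; ties are broken by position order.
    """
    idx = m.labels.index_of(residue)
    pairs = []
    for j in range(m.size):
        if j == idx:
            continue
        score = float(m.values[idx, j])
        if score >= cutoff:
            pairs.append((m.labels[j], score))
    pairs.sort(key=lambda t: -t[1])
    return NeighborSet(focus=residue, cutoff=cutoff, members=pairs)


# ---------------------------------------------------------------------------
# heat map
# ---------------------------------------------------------------------------

def render_heatmap(
    m: MetricMatrix,
    out: str | Path,
    region: Optional[tuple[int, int, int, int]] = None,
) -> None:
    """Write a PNG heat map of the matrix.

    ``region`` is a (row_start, row_stop, col_start, col_stop) crop in
    0-based half-open coordinates, standing in for interactive zoom.
    """
    v = m.values
    labels = list(m.labels.labels)
    if region is not None:
        r0, r1, c0, c1 = region
        if not (0 <= r0 < r1 <= m.size and 0 <= c0 < c1 <= m.size):
            raise InputError(f"region {region} out of bounds for L={m.size}")
        v = v[r0:r1, c0:c1]
        row_labels = labels[r0:r1]
        col_labels = labels[c0:c1]
    else:
        row_labels = col_labels = labels

    fig, ax = plt.subplots(
        figsize=(max(4, min(12, v.shape[1] * 0.25)), max(4, min(12, v.shape[0] * 0.25)))
    )
    im = ax.imshow(v, cmap=heatmap_colormap(m.metric), vmin=0.0, vmax=1.0)
    step_r = max(1, len(row_labels) // 40)
    step_c = max(1, len(col_labels) // 40)
    ax.set_xticks(range(0, len(col_labels), step_c))
    ax.set_xticklabels(col_labels[::step_c], rotation=90, fontsize=6)
    ax.set_yticks(range(0, len(row_labels), step_r))
    ax.set_yticklabels(row_labels[::step_r], fontsize=6)
    ax.set_title(f"{m.metric} ({m.weighting} weighting)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cluster tree
# ---------------------------------------------------------------------------

def render_tree(t: Dendrogram, aln: Alignment, out: str | Path) -> None:
    """Write a PNG dendrogram with hydropathy-colored leaf labels.

    Leaf labels read residue letter + residue label ("E171" style); the
    leaf ordering comes from the merge structure.
    """
    from scipy.cluster.hierarchy import dendrogram as _scipy_dendrogram

    numbering = ResidueNumbering(list(t.leaves))
    if len(numbering) != aln.length:
        raise InputError("dendrogram leaves do not match alignment length")
    Z = t.to_linkage()
    leaf_text = [f"{aln.query_seq[i]}{numbering[i]}" for i in range(aln.length)]

    fig, ax = plt.subplots(figsize=(max(5, min(20, aln.length * 0.2)), 5))
    dd = _scipy_dendrogram(
        Z,
        ax=ax,
        labels=list(range(aln.length)),
        color_threshold=0.0,
        link_color_func=lambda _: "#555555",
    )
    ax.set_xticklabels(
        [leaf_text[i] for i in dd["leaves"]], rotation=90, fontsize=7
    )
    for tick, i in zip(ax.get_xticklabels(), dd["leaves"]):
        tick.set_color(HYDROPATHY_COLORS[hydropathy_class(aln.query_seq[i])])
    ax.set_ylabel("complete-linkage distance")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# circular neighbor diagram (SVG)
# ---------------------------------------------------------------------------

SVG_NS = "http://www.w3.org/2000/svg"


def render_circular(n: NeighborSet, out: str | Path) -> None:
    """Write an SVG circular diagram: focus + members on a circle, chords
    from the focus to each member with width/opacity scaled by score.

    Members are placed clockwise from the top in descending-score order.
    An empty member set still produces a valid file with the focus alone.
    """
    size = 480.0
    cx = cy = size / 2
    radius = size * 0.38
    ET.register_namespace("", SVG_NS)
    svg = ET.Element(
        f"{{{SVG_NS}}}svg",
        {"width": str(int(size)), "height": str(int(size)),
         "viewBox": f"0 0 {int(size)} {int(size)}"},
    )
    k = len(n.members)
    # focus at the top; members fill the remaining circle positions
    angles = [-math.pi / 2 + 2 * math.pi * t / (k + 1) for t in range(k + 1)]
    coords = [(cx + radius * math.cos(a), cy + radius * math.sin(a)) for a in angles]
    fx, fy = coords[0]
    max_score = max((s for _, s in n.members), default=1.0) or 1.0
    for (label, score), (x, y) in zip(n.members, coords[1:]):
        frac = max(score / max_score, 0.05)
        chord = ET.SubElement(
            svg, f"{{{SVG_NS}}}line",
            {"x1": f"{fx:.2f}", "y1": f"{fy:.2f}", "x2": f"{x:.2f}", "y2": f"{y:.2f}",
             "stroke": "#d62728", "stroke-width": f"{1 + 4 * frac:.2f}",
             "stroke-opacity": f"{0.25 + 0.75 * frac:.3f}",
             "class": "chord"},
        )
        chord.set("data-score", f"{score:.6f}")
    for idx, ((x, y), label) in enumerate(
        zip(coords, [n.focus] + [lab for lab, _ in n.members])
    ):
        g = ET.SubElement(svg, f"{{{SVG_NS}}}g", {"class": "node"})
        ET.SubElement(
            g, f"{{{SVG_NS}}}circle",
            {"cx": f"{x:.2f}", "cy": f"{y:.2f}", "r": "14",
             "fill": "#1f77b4" if idx == 0 else "#ffffff",
             "stroke": "#333333"},
        )
        txt = ET.SubElement(
            g, f"{{{SVG_NS}}}text",
            {"x": f"{x:.2f}", "y": f"{y + 4:.2f}", "text-anchor": "middle",
             "font-size": "10", "fill": "#000000" if idx else "#ffffff"},
        )
        txt.text = label
    ET.ElementTree(svg).write(str(out), xml_declaration=True, encoding="unicode")


# ---------------------------------------------------------------------------
# TSV matrix dialect
# ---------------------------------------------------------------------------

def export_matrix_tsv(m: MetricMatrix, out: str | Path) -> None:
    """Write the matrix in the toolkit's tab-separated dialect.

    '#'-prefixed metadata lines, a header row of residue labels, then one row
    per residue: label + L values at 6 decimal places.  Tab is the only
    delimiter, so labels may contain spaces.
    """
    with open(out, "w") as fh:
        fh.write(f"# metric\t{m.metric}\n")
        fh.write(f"# weighting\t{m.weighting}\n")
        fh.write(f"# normalized\t{str(m.normalized).lower()}\n")
        fh.write(f"# diagonal_kind\t{m.diagonal_kind}\n")
        fh.write(f"# similarity_source\t{m.similarity_source}\n")
        fh.write("\t" + "\t".join(m.labels.labels) + "\n")
        for i, lab in enumerate(m.labels.labels):
            vals = "\t".join(f"{v:.6f}" for v in m.values[i])
            fh.write(f"{lab}\t{vals}\n")


def read_matrix_tsv(path: str | Path) -> MetricMatrix:
    """Parse a matrix written by :func:`export_matrix_tsv`."""
    meta: dict[str, str] = {}
    header: Optional[list[str]] = None
    rows: list[list[float]] = []
    row_labels: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2:
                    meta[parts[0].strip()] = parts[1]
                continue
            fields = line.split("\t")
            if header is None:
                header = fields[1:]
                continue
            row_labels.append(fields[0])
            try:
                rows.append([float(x) for x in fields[1:]])
            except ValueError as exc:
                raise InputError(f"non-numeric matrix cell in {path}") from exc
    if header is None or not rows:
        raise InputError(f"no matrix data found in {path}")
    if row_labels != header or any(len(r) != len(header) for r in rows):
        raise InputError("matrix TSV is not square with matching labels")
    for key in ("metric", "weighting", "normalized", "diagonal_kind"):
        if key not in meta:
            raise InputError(f"matrix TSV missing metadata line '# {key}'")
    return MetricMatrix(
        metric=meta["metric"],
        weighting=meta["weighting"],
        values=np.array(rows),
        diagonal_kind=meta["diagonal_kind"],
        normalized=meta["normalized"] == "true",
        labels=ResidueNumbering(header),
        similarity_source=meta.get("similarity_source", "n/a"),
    )
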