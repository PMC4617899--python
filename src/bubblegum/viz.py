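"""Static rendering: the bubble-matrix figure and the 5-color heatmap.

Bubble semantics: one glyph per (gene set, comparison) cell; circle *area*
proportional to |NES| (radius proportional to sqrt(|NES|)); fill color names
the enriched side of the comparison; color intensity (opacity) grows with
significance, saturating at a floor FDR; cells whose FDR exceeds the display
threshold are drawn as outline-only circles of the same area.  Cells with an
undefined NES are drawn as crossed markers and listed in a sidecar log.

SVG output is generated by a small deterministic emitter (fixed float
formatting, no timestamps) so repeated renders of the same grid and style
are byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import ExpressionDataset, ValidationError
from .genesign import Signature
from .bubblemap import BubbleMapResult

__all__ = ["BubbleStyle", "render_bubblemap", "render_heatmap"]

_CLASS_PALETTE = [
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd", "#ff7f0e",
    "#8c564b", "#e377c2", "#17becf", "#bcbd22", "#7f7f7f",
]
_HEATMAP_COLORS = ["#2166ac", "#92c5de", "#f7f7f7", "#f4a582", "#b2182b"]
_Z_CUTS = [-1.5, -0.5, 0.5, 1.5]


@dataclass
class BubbleStyle:
    """Visual mapping of a bubble map.

    ``radius_scale`` is in pixels per unit sqrt(|NES|), so bubble area stays
    proportional to |NES|.  ``intensity_floor_fdr`` is the FDR at which the
    color reaches full saturation.
    """

    fdr_display_threshold: float = 0.25
    radius_scale: float = 7.0
    intensity_floor_fdr: float = 1e-3
    min_alpha: float = 0.15
    cell: int = 30
    class_colors: dict[str, str] = field(default_factory=dict)

    def color_of(self, label: str, classes: list[str]) -> str:
        if label in self.class_colors:
            return self.class_colors[label]
        return _CLASS_PALETTE[classes.index(label) % len(_CLASS_PALETTE)]

    def alpha_of(self, fdr: float) -> float:
        if fdr <= 0:
            return 1.0
        a = math.log10(fdr) / math.log10(self.intensity_floor_fdr)
        return min(1.0, max(self.min_alpha, a))

    def radius_of(self, nes: float) -> float:
        return min(self.radius_scale * math.sqrt(abs(nes)), self.cell / 2 - 1)


def _f(x: float) -> str:
    return f"{x:.2f}"


def render_bubblemap(grid: BubbleMapResult, style: BubbleStyle | None = None,
                     path: str | Path = "bubblemap.svg") -> Path:
    """Write the bubble-matrix figure as SVG (byte-stable) or PNG.

    Undefined-NES cells are drawn as crossed markers and listed in a sidecar
    ``<path>.log`` file.
    """
    if style is None:
        style = BubbleStyle()
    path = Path(path)
    cells = grid.cells
    if len(cells) == 0:
        raise ValidationError("refusing to render an empty grid view")
    classes = grid.metadata.get("classes", sorted({*cells["left"], *cells["right"]}))
    view = grid.metadata.get("view") or {}
    rows = view.get("row_order") or list(dict.fromkeys(cells["set"]))
    cols = [tuple(c) for c in view.get("col_order") or []] or \
        list(dict.fromkeys(zip(cells["left"], cells["right"])))
    if path.suffix.lower() == ".png":
        return _render_png(grid, style, path, rows, cols, classes)

    c = style.cell
    left_margin = 10 + int(max(len(r) for r in rows) * 6.5)
    top_margin = 16 + int(max(len(f"{l} vs {r}") for l, r in cols) * 4.6)
    legend_h = 70
    width = left_margin + c * len(cols) + 20
    height = top_margin + c * len(rows) + legend_h

    out = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
        '<style>text{font-family:Helvetica,Arial,sans-serif;font-size:10px;}</style>',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    for j, (l, r) in enumerate(cols):
        x = left_margin + c * j + c / 2
        out.append(
            f'<text x="{_f(x)}" y="{_f(top_margin - 6)}" '
            f'transform="rotate(-45 {_f(x)} {_f(top_margin - 6)})">{l} vs {r}</text>')
    for i, name in enumerate(rows):
        y = top_margin + c * i + c / 2 + 3
        out.append(f'<text x="4" y="{_f(y)}">{name}</text>')

    undefined: list[str] = []
    cell_index = {(s, l, r): idx for idx, (s, l, r)
                  in enumerate(zip(cells["set"], cells["left"], cells["right"]))}
    for i, name in enumerate(rows):
        for j, (l, r) in enumerate(cols):
            idx = cell_index.get((name, l, r))
            if idx is None:
                continue
            row = cells.iloc[idx]
            cx = left_margin + c * j + c / 2
            cy = top_margin + c * i + c / 2
            if np.isnan(row["nes"]):
                undefined.append(f"{name}\t{l} vs {r}")
                d = c / 4
                out.append(f'<line x1="{_f(cx - d)}" y1="{_f(cy - d)}" x2="{_f(cx + d)}" '
                           f'y2="{_f(cy + d)}" stroke="#888" stroke-width="1.5"/>')
                out.append(f'<line x1="{_f(cx - d)}" y1="{_f(cy + d)}" x2="{_f(cx + d)}" '
                           f'y2="{_f(cy - d)}" stroke="#888" stroke-width="1.5"/>')
                continue
            color = style.color_of(row["enriched_side"], classes)
            radius = style.radius_of(row["nes"])
            if row["fdr"] > style.fdr_display_threshold:
                out.append(f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(radius)}" '
                           f'fill="none" stroke="{color}" stroke-width="1.2"/>')
            else:
                alpha = style.alpha_of(float(row["fdr"]))
                out.append(f'<circle cx="{_f(cx)}" cy="{_f(cy)}" r="{_f(radius)}" '
                           f'fill="{color}" fill-opacity="{_f(alpha)}" '
                           f'stroke="{color}" stroke-width="0.8"/>')

    # legend: size references and intensity ramp
    ly = top_margin + c * len(rows) + 22
    lx = left_margin
    out.append(f'<text x="{_f(lx)}" y="{_f(ly - 12)}">|NES| (area)   /   FDR (intensity), '
               f'empty circle: FDR &gt; {style.fdr_display_threshold:g}</text>')
    for k, v in enumerate((1.0, 2.0, 3.0)):
        cx = lx + 14 + 40 * k
        out.append(f'<circle cx="{_f(cx)}" cy="{_f(ly + 10)}" r="{_f(style.radius_of(v))}" '
                   f'fill="#555"/>')
        out.append(f'<text x="{_f(cx - 4)}" y="{_f(ly + 34)}">{v:g}</text>')
    for k, fdr in enumerate((0.25, 0.05, 0.001)):
        cx = lx + 160 + 40 * k
        out.append(f'<circle cx="{_f(cx)}" cy="{_f(ly + 10)}" r="{_f(style.radius_of(2.0))}" '
                   f'fill="#1f77b4" fill-opacity="{_f(style.alpha_of(fdr))}"/>')
        out.append(f'<text x="{_f(cx - 10)}" y="{_f(ly + 34)}">{fdr:g}</text>')
    out.append("</svg>")
    path.write_text("\n".join(out) + "\n")
    if undefined:
        Path(str(path) + ".log").write_text(
            "undefined NES cells (crossed markers):\n" + "\n".join(undefined) + "\n")
    return path


def _render_png(grid: BubbleMapResult, style: BubbleStyle, path: Path,
                rows: list[str], cols: list[tuple[str, str]],
                classes: list[str]) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cells = grid.cells
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.32 * len(cols), 1.5 + 0.32 * len(rows)), dpi=150)
    row_of = {n: i for i, n in enumerate(rows)}
    col_of = {p: j for j, p in enumerate(cols)}
    for _, row in cells.iterrows():
        j = col_of[(row["left"], row["right"])]
        i = row_of[row["set"]]
        if np.isnan(row["nes"]):
            ax.plot(j, i, marker="x", color="#888", ms=6)
            continue
        color = style.color_of(row["enriched_side"], classes)
        r = style.radius_of(row["nes"])
        if row["fdr"] > style.fdr_display_threshold:
            ax.scatter(j, i, s=(2 * r) ** 2, facecolors="none", edgecolors=color)
        else:
            ax.scatter(j, i, s=(2 * r) ** 2, color=color,
                       alpha=style.alpha_of(float(row["fdr"])))
    ax.set_xticks(range(len(cols)), [f"{l} vs {r}" for l, r in cols],
                  rotation=45, ha="right", fontsize=7)
    ax.set_yticks(range(len(rows)), rows, fontsize=7)
    ax.set_xlim(-0.5, len(cols) - 0.5)
    ax.set_ylim(len(rows) - 0.5, -0.5)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return path


def render_heatmap(signature: Signature, dataset: ExpressionDataset,
                   path: str | Path) -> Path:
    """5-color expression heatmap of a signature.

    Rows follow the signature order; columns are samples grouped by class
    with an annotation bar.  Each gene is z-scored across samples and binned
    at z = -1.5, -0.5, 0.5, 1.5; a flat gene falls in the middle bin.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if len(signature) == 0:
        raise ValidationError("cannot render a heatmap of an empty signature")
    idx = dataset.gene_index()
    missing = [g for g in signature.genes if g not in idx]
    if missing:
        raise ValidationError(f"signature genes absent from dataset: {missing[:5]}")
    order = np.concatenate([dataset.samples_of(c) for c in dataset.classes])
    X = np.array([dataset.values[idx[g]][order] for g in signature.genes])
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)

    cmap = ListedColormap(_HEATMAP_COLORS)
    norm = BoundaryNorm([-np.inf, *_Z_CUTS, np.inf], cmap.N)
    fig, (ax_bar, ax) = plt.subplots(
        2, 1, figsize=(1.2 + 0.25 * X.shape[1], 1.0 + 0.22 * X.shape[0]),
        height_ratios=[1, max(4, X.shape[0])], sharex=True, dpi=150)
    classes_row = np.array([[dataset.classes.index(
        dataset.class_of[dataset.sample_names[i]]) for i in order]])
    ax_bar.imshow(classes_row, aspect="auto", cmap="tab10", vmin=0, vmax=9,
                  interpolation="nearest")
    ax_bar.set_yticks([])
    ax.imshow(z, aspect="auto", cmap=cmap, norm=norm, interpolation="nearest")
    ax.set_yticks(range(len(signature.genes)), signature.genes, fontsize=6)
    ax.set_xticks(range(X.shape[1]),
                  [dataset.sample_names[i] for i in order],
                  rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def heatmap_bins(signature: Signature, dataset: ExpressionDataset) -> np.ndarray:
    """The 5-level bin matrix (0..4) the heatmap draws; exposed for testing
    and for text export."""
    idx = dataset.gene_index()
    order = np.concatenate([dataset.samples_of(c) for c in dataset.classes])
    X = np.array([dataset.values[idx[g]][order] for g in signature.genes])
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return np.digitize(z, _Z_CUTS)
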