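"""Rendering of the three standard views of a differential result.

* ``limpet_plot`` — circular bipartite view: TFs on the upper arc in
  functional-group order, genes with at least one significant change on
  the lower arc, one colored chord per flagged TF-gene pair.  Blue means
  the interaction is stronger in the reference (wild-type) condition,
  red stronger in the alternate (knock-out).
* ``strength_plot`` — per-TF change in a summary quantity (average
  strength or concentration) with dashed guides at the median +/- k SD.
* ``change_heatmap`` — TFs x datasets matrix, darker = larger value,
  rows in functional-group order.

SVG is the canonical output: every figure is first built as a list of
primitive shapes and then serialized with fixed number formatting, so
identical inputs produce byte-identical files (which the test suite and
the pipeline's checksum manifest rely on).  In the SVG, ``<line>``
elements are reserved for data chords; axes and guides use ``<path>``.
PNG output rasterizes the same primitives through matplotlib.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .differential import REGULATION_DOWN, DifferentialResult
from .errors import ValidationError
from .io import TFAnnotation

# Okabe-Ito colorblind-safe cycle for functional groups
_DEFAULT_PALETTE = [
    "#E69F00", "#56B4E9", "#009E73", "#F0E442",
    "#0072B2", "#D55E00", "#CC79A7", "#999999",
]


@dataclass
class PlotSpec:
    width: int = 900
    height: int = 700
    color_up: str = "#d62728"      # stronger in the perturbed condition
    color_down: str = "#1f77b4"    # stronger in the reference condition
    color_neutral: str = "#aaaaaa"
    group_palette: list[str] = field(default_factory=lambda: list(_DEFAULT_PALETTE))
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValidationError("plot dimensions must be positive")
        if self.output_format not in ("svg", "png"):
            raise ValidationError("output_format must be 'svg' or 'png'")
        if not self.group_palette:
            raise ValidationError("group_palette must not be empty")

    def group_color(self, group_index: int) -> str:
        return self.group_palette[group_index % len(self.group_palette)]


def _f(x: float) -> str:
    return f"{x:.2f}"


# ---------------------------------------------------------------------------
# scene primitives: dicts with a "kind" key, serialized to SVG or matplotlib


def _line(x1, y1, x2, y2, color, width=1.0, cls=""):
    return {"kind": "line", "x1": x1, "y1": y1, "x2": x2, "y2": y2,
            "color": color, "width": width, "cls": cls}


def _path(points, color, width=1.0, dashed=False):
    return {"kind": "path", "points": points, "color": color, "width": width, "dashed": dashed}


def _arc(cx, cy, r, a0, a1, color, width=6.0):
    return {"kind": "arc", "cx": cx, "cy": cy, "r": r, "a0": a0, "a1": a1,
            "color": color, "width": width}


def _rect(x, y, w, h, fill, stroke="none", value=None):
    return {"kind": "rect", "x": x, "y": y, "w": w, "h": h, "fill": fill,
            "stroke": stroke, "value": value}


def _circle(cx, cy, r, fill):
    return {"kind": "circle", "cx": cx, "cy": cy, "r": r, "fill": fill}


def _text(x, y, s, size=11, color="#222222", anchor="middle"):
    return {"kind": "text", "x": x, "y": y, "s": s, "size": size,
            "color": color, "anchor": anchor}


def _svg_element(p) -> str:
    k = p["kind"]
    if k == "line":
        cls = f' class="{p["cls"]}"' if p["cls"] else ""
        return (f'<line{cls} x1="{_f(p["x1"])}" y1="{_f(p["y1"])}" '
                f'x2="{_f(p["x2"])}" y2="{_f(p["y2"])}" '
                f'stroke="{p["color"]}" stroke-width="{_f(p["width"])}" />')
    if k == "path":
        d = "M " + " L ".join(f"{_f(x)} {_f(y)}" for x, y in p["points"])
        dash = ' stroke-dasharray="6 4"' if p["dashed"] else ""
        return (f'<path d="{d}" fill="none" stroke="{p["color"]}" '
                f'stroke-width="{_f(p["width"])}"{dash} />')
    if k == "arc":
        x0 = p["cx"] + p["r"] * math.cos(p["a0"])
        y0 = p["cy"] - p["r"] * math.sin(p["a0"])
        x1 = p["cx"] + p["r"] * math.cos(p["a1"])
        y1 = p["cy"] - p["r"] * math.sin(p["a1"])
        large = 1 if abs(p["a1"] - p["a0"]) > math.pi else 0
        sweep = 1 if p["a1"] < p["a0"] else 0
        return (f'<path d="M {_f(x0)} {_f(y0)} A {_f(p["r"])} {_f(p["r"])} 0 '
                f'{large} {sweep} {_f(x1)} {_f(y1)}" fill="none" '
                f'stroke="{p["color"]}" stroke-width="{_f(p["width"])}" />')
    if k == "rect":
        val = f' data-value="{p["value"]:.6g}"' if p["value"] is not None else ""
        return (f'<rect x="{_f(p["x"])}" y="{_f(p["y"])}" width="{_f(p["w"])}" '
                f'height="{_f(p["h"])}" fill="{p["fill"]}" stroke="{p["stroke"]}"{val} />')
    if k == "circle":
        return (f'<circle cx="{_f(p["cx"])}" cy="{_f(p["cy"])}" r="{_f(p["r"])}" '
                f'fill="{p["fill"]}" />')
    if k == "text":
        return (f'<text x="{_f(p["x"])}" y="{_f(p["y"])}" font-size="{p["size"]}" '
                f'font-family="sans-serif" fill="{p["color"]}" '
                f'text-anchor="{p["anchor"]}">{p["s"]}</text>')
    raise ValidationError(f"unknown primitive {k!r}")


def _render_svg(scene, spec: PlotSpec, out_path) -> None:
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width}" '
        f'height="{spec.height}" viewBox="0 0 {spec.width} {spec.height}">',
        f'<rect x="0" y="0" width="{spec.width}" height="{spec.height}" '
        f'fill="#ffffff" stroke="none" />',
    ]
    lines.extend(_svg_element(p) for p in scene)
    lines.append("</svg>")
    with open(out_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _render_png(scene, spec: PlotSpec, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import patches

    dpi = 100.0
    fig, ax = plt.subplots(figsize=(spec.width / dpi, spec.height / dpi), dpi=dpi)
    ax.set_xlim(0, spec.width)
    ax.set_ylim(spec.height, 0)  # SVG coordinates: y grows downward
    ax.axis("off")
    for p in scene:
        k = p["kind"]
        if k == "line":
            ax.plot([p["x1"], p["x2"]], [p["y1"], p["y2"]],
                    color=p["color"], linewidth=p["width"])
        elif k == "path":
            xs, ys = zip(*p["points"])
            ax.plot(xs, ys, color=p["color"], linewidth=p["width"],
                    linestyle="--" if p["dashed"] else "-")
        elif k == "arc":
            deg0, deg1 = math.degrees(p["a0"]), math.degrees(p["a1"])
            ax.add_patch(patches.Arc(
                (p["cx"], p["cy"]), 2 * p["r"], 2 * p["r"],
                theta1=min(deg0, deg1), theta2=max(deg0, deg1),
                color=p["color"], linewidth=p["width"]))
        elif k == "rect":
            ax.add_patch(patches.Rectangle(
                (p["x"], p["y"]), p["w"], p["h"], facecolor=p["fill"],
                edgecolor=None if p["stroke"] == "none" else p["stroke"]))
        elif k == "circle":
            ax.add_patch(patches.Circle((p["cx"], p["cy"]), p["r"], facecolor=p["fill"]))
        elif k == "text":
            ha = {"middle": "center", "start": "left", "end": "right"}[p["anchor"]]
            ax.text(p["x"], p["y"], p["s"], fontsize=p["size"] * 72 / dpi,
                    color=p["color"], ha=ha, va="center")
    fig.savefig(out_path, dpi=dpi)
    plt.close(fig)


def _render(scene, spec: PlotSpec, out_path) -> None:
    if spec.output_format == "png":
        _render_png(scene, spec, out_path)
    else:
        _render_svg(scene, spec, out_path)


# ---------------------------------------------------------------------------
# figures


def _group_runs(tf_order, annotation: TFAnnotation):
    """Contiguous runs of TFs sharing a functional group, in display order."""
    runs = []
    for i, tf in enumerate(tf_order):
        idx, name = annotation.group_of(tf)
        if runs and runs[-1][0] == idx:
            runs[-1][2].append(i)
        else:
            runs.append((idx, name, [i]))
    return runs


def limpet_plot(
    result: DifferentialResult,
    annotation: TFAnnotation | None = None,
    spec: PlotSpec | None = None,
    out_path="limpet.svg",
) -> int:
    """Circular bipartite view of the flagged TF-gene changes.

    Returns the number of chords drawn.  With zero flagged pairs an
    empty frame with a message is still written.
    """
    annotation = annotation or TFAnnotation()
    spec = spec or PlotSpec()
    cx, cy = spec.width / 2.0, spec.height / 2.0
    radius = 0.38 * min(spec.width, spec.height)

    tf_order = annotation.order(result.tf_ids)
    genes = result.flagged_genes
    scene = []

    # TF anchor positions on the upper semicircle, left to right
    n_tf = len(tf_order)
    tf_xy = {}
    for i, tf in enumerate(tf_order):
        a = math.pi - math.pi * (i + 0.5) / n_tf
        tf_xy[tf] = (cx + radius * math.cos(a), cy - radius * math.sin(a))

    # functional-group arcs along the upper perimeter
    for idx, name, members in _group_runs(tf_order, annotation):
        a0 = math.pi - math.pi * members[0] / n_tf
        a1 = math.pi - math.pi * (members[-1] + 1) / n_tf
        scene.append(_arc(cx, cy, radius + 14, a0, a1, spec.group_color(idx), width=8.0))

    gene_xy = {}
    if genes:
        n_g = len(genes)
        for i, g in enumerate(genes):
            a = math.pi + math.pi * (i + 0.5) / n_g
            gene_xy[g] = (cx + radius * math.cos(a), cy - radius * math.sin(a))
        scene.append(_arc(cx, cy, radius + 14, math.pi, 2 * math.pi, "#cccccc", width=4.0))

    # chords: one <line> per flagged pair, color encodes the sign of D
    for pair in result.flagged_pairs:
        x1, y1 = tf_xy[pair.tf_id]
        x2, y2 = gene_xy[pair.gene_id]
        color = spec.color_down if pair.regulation == REGULATION_DOWN else spec.color_up
        scene.append(_line(x1, y1, x2, y2, color, width=0.8,
                           cls=f"pair {pair.regulation.lower()}"))

    for tf in tf_order:
        x, y = tf_xy[tf]
        scene.append(_circle(x, y, 2.5, "#333333"))
    if n_tf <= 80:
        for tf in tf_order:
            x, y = tf_xy[tf]
            scale = (radius + 30) / radius
            scene.append(_text(cx + (x - cx) * scale, cy + (y - cy) * scale, tf, size=9))
    if genes and len(genes) <= 80:
        for g in genes:
            x, y = gene_xy[g]
            scale = (radius + 30) / radius
            scene.append(_text(cx + (x - cx) * scale, cy + (y - cy) * scale, g, size=8))

    if not result.flagged_pairs:
        scene.append(_text(cx, cy, "no significant TF-gene changes at this cutoff", size=14))

    title = f"{result.ref_label or 'reference'} vs {result.alt_label or 'alternate'}"
    scene.append(_text(cx, 22, f"TF activity changes: {title}", size=14))
    scene.append(_text(60, spec.height - 30, "Down (stronger in reference)", size=10,
                       color=spec.color_down, anchor="start"))
    scene.append(_text(60, spec.height - 16, "Up (stronger in alternate)", size=10,
                       color=spec.color_up, anchor="start"))
    _render(scene, spec, out_path)
    return len(result.flagged_pairs)


def strength_plot(
    tf_ids,
    v_ref: np.ndarray,
    v_alt: np.ndarray,
    k: float = 2.0,
    annotation: TFAnnotation | None = None,
    spec: PlotSpec | None = None,
    out_path="strength.svg",
    quantity: str = "average strength",
) -> int:
    """Per-TF change with median +/- k SD guides; returns highlighted count."""
    tf_ids = list(tf_ids)
    if len(tf_ids) < 3:
        raise ValidationError("need at least 3 TFs for a strength plot")
    annotation = annotation or TFAnnotation()
    spec = spec or PlotSpec()
    order = annotation.order(tf_ids)
    pos = {t: i for i, t in enumerate(tf_ids)}
    delta = np.asarray(v_ref, dtype=float) - np.asarray(v_alt, dtype=float)
    med = float(np.median(delta))
    sd = float(np.std(delta, ddof=1))
    hi, lo = med + k * sd, med - k * sd

    margin = 60.0
    span_x = spec.width - 2 * margin
    lo_v = min(float(delta.min()), lo)
    hi_v = max(float(delta.max()), hi)
    pad = 0.05 * (hi_v - lo_v or 1.0)
    lo_v, hi_v = lo_v - pad, hi_v + pad

    def ypix(v):
        return spec.height - margin - (v - lo_v) / (hi_v - lo_v) * (spec.height - 2 * margin)

    def xpix(i):
        return margin + span_x * (i + 0.5) / len(order)

    scene = [
        _path([(margin, ypix(med)), (spec.width - margin, ypix(med))], "#555555", 1.0),
        _path([(margin, ypix(hi)), (spec.width - margin, ypix(hi))], "#555555", 1.0, dashed=True),
        _path([(margin, ypix(lo)), (spec.width - margin, ypix(lo))], "#555555", 1.0, dashed=True),
    ]
    n_high = 0
    for i, tf in enumerate(order):
        d = float(delta[pos[tf]])
        x, y = xpix(i), ypix(d)
        if d - med > k * sd:
            color = spec.color_down
            n_high += 1
        elif med - d > k * sd:
            color = spec.color_up
            n_high += 1
        else:
            color = spec.color_neutral
        scene.append(_path([(x, ypix(med)), (x, y)], color, 1.0))
        scene.append(_circle(x, y, 4.0, color))
        scene.append(_text(x, spec.height - margin + 16, tf, size=8))
    scene.append(_text(spec.width / 2, 22,
                       f"Change in {quantity} per TF (guides: median ± {k:g} SD)", size=13))
    _render(scene, spec, out_path)
    return n_high


def change_heatmap(
    matrix: np.ndarray,
    tf_ids,
    dataset_labels,
    annotation: TFAnnotation | None = None,
    spec: PlotSpec | None = None,
    out_path="heatmap.svg",
) -> None:
    """TF x dataset heatmap; darker cells are larger values.

    Rows follow functional-group order with the group index printed on
    the right; the legend states the data range the shades span.
    """
    matrix = np.asarray(matrix, dtype=float)
    tf_ids = list(tf_ids)
    dataset_labels = list(dataset_labels)
    if matrix.shape != (len(tf_ids), len(dataset_labels)):
        raise ValidationError("heatmap matrix shape does not match its labels")
    if matrix.size == 0 or not np.all(np.isfinite(matrix)):
        raise ValidationError("heatmap matrix must be non-empty and finite")
    annotation = annotation or TFAnnotation()
    spec = spec or PlotSpec()
    order = annotation.order(tf_ids)
    pos = {t: i for i, t in enumerate(tf_ids)}

    vmin, vmax = float(matrix.min()), float(matrix.max())
    rng = vmax - vmin

    def shade(v):
        z = 0.5 if rng == 0 else (v - vmin) / rng
        level = int(round(245 - 225 * z))  # higher value -> darker
        return f"rgb({level},{level},{level})"

    margin = 80.0
    cw = (spec.width - 2 * margin) / len(dataset_labels)
    ch = (spec.height - 2 * margin) / len(order)
    scene = []
    for i, tf in enumerate(order):
        for j in range(len(dataset_labels)):
            v = float(matrix[pos[tf], j])
            scene.append(_rect(margin + j * cw, margin + i * ch, cw, ch,
                               shade(v), stroke="#ffffff", value=v))
        gi, _ = annotation.group_of(tf)
        label = str(gi) if gi != annotation.unknown_index else "?"
        scene.append(_text(spec.width - margin + 8, margin + (i + 0.5) * ch,
                           label, size=9, anchor="start"))
        scene.append(_text(margin - 8, margin + (i + 0.5) * ch, tf, size=8, anchor="end"))
    for j, lab in enumerate(dataset_labels):
        scene.append(_text(margin + (j + 0.5) * cw, margin - 10, lab, size=10))
    scene.append(_text(spec.width / 2, spec.height - 20,
                       f"shade range: min={vmin:.4g} (light) to max={vmax:.4g} (dark)", size=10))
    _render(scene, spec, out_path)
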