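"""SVG rendering of the per-sequence segmentation with the cluster tree.

Static SVG 1.1.  Sequences appear in tree leaf order, one horizontal
track each, scaled by nucleotide length; uncovered stretches are thin
baseline segments and module occurrences are boxes filled with a
deterministic texture cycled by module id.  Reverse occurrences carry a
triangle marker, truncated occurrences are drawn as crossed boxes; a
legend maps textures to module ids.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from temodules.clustering import ClusterNode, ClusterTree
from temodules.detection import ModuleCatalog

_COLORS = [
    "#4e79a7", "#f28e2b", "#e15759", "#76b7b2", "#59a14f",
    "#edc948", "#b07aa1", "#ff9da7", "#9c755f", "#bab0ac",
]
_STYLES = ("solid", "hatch", "cross", "dots", "vlines")

ROW_H = 24
BOX_H = 14
TREE_W = 140
LABEL_W = 110
TRACK_W = 620
MARGIN = 12


def _pattern_defs(n_modules: int) -> str:
    """One texture per module id: color x fill-style, cycled."""
    out = []
    for mid in range(1, n_modules + 1):
        color = _COLORS[(mid - 1) % len(_COLORS)]
        style = _STYLES[((mid - 1) // len(_COLORS)) % len(_STYLES)]
        pid = f"pat{mid}"
        body = ""
        if style == "solid":
            body = f'<rect width="8" height="8" fill="{color}"/>'
        elif style == "hatch":
            body = (
                f'<rect width="8" height="8" fill="white"/>'
                f'<path d="M0,8 L8,0" stroke="{color}" stroke-width="2"/>'
            )
        elif style == "cross":
            body = (
                f'<rect width="8" height="8" fill="white"/>'
                f'<path d="M0,0 L8,8 M0,8 L8,0" stroke="{color}" stroke-width="1.5"/>'
            )
        elif style == "dots":
            body = (
                f'<rect width="8" height="8" fill="white"/>'
                f'<circle cx="4" cy="4" r="2" fill="{color}"/>'
            )
        else:  # vlines
            body = (
                f'<rect width="8" height="8" fill="white"/>'
                f'<path d="M4,0 L4,8" stroke="{color}" stroke-width="2"/>'
            )
        out.append(
            f'<pattern id="{pid}" width="8" height="8" '
            f'patternUnits="userSpaceOnUse">{body}</pattern>'
        )
    return "".join(out)


def _tree_lines(
    tree: Optional[ClusterTree], leaf_y: dict[int, float]
) -> list[str]:
    if tree is None or tree.root.is_leaf:
        return []
    hmax = max(tree.root.height, 1e-12)

    def x_of(node: ClusterNode) -> float:
        return MARGIN + (1.0 - node.height / hmax) * (TREE_W - MARGIN)

    lines: list[str] = []

    def walk(node: ClusterNode) -> float:
        if node.is_leaf:
            return leaf_y[node.leaf]
        ys = [walk(c) for c in node.children]
        x = x_of(node)
        for c, y in zip(node.children, ys):
            xc = x_of(c) if not c.is_leaf else TREE_W
            lines.append(
                f'<line x1="{x:.2f}" y1="{y:.2f}" x2="{xc:.2f}" y2="{y:.2f}" '
                f'stroke="black" stroke-width="1"/>'
            )
        lines.append(
            f'<line x1="{x:.2f}" y1="{min(ys):.2f}" x2="{x:.2f}" '
            f'y2="{max(ys):.2f}" stroke="black" stroke-width="1"/>'
        )
        return sum(ys) / len(ys)

    walk(tree.root)
    return lines


def render_svg(
    catalog: ModuleCatalog,
    tree: Optional[ClusterTree],
    path: str | Path,
) -> None:
    """Render the segmentation (and tree, when given) to an SVG file."""
    family = catalog.family
    order = tree.leaf_order() if tree is not None else list(range(family.n))
    max_len = max(len(s) for s in family.sequences)
    scale = TRACK_W / max(max_len, 1)
    x0 = TREE_W + LABEL_W

    leaf_y = {si: MARGIN + ROW_H * (row + 0.5) for row, si in enumerate(order)}
    n_rows = len(order)
    legend_rows = (catalog.m + 5) // 6
    height = MARGIN * 3 + ROW_H * n_rows + 20 * max(legend_rows, 1) + 16
    width = x0 + TRACK_W + MARGIN

    parts: list[str] = []
    parts.append(
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{width}" height="{height:.0f}">'
    )
    parts.append("<defs>" + _pattern_defs(catalog.m) + "</defs>")
    parts.extend(_tree_lines(tree, leaf_y))

    for si in order:
        y = leaf_y[si]
        rid, seq = family.records[si]
        parts.append(
            f'<text x="{TREE_W + 4}" y="{y + 4:.2f}" font-size="11" '
            f'font-family="monospace">{rid}</text>'
        )
        # baseline for the whole (possibly uncovered) sequence
        parts.append(
            f'<line x1="{x0:.2f}" y1="{y:.2f}" '
            f'x2="{x0 + len(seq) * scale:.2f}" y2="{y:.2f}" '
            f'stroke="#888" stroke-width="1"/>'
        )

    for mod, occ in catalog.all_occurrences():
        y = leaf_y[occ.seq_index]
        bx = x0 + occ.start * scale
        bw = max(occ.span * scale, 1.0)
        top = y - BOX_H / 2
        box = (
            f'<rect class="module-box" x="{bx:.2f}" y="{top:.2f}" '
            f'width="{bw:.2f}" height="{BOX_H}" fill="url(#pat{mod.id})" '
            f'stroke="black" stroke-width="0.8"/>'
        )
        extras = []
        if occ.kind.startswith("truncated"):
            extras.append(
                f'<g class="truncated-marker">'
                f'<line x1="{bx:.2f}" y1="{top:.2f}" x2="{bx + bw:.2f}" '
                f'y2="{top + BOX_H:.2f}" stroke="black" stroke-width="1"/>'
                f'<line x1="{bx:.2f}" y1="{top + BOX_H:.2f}" x2="{bx + bw:.2f}" '
                f'y2="{top:.2f}" stroke="black" stroke-width="1"/></g>'
            )
        if occ.kind in ("reverse", "truncated_reverse"):
            cx = bx + bw / 2
            extras.append(
                f'<polygon class="reverse-marker" points="'
                f'{cx - 4:.2f},{top - 2:.2f} {cx + 4:.2f},{top - 2:.2f} '
                f'{cx:.2f},{top - 8:.2f}" fill="black"/>'
            )
        parts.append(box + "".join(extras))

    # legend
    ly = MARGIN * 2 + ROW_H * n_rows
    for i, mod in enumerate(catalog.modules):
        col = i % 6
        row = i // 6
        lx = MARGIN + col * 120
        yy = ly + row * 20
        parts.append(
            f'<rect class="legend-box" x="{lx}" y="{yy}" width="14" height="12" '
            f'fill="url(#pat{mod.id})" stroke="black" stroke-width="0.6"/>'
        )
        parts.append(
            f'<text x="{lx + 18}" y="{yy + 10}" font-size="11" '
            f'font-family="monospace">M{mod.id}</text>'
        )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts) + "\n")
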