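"""Tree and overlay serialization: Newick, NEXUS, phyloXML, SVG.

All three tree formats encode the same topology, leaf labels and branch
lengths; serialization is deterministic, so identical recognized trees give
byte-identical files. Branch lengths are raw pixels of the rescaled image
unless normalized via ``normalize_lengths``.
"""

from __future__ import annotations

from xml.sax.saxutils import escape

from .contour import Contour
from .labeling import _SAFE_LABEL, LabelBox
from .raster import ScaleReport
from .tree import Node, RecognizedTree


def _fmt_len(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else repr(round(float(value), 6))


def _newick_label(label: str | None) -> str:
    if not label:
        return ""
    if label.startswith("'") and label.endswith("'") and len(label) > 1:
        return label  # already quoted by sanitize_label
    if not _SAFE_LABEL.match(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _unquote(label: str | None) -> str:
    if not label:
        return ""
    if label.startswith("'") and label.endswith("'") and len(label) > 1:
        return label[1:-1].replace("''", "'")
    return label


def to_newick(tree: RecognizedTree, include_lengths: bool = True) -> str:
    """Standard Newick, children in stored top-to-bottom order."""

    def render(node: Node) -> str:
        if node.is_leaf:
            body = _newick_label(node.label)
        else:
            body = "(" + ",".join(render(c) for c in node.children) + ")"
        if include_lengths:
            body += f":{_fmt_len(node.branch_length)}"
        return body

    return render(tree.root) + ";"


def to_nexus(tree: RecognizedTree, include_lengths: bool = True) -> str:
    """NEXUS file with TAXA and TREES blocks matching the Newick leaf set."""
    taxa = [_newick_label(leaf.label) or "_" for leaf in tree.leaves()]
    lines = [
        "#NEXUS",
        "",
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS",
    ]
    lines += [f"        {t}" for t in taxa]
    lines += [
        "    ;",
        "END;",
        "",
        "BEGIN TREES;",
        f"    TREE recognized = {to_newick(tree, include_lengths)}",
        "END;",
        "",
    ]
    return "\n".join(lines)


def to_phyloxml(tree: RecognizedTree, include_lengths: bool = True) -> str:
    """phyloXML document: nested clade elements mirroring the topology."""
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        '<phyloxml xmlns="http://www.phyloxml.org" '
        'xmlns:xsi="http://www.w3.org/2001/XMLSchema-instance">',
        '  <phylogeny rooted="true">',
    ]

    def emit(node: Node, depth: int) -> None:
        pad = "  " * (depth + 2)
        out.append(f"{pad}<clade>")
        label = _unquote(node.label)
        if label:
            out.append(f"{pad}  <name>{escape(label)}</name>")
        if include_lengths:
            out.append(
                f"{pad}  <branch_length>{_fmt_len(node.branch_length)}</branch_length>"
            )
        for child in node.children:
            emit(child, depth + 1)
        out.append(f"{pad}</clade>")

    emit(tree.root, 0)
    out.append("  </phylogeny>")
    out.append("</phyloxml>")
    out.append("")
    return "\n".join(out)


def to_svg_overlay(
    contours: list[Contour],
    boxes: list[LabelBox],
    scale: ScaleReport,
    image_dims: tuple[int, int],
) -> str:
    """Diagnostic SVG at original-image size: traced contours + label boxes.

    ``image_dims`` is (width, height) of the original image; contour points
    are in rescaled coordinates and are mapped back through ``scale``.
    """
    width, height = image_dims
    inv = 1.0 / scale.scale_factor
    out = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" height="{height}" '
        f'viewBox="0 0 {width} {height}">',
    ]
    for contour in contours:
        pts = " ".join(
            f"{x * inv:.2f},{y * inv:.2f}" for x, y in contour.points
        )
        out.append(
            f'  <polyline points="{pts}" fill="none" stroke="red" stroke-width="1"/>'
        )
    for box in boxes:
        if box.empty:
            continue
        out.append(
            f'  <rect x="{box.x0}" y="{box.y0}" width="{box.x1 - box.x0 + 1}" '
            f'height="{box.y1 - box.y0 + 1}" fill="none" stroke="blue" stroke-width="1"/>'
        )
    out.append("</svg>")
    out.append("")
    return "\n".join(out)


def normalize_lengths(tree: RecognizedTree) -> RecognizedTree:
    """Divide all branch lengths by the root-to-farthest-tip pixel distance."""

    def depth(node: Node) -> float:
        if node.is_leaf:
            return node.branch_length
        return node.branch_length + max(depth(c) for c in node.children)

    total = depth(tree.root)
    if total <= 0:
        return tree
    for node in tree.root.walk():
        node.branch_length = node.branch_length / total
    tree.root_length = tree.root.branch_length
    return tree
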