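"""Synthetic phylogram generator: ground-truth trees, renders, degradations.

Every recognizer test ultimately round-trips through this module: a random
multifurcating tree is rendered as a left-rooted rectangular phylogram with
known geometry (every drawn line, tip point and label box is recorded), the
image is optionally degraded (speckle, line breaks, support numerals, lossy
re-encoding), and recognition output is compared against the recorded truth.

Renders satisfy the recognizer's prerequisites by construction: dark
foreground on a light homogeneous background, root on the left, horizontal
branches with strictly positive tip lengths, and a single connected tree
component (labels and numerals never touch the lines). Branch lengths are
drawn no shorter than 15 px so unrelated lines keep comfortable clearance
from each other — a property real published phylograms share, and the reason
the segment-adjacency tolerance of one pixel is safe.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .errors import ParameterError
from .tree import Node, RecognizedTree

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"


def _word(rng: np.random.Generator, n_syllables: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syllables)
    )


def random_labels(rng: np.random.Generator, n: int) -> list[str]:
    """Unique pronounceable genus_species-style labels."""
    labels: list[str] = []
    seen = set()
    while len(labels) < n:
        name = _word(rng, int(rng.integers(2, 4))).capitalize() + "_" + _word(
            rng, int(rng.integers(1, 4))
        )
        if name in seen:
            name = f"{name}_{len(labels) + 1}"
        seen.add(name)
        labels.append(name)
    return labels


def random_tree(
    n_leaves: int,
    multifurcation_prob: float = 0.15,
    seed: int | None = None,
    branch_len_range: tuple[int, int] = (18, 80),
    root_len_range: tuple[int, int] = (12, 40),
) -> Node:
    """Random rooted tree with exactly ``n_leaves`` leaves, by leaf attachment.

    Starting from a cherry, each step picks a random leaf and either splits
    it into a new cherry or — with probability ``multifurcation_prob`` —
    attaches the new leaf as an extra child of its parent, widening that
    node into a multifurcation. Branch lengths (px) are uniform integers in
    ``branch_len_range``; reproducible for a given seed.
    """
    if n_leaves < 2:
        raise ParameterError("a tree needs at least 2 leaves")
    if not 0 <= multifurcation_prob < 1:
        raise ParameterError("multifurcation_prob must be in [0, 1)")
    rng = np.random.default_rng(seed)
    lo, hi = branch_len_range

    def new_len() -> float:
        return float(rng.integers(lo, hi + 1))

    root = Node(branch_length=float(rng.integers(*root_len_range)))
    parent: dict[int, Node] = {}
    leaves = [Node(branch_length=new_len()), Node(branch_length=new_len())]
    root.children = list(leaves)
    for leaf in leaves:
        parent[id(leaf)] = root
    while len(leaves) < n_leaves:
        target = leaves[int(rng.integers(len(leaves)))]
        newleaf = Node(branch_length=new_len())
        if rng.random() < multifurcation_prob:
            par = parent[id(target)]
            par.children.insert(int(rng.integers(len(par.children) + 1)), newleaf)
            parent[id(newleaf)] = par
        else:
            inner_a = Node(branch_length=new_len())
            target_parent = parent[id(target)]
            # Convert the picked leaf into an internal node with two fresh
            # leaves; it keeps its branch length.
            target.children = [inner_a, newleaf]
            parent[id(inner_a)] = target
            parent[id(newleaf)] = target
            leaves.remove(target)
            leaves.append(inner_a)
        leaves.append(newleaf)
    for leaf, label in zip(root.leaves(), random_labels(rng, n_leaves)):
        leaf.label = label
    return root


@dataclass(frozen=True)
class RenderSpec:
    """Geometry of a rendered phylogram, all units in pixels."""

    line_thickness: int = 2
    font_height: int = 11
    leaf_spacing: int = 14
    margin: int = 20
    min_tip_length: int = 15
    label_gap: int = 5
    image_format: str = "PNG"
    antialias: bool = True
    draw_labels: bool = True
    max_dim: int = 8000

    def __post_init__(self) -> None:
        if self.min_tip_length < 1:
            raise ParameterError("min_tip_length must be >= 1")
        if self.leaf_spacing <= self.font_height:
            raise ParameterError("leaf_spacing must exceed font_height")
        if self.image_format.upper() not in {"PNG", "JPEG", "GIF"}:
            raise ParameterError(f"unsupported format {self.image_format}")


@dataclass(frozen=True)
class DegradationSpec:
    """Stress parameters for the cleaning chain."""

    speckle_density: float = 0.0
    gap_count: int = 0
    gap_width: int = 2
    node_numerals: bool = False
    jpeg_quality: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.speckle_density <= 0.01:
            raise ParameterError("speckle_density must be in [0, 0.01]")
        if not 0 <= self.gap_width <= 4:
            raise ParameterError("gap_width must be in [0, 4]")


@dataclass(frozen=True)
class DrawnLine:
    orientation: str  # "horizontal" | "vertical"
    x0: int
    x1: int
    y0: int
    y1: int
    role: str  # "branch" | "connector" | "root"


@dataclass
class RenderTruth:
    """A rendered phylogram plus every fact needed to verify recognition."""

    image: np.ndarray                      # uint8 luminance
    root: Node                             # source topology with px lengths
    tip_points: list[tuple[int, float]]    # (x, y) drawn tip ends, top to bottom
    tip_boxes: list[tuple[int, int, int, int]]  # exact label (x0, y0, x1, y1)
    line_list: list[DrawnLine]
    internal_nodes: list[tuple[int, int]]  # (x, y) junction positions
    spec: RenderSpec
    numeral_pixel_sets: list[np.ndarray] = field(default_factory=list)
    degradation: DegradationSpec | None = None

    def tree(self) -> RecognizedTree:
        return RecognizedTree(root=self.root, root_length=self.root.branch_length)

    def n_leaves(self) -> int:
        return self.root.n_leaves()

    def encode(self, fmt: str | None = None) -> bytes:
        fmt = (fmt or self.spec.image_format).upper()
        buf = io.BytesIO()
        Image.fromarray(self.image).save(buf, format=fmt)
        return buf.getvalue()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        suffix = path.suffix.lstrip(".").upper().replace("JPG", "JPEG")
        path.write_bytes(self.encode(suffix or None))
        return path


def _font(size: int) -> ImageFont.ImageFont:
    return ImageFont.load_default(size=size)


def _layout(
    root: Node, spec: RenderSpec
) -> tuple[dict[int, int], dict[int, int], list[Node]]:
    """Leaf rows and node x positions for the rectangular layout."""
    leaves = root.leaves()
    ys: dict[int, int] = {}
    for i, leaf in enumerate(leaves):
        ys[id(leaf)] = spec.margin + i * spec.leaf_spacing + spec.leaf_spacing // 2

    def assign_y(node: Node) -> int:
        if node.is_leaf:
            return ys[id(node)]
        child_ys = [assign_y(c) for c in node.children]
        ys[id(node)] = (child_ys[0] + child_ys[-1]) // 2
        return ys[id(node)]

    assign_y(root)
    xs: dict[int, int] = {}

    def assign_x(node: Node, base: int) -> None:
        xs[id(node)] = base + int(round(node.branch_length))
        for c in node.children:
            assign_x(c, xs[id(node)])

    assign_x(root, spec.margin)
    return ys, xs, leaves


def render_tree(root: Node, spec: RenderSpec | None = None) -> RenderTruth:
    """Draw the tree as a left-rooted rectangular phylogram.

    Horizontal branch extents are the tree's branch lengths; leaves sit at
    evenly spaced rows; vertical connectors span the child rows of each
    internal node; labels are drawn right of the tips with a fixed gap.
    """
    spec = spec or RenderSpec()
    t = spec.line_thickness
    ys, xs, leaves = _layout(root, spec)
    n = len(leaves)
    height = n * spec.leaf_spacing + 2 * spec.margin

    font = _font(spec.font_height)
    probe = ImageDraw.Draw(Image.new("L", (8, 8), 255))
    label_widths = {}
    for leaf in leaves:
        text = leaf.label or ""
        if text and spec.draw_labels:
            bb = probe.textbbox((0, 0), text, font=font, anchor="lm")
            label_widths[id(leaf)] = bb[2] - bb[0]
        else:
            label_widths[id(leaf)] = 0
    width = (
        max(
            xs[id(leaf)] + t - 1 + spec.label_gap + 1 + label_widths[id(leaf)]
            for leaf in leaves
        )
        + spec.margin
    )
    if width > spec.max_dim or height > spec.max_dim:
        raise ParameterError(
            f"layout of {width}x{height} exceeds the {spec.max_dim} px limit"
        )

    arr = np.full((height, width), 255, dtype=np.uint8)
    line_list: list[DrawnLine] = []
    internal_nodes: list[tuple[int, int]] = []

    def hline(x0: int, x1: int, y: int, role: str) -> None:
        arr[y : y + t, x0 : x1 + 1] = 0
        line_list.append(DrawnLine("horizontal", x0, x1, y, y + t - 1, role))

    def vline(x: int, y0: int, y1: int, role: str) -> None:
        arr[y0 : y1 + 1, x : x + t] = 0
        line_list.append(DrawnLine("vertical", x, x + t - 1, y0, y1, role))

    def draw(node: Node, parent_x: int, role: str) -> None:
        x, y = xs[id(node)], ys[id(node)]
        hline(parent_x, x + t - 1, y, role)
        if not node.is_leaf:
            internal_nodes.append((x, y))
            y_first = ys[id(node.children[0])]
            y_last = ys[id(node.children[-1])]
            vline(x, y_first, y_last + t - 1, "connector")
            for child in node.children:
                draw(child, x, "branch")

    draw(root, spec.margin, "root")

    tip_points = [
        (xs[id(leaf)] + t - 1, ys[id(leaf)] + (t - 1) / 2) for leaf in leaves
    ]
    tip_boxes: list[tuple[int, int, int, int]] = []
    if spec.draw_labels:
        layer = Image.new("L", (width, height), 255)
        draw_layer = ImageDraw.Draw(layer)
        for leaf in leaves:
            text = leaf.label or ""
            if not text:
                tip_boxes.append((0, 0, 0, 0))
                continue
            x0 = xs[id(leaf)] + t - 1 + spec.label_gap + 1
            anchor_y = ys[id(leaf)] + t // 2
            draw_layer.text((x0, anchor_y), text, font=font, fill=0, anchor="lm")
            bb = draw_layer.textbbox((x0, anchor_y), text, font=font, anchor="lm")
            tip_boxes.append((bb[0], bb[1], bb[2] - 1, bb[3] - 1))
        glyphs = np.asarray(layer)
        if not spec.antialias:
            glyphs = np.where(glyphs < 128, 0, 255).astype(np.uint8)
        arr = np.minimum(arr, glyphs)
    else:
        tip_boxes = [(0, 0, 0, 0)] * n

    return RenderTruth(
        image=arr,
        root=root,
        tip_points=tip_points,
        tip_boxes=tip_boxes,
        line_list=line_list,
        internal_nodes=internal_nodes,
        spec=spec,
    )


def _place_numeral(
    arr: np.ndarray,
    rng: np.random.Generator,
    node_xy: tuple[int, int],
    spec: RenderSpec,
    obstacles: list[tuple[int, int, int, int]],
) -> np.ndarray | None:
    """Draw a 2-digit support value near a junction, never touching anything.

    Returns the (row, col) pixel array of the drawn numeral, or None when no
    clear position was found within a few shifts.
    """
    font = _font(max(spec.font_height - 1, 8))
    value = str(int(rng.integers(50, 100)))
    probe = ImageDraw.Draw(Image.new("L", (8, 8), 255))
    bb = probe.textbbox((0, 0), value, font=font)
    w, h = bb[2] - bb[0], bb[3] - bb[1]
    x_n, y_n = node_xy
    t = spec.line_thickness
    # Must exceed the cleaner's default patchable gap (3 px): a numeral
    # closer than that would be welded onto the tree by gap bridging.
    clearance = 4
    candidates = [
        (x_n - w - dx, y_n + dy)
        for dy in (-h - 5, t + 5, -h - 8, t + 8)
        for dx in (5, 8, 12, 16)
    ]
    for x0, y0 in candidates:
        x1, y1 = x0 + w - 1, y0 + h - 1
        if x0 < 0 or y0 < 0 or y1 >= arr.shape[0]:
            continue
        grown = (x0 - clearance, y0 - clearance, x1 + clearance, y1 + clearance)
        if any(
            not (grown[2] < ox0 or grown[0] > ox1 or grown[3] < oy0 or grown[1] > oy1)
            for ox0, oy0, ox1, oy1 in obstacles
        ):
            continue
        layer = Image.new("L", (w + 2, h + 2), 255)
        ImageDraw.Draw(layer).text((1 - bb[0], 1 - bb[1]), value, font=font, fill=0)
        glyph = np.where(np.asarray(layer) < 128, 0, 255).astype(np.uint8)
        rows, cols = np.nonzero(glyph == 0)
        if rows.size == 0:
            return None
        coords = np.stack([rows + y0 - 1, cols + x0 - 1], axis=1)
        inside = (
            (coords[:, 0] >= 0)
            & (coords[:, 0] < arr.shape[0])
            & (coords[:, 1] >= 0)
            & (coords[:, 1] < arr.shape[1])
        )
        coords = coords[inside]
        arr[coords[:, 0], coords[:, 1]] = 0
        obstacles.append((x0, y0, x1, y1))
        return coords
    return None


def degrade(truth: RenderTruth, deg: DegradationSpec) -> RenderTruth:
    """Apply seeded degradations; the recorded truth geometry is untouched."""
    rng = np.random.default_rng(deg.seed)
    arr = truth.image.copy()
    numeral_sets: list[np.ndarray] = []

    if deg.node_numerals:
        obstacles = [
            (ln.x0, ln.y0, ln.x1, ln.y1) for ln in truth.line_list
        ] + [bb for bb in truth.tip_boxes if bb != (0, 0, 0, 0)]
        for node_xy in truth.internal_nodes:
            coords = _place_numeral(arr, rng, node_xy, truth.spec, obstacles)
            if coords is not None:
                numeral_sets.append(coords)

    if deg.gap_count > 0:
        t = truth.spec.line_thickness
        candidates = [
            ln
            for ln in truth.line_list
            if ln.orientation == "horizontal"
            and (ln.x1 - ln.x0 + 1) >= deg.gap_width + 2 * (t + 3)
        ]
        chosen = rng.choice(
            len(candidates), size=min(deg.gap_count, len(candidates)), replace=False
        )
        for k in chosen:
            ln = candidates[int(k)]
            g0 = int(
                rng.integers(ln.x0 + t + 3, ln.x1 - t - 2 - deg.gap_width + 1)
            )
            arr[ln.y0 : ln.y1 + 1, g0 : g0 + deg.gap_width] = 255

    if deg.speckle_density > 0:
        flips = rng.random(arr.shape) < deg.speckle_density
        arr[flips] = 0

    if deg.jpeg_quality is not None:
        buf = io.BytesIO()
        Image.fromarray(arr).save(buf, format="JPEG", quality=int(deg.jpeg_quality))
        arr = np.asarray(Image.open(buf).convert("L"))

    return RenderTruth(
        image=arr,
        root=truth.root,
        tip_points=truth.tip_points,
        tip_boxes=truth.tip_boxes,
        line_list=truth.line_list,
        internal_nodes=truth.internal_nodes,
        spec=truth.spec,
        numeral_pixel_sets=numeral_sets,
        degradation=deg,
    )


def render_radial(
    n_rays: int = 10, size: int = 400, thickness: int = 2, seed: int = 0
) -> np.ndarray:
    """Negative control: a radial (star) layout the recognizer must reject."""
    rng = np.random.default_rng(seed)
    img = Image.new("L", (size, size), 255)
    d = ImageDraw.Draw(img)
    cx = cy = size // 2
    for k in range(n_rays):
        angle = 2 * math.pi * k / n_rays + rng.uniform(-0.1, 0.1)
        r = size * 0.4 * rng.uniform(0.6, 1.0)
        d.line(
            [(cx, cy), (cx + r * math.cos(angle), cy + r * math.sin(angle))],
            fill=0,
            width=thickness,
        )
    return np.asarray(img, dtype=np.uint8)


def zero_length_tip_render(spec: RenderSpec | None = None) -> RenderTruth:
    """Negative control: a cherry whose upper tip has branch length 0."""
    root = Node(branch_length=25.0)
    root.children = [
        Node(branch_length=0.0, label="Zero_tip"),
        Node(branch_length=40.0, label="Long_tip"),
    ]
    spec = spec or RenderSpec(draw_labels=False)
    return render_tree(root, spec)


def make_benchmark(
    out_dir: str | Path,
    n_images: int = 100,
    leaf_range: tuple[int, int] = (5, 60),
    seed: int = 0,
    multifurcation_prob: float = 0.15,
    degradation: DegradationSpec | None = None,
    spec: RenderSpec | None = None,
) -> Path:
    """Write paired image + Newick truth files with a TSV manifest.

    The default batch of 100 images mirrors the size of a typical published
    benchmarking set. Fully reproducible per seed.
    """
    from .serialize import to_newick  # local import to avoid a cycle

    if n_images < 1:
        raise ParameterError("n_images must be >= 1")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"benchmark directory not writable: {out_dir}") from exc
    spec = spec or RenderSpec()
    rng = np.random.default_rng(seed)
    rows = ["filename\tn_leaves\tseed\tspeckle\tgaps\tnumerals\tjpeg_quality"]
    ext = {"PNG": "png", "JPEG": "jpg", "GIF": "gif"}[spec.image_format.upper()]
    for i in range(n_images):
        tree_seed = int(rng.integers(0, 2**31 - 1))
        n_leaves = int(rng.integers(leaf_range[0], leaf_range[1] + 1))
        root = random_tree(n_leaves, multifurcation_prob, seed=tree_seed)
        truth = render_tree(root, spec)
        deg = degradation
        if deg is not None:
            deg = replace(deg, seed=(deg.seed + i) % 2**31)
            truth = degrade(truth, deg)
        stem = f"tree_{i:03d}"
        truth.save(out_dir / f"{stem}.{ext}")
        tree = truth.tree()
        (out_dir / f"{stem}.nwk").write_text(to_newick(tree) + "\n")
        rows.append(
            "\t".join(
                [
                    f"{stem}.{ext}",
                    str(n_leaves),
                    str(tree_seed),
                    str(deg.speckle_density if deg else 0.0),
                    str(deg.gap_count if deg else 0),
                    str(int(deg.node_numerals)) if deg else "0",
                    str(deg.jpeg_quality if deg and deg.jpeg_quality else ""),
                ]
            )
        )
    (out_dir / "manifest.tsv").write_text("\n".join(rows) + "\n")
    return out_dir / "manifest.tsv"
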