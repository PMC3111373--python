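"""Pipeline orchestration: image in, recognized tree + output bundle out.

Stage order mirrors the recognizer's architecture: decode → binarize →
thickness-normalizing rescale → clean → segment/contour extraction → tree
assembly → prerequisite validation → label boxes → OCR → serialization.
Any diagnosable failure is captured into the result's status, never raised
through the top level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import raster, serialize
from .cleaning import CleaningConfig, CleaningReport, clean
from .contour import trace_contours
from .errors import ConfigurationError, PhylopixError
from .labeling import (
    FakeOcrEngine,
    OcrEngine,
    TesseractEngine,
    estimate_label_boxes,
    ocr_label,
    sanitize_label,
)
from .segments import detect_tips, extract_segments
from .tree import RecognizedTree, build_tree

OCR_MODES = ("engine", "fake", "off")


@dataclass
class PipelineConfig:
    """All knobs of a recognition run; every field has a usable default."""

    cleaning: CleaningConfig = field(default_factory=CleaningConfig)
    threshold: int | None = None          # None → Otsu from the histogram
    ocr_mode: str = "off"                 # engine | fake | off
    ocr_command: str = "tesseract"
    ocr_language: str | None = None
    include_lengths: bool = True
    normalize_lengths: bool = False
    out_dir: str | None = None
    stem: str | None = None
    verbosity: int = 1

    def __post_init__(self) -> None:
        if self.ocr_mode not in OCR_MODES:
            raise ConfigurationError(
                f"ocr_mode must be one of {OCR_MODES}, got {self.ocr_mode!r}"
            )

    # -- flat key=value config file representation ------------------------
    def to_file(self, path: str | Path) -> None:
        lines = []
        for f in fields(CleaningConfig):
            lines.append(f"cleaning.{f.name} = {getattr(self.cleaning, f.name)}")
        for name in (
            "threshold",
            "ocr_mode",
            "ocr_command",
            "ocr_language",
            "include_lengths",
            "normalize_lengths",
            "out_dir",
            "stem",
            "verbosity",
        ):
            lines.append(f"{name} = {getattr(self, name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        def parse(value: str):
            if value == "None":
                return None
            if value in ("True", "False"):
                return value == "True"
            try:
                return int(value)
            except ValueError:
                return value

        kwargs: dict = {}
        cleaning_kwargs: dict = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), parse(value.strip())
            if key.startswith("cleaning."):
                cleaning_kwargs[key.split(".", 1)[1]] = value
            else:
                kwargs[key] = value
        return cls(cleaning=CleaningConfig(**cleaning_kwargs), **kwargs)


@dataclass
class OutputBundle:
    """The serialized outputs of one successful recognition."""

    newick: str
    nexus: str
    phyloxml: str
    svg: str
    log: dict

    def write(self, out_dir: str | Path, stem: str) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for suffix, text in (
            (".nwk", self.newick + "\n"),
            (".nex", self.nexus),
            (".xml", self.phyloxml),
            (".svg", self.svg),
            (".log", "".join(f"{k}\t{v}\n" for k, v in sorted(self.log.items()))),
        ):
            p = out_dir / f"{stem}{suffix}"
            p.write_text(text)
            paths.append(p)
        return paths


@dataclass
class RecognitionResult:
    status: str                      # "success" | "failed"
    stage: str | None = None         # failing stage when failed
    reason: str | None = None
    tree: RecognizedTree | None = None
    bundle: OutputBundle | None = None
    scale_report: raster.ScaleReport | None = None
    cleaning_report: CleaningReport | None = None

    @property
    def ok(self) -> bool:
        return self.status == "success"

    def n_leaves(self) -> int | None:
        return self.tree.n_leaves() if self.tree is not None else None


def _make_engine(config: PipelineConfig) -> OcrEngine | None:
    if config.ocr_mode == "off":
        return None
    if config.ocr_mode == "fake":
        return FakeOcrEngine()
    return TesseractEngine(config.ocr_command, config.ocr_language)


def recognize_gray(
    gray: np.ndarray,
    config: PipelineConfig | None = None,
    engine: OcrEngine | None = None,
) -> RecognitionResult:
    """Run the recognition stages on a decoded luminance raster."""
    config = config or PipelineConfig()
    stage = "configuration"
    try:
        if engine is None:
            engine = _make_engine(config)
        log: dict = {}

        stage = "binarize"
        threshold = (
            config.threshold
            if config.threshold is not None
            else raster.otsu_threshold(gray)
        )
        bin_original = raster.binarize(gray, threshold)
        log["threshold"] = threshold

        stage = "rescale"
        rescaled, scale_report = raster.rescale_to_thickness(bin_original)
        log["measured_thickness"] = scale_report.measured_thickness
        log["scale_factor"] = round(scale_report.scale_factor, 6)

        stage = "clean"
        cleaned, cleaning_report = clean(rescaled, config.cleaning)
        log.update(cleaning_report.as_dict())

        stage = "segments"
        segs = extract_segments(cleaned, raster.TARGET_THICKNESS)
        log["n_horizontals"] = len(segs.horizontals)
        log["n_verticals"] = len(segs.verticals)

        stage = "contour"
        contours = trace_contours(cleaned)
        log["n_contours"] = len(contours)

        stage = "tips"
        tips = detect_tips(segs)
        log["n_tips"] = len(tips)

        stage = "tree"
        tree = build_tree(segs)

        stage = "validate"
        violations = tree.validate()
        if violations:
            return RecognitionResult(
                status="failed",
                stage=stage,
                reason="; ".join(violations),
                scale_report=scale_report,
                cleaning_report=cleaning_report,
            )

        stage = "labels"
        boxes = estimate_label_boxes(tips, scale_report, gray, bin_original)
        leaves = tree.leaves()
        for k, (leaf, box) in enumerate(zip(leaves, boxes)):
            raw = ocr_label(box, gray, engine)
            leaf.label = sanitize_label(raw, k)

        stage = "serialize"
        if config.normalize_lengths:
            tree = serialize.normalize_lengths(tree)
        bundle = OutputBundle(
            newick=serialize.to_newick(tree, config.include_lengths),
            nexus=serialize.to_nexus(tree, config.include_lengths),
            phyloxml=serialize.to_phyloxml(tree, config.include_lengths),
            svg=serialize.to_svg_overlay(
                contours, boxes, scale_report, (gray.shape[1], gray.shape[0])
            ),
            log=log,
        )
        return RecognitionResult(
            status="success",
            tree=tree,
            bundle=bundle,
            scale_report=scale_report,
            cleaning_report=cleaning_report,
        )
    except PhylopixError as exc:
        return RecognitionResult(status="failed", stage=stage, reason=str(exc))
    except RecursionError:
        return RecognitionResult(
            status="failed", stage=stage, reason="structure too deeply nested"
        )


def run_pipeline(
    path: str | Path, config: PipelineConfig | None = None
) -> RecognitionResult:
    """Full recognition run on an image file; writes outputs when configured.

    Never raises for recognition failures — the result's ``status`` carries
    the failing stage and reason. Only I/O errors while writing the output
    files propagate.
    """
    config = config or PipelineConfig()
    try:
        gray = raster.load_image(path)
    except PhylopixError as exc:
        return RecognitionResult(status="failed", stage="load", reason=str(exc))
    result = recognize_gray(gray, config)
    if result.ok and config.out_dir is not None:
        stem = config.stem or Path(path).stem
        result.bundle.write(config.out_dir, stem)
    return result


def validate_prerequisites(tree: RecognizedTree) -> list[str]:
    """Prerequisite violations of a built tree (empty list = none)."""
    return tree.validate()
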