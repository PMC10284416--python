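"""Evaluation protocol: staged timing, region-cropped PSNR, model comparison.

A run is timed in two stages — smoothing + edge indicator ("noise
reduction") and evolution + contour extraction ("edge extraction") — and
scored by the PSNR between the clean reference crop and the smoothed-image
crop. ``compare_models`` runs the Gaussian variant ("before") and the
bilateral variant ("after") from a shared initial level set and emits the
paired report in the column order

    noise reduction | edge extraction | total length | PSNR
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .core import (
    Contour,
    EnergyTrace,
    EvolveParams,
    LevelSet,
    evolve,
    extract_zero_contour,
    init_binary_step,
)
from .edges import (
    EdgeMap,
    edge_indicator_bilateral,
    edge_indicator_gaussian,
)
from .errors import ValidationError
from .filters import (
    BilateralSpec,
    GaussianSpec,
    bilateral_smooth,
    gaussian_smooth,
)
from .image import (
    GrayImage,
    Region,
    add_gaussian_noise,
    crop_region,
    make_disk_image,
    read_gray,
    write_gray,
)

__all__ = [
    "EvalReport",
    "RunConfig",
    "RunResult",
    "psnr",
    "mean_contour_distance",
    "hausdorff",
    "run_segmentation",
    "compare_models",
]

REPORT_COLUMNS = (
    "Noise reduction",
    "Edge extraction",
    "Total length",
    "Peak Signal to Noise Ratio",
)


def psnr(reference: GrayImage, test: GrayImage, peak: float = 255.0) -> float:
    """10 log10(peak^2 / MSE) in dB; ``inf`` signals identical images."""
    if reference.shape != test.shape:
        raise ValidationError(
            f"shape mismatch {reference.shape} vs {test.shape}"
        )
    if peak <= 0:
        raise ValidationError(f"peak must be > 0, got {peak}")
    mse = float(((reference.pixels - test.pixels) ** 2).mean())
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / mse))


def _points_of(obj) -> np.ndarray:
    pts = obj.points if isinstance(obj, Contour) else np.asarray(obj, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] == 0:
        raise ValidationError("need a non-empty (n, 2) point set")
    return pts


def mean_contour_distance(contour, truth) -> float:
    """Mean nearest-neighbour distance from contour points to truth points."""
    cpts = _points_of(contour)
    tpts = _points_of(truth)
    dists, _ = cKDTree(tpts).query(cpts)
    return float(dists.mean())


def hausdorff(contour, truth) -> float:
    """Symmetric Hausdorff distance between the two point sets."""
    cpts = _points_of(contour)
    tpts = _points_of(truth)
    d_ct, _ = cKDTree(tpts).query(cpts)
    d_tc, _ = cKDTree(cpts).query(tpts)
    return float(max(d_ct.max(), d_tc.max()))


@dataclass
class EvalReport:
    """One row of the before/after comparison table."""

    model: str  # "before" (gaussian) | "after" (bilateral)
    noise_reduction_seconds: float
    edge_extraction_seconds: float
    psnr_db: float
    psnr_region: Region

    @property
    def total_seconds(self) -> float:
        return self.noise_reduction_seconds + self.edge_extraction_seconds

    def row(self) -> list:
        return [
            self.model,
            self.noise_reduction_seconds,
            self.edge_extraction_seconds,
            self.total_seconds,
            self.psnr_db,
        ]


@dataclass
class RunConfig:
    """Everything one segmentation run needs.

    Exactly one of ``input_path`` (external image) or the disk-fixture
    fields is used; when ``input_path`` is None a noisy synthetic disk is
    generated from (``fixture_size``, ``fixture_radius``, ``noise_sigma``,
    ``seed``) and its clean version is the PSNR reference.
    """

    variant: str = "bilateral"  # "gaussian" | "bilateral"
    input_path: str | None = None
    fixture_size: tuple[int, int] = (128, 128)
    fixture_radius: float = 30.0
    fixture_fg: float = 200.0
    fixture_bg: float = 50.0
    noise_sigma: float = 10.0
    seed: int = 0
    gaussian: GaussianSpec = field(default_factory=lambda: GaussianSpec(1.5))
    bilateral: BilateralSpec = field(
        default_factory=lambda: BilateralSpec(1.5, 75.0)
    )
    params: EvolveParams = field(default_factory=EvolveParams)
    init_margin: int = 14  # rectangle seed mask inset from the frame
    snapshot_iters: tuple[int, ...] = ()
    psnr_region: Region | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("gaussian", "bilateral"):
            raise ValidationError(
                f"variant must be 'gaussian' or 'bilateral', got {self.variant!r}"
            )


@dataclass
class RunResult:
    contours: list[Contour]
    report: EvalReport
    trace: EnergyTrace
    final: LevelSet
    clean: GrayImage
    noisy: GrayImage
    smoothed: GrayImage
    truth_boundary: np.ndarray | None = None


def _load_inputs(config: RunConfig):
    """Return (clean, noisy, truth_boundary_or_None)."""
    if config.input_path is not None:
        img = read_gray(config.input_path)
        noisy = (
            add_gaussian_noise(img, config.noise_sigma, config.seed)
            if config.noise_sigma > 0
            else img
        )
        return img, noisy, None
    h, w = config.fixture_size
    clean, truth = make_disk_image(
        h,
        w,
        center=(h / 2.0, w / 2.0),
        radius=config.fixture_radius,
        fg=config.fixture_fg,
        bg=config.fixture_bg,
    )
    noisy = add_gaussian_noise(clean, config.noise_sigma, config.seed)
    return clean, noisy, truth.boundary


def _seed_mask(shape: tuple[int, int], margin: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    mask[margin:-margin, margin:-margin] = True
    return mask


def _default_region(shape: tuple[int, int]) -> Region:
    return Region(1, shape[0], 1, shape[1])


def _smooth_and_edges(
    noisy: GrayImage, config: RunConfig
) -> tuple[GrayImage, EdgeMap]:
    if config.variant == "gaussian":
        smoothed = gaussian_smooth(noisy, config.gaussian)
        g = edge_indicator_gaussian(noisy, config.gaussian)
    else:
        smoothed = bilateral_smooth(noisy, config.bilateral)
        g = edge_indicator_bilateral(noisy, config.bilateral)
    return smoothed, g


def run_segmentation(config: RunConfig) -> RunResult:
    """Full pipeline: smooth, build g, evolve, extract, time and score."""
    clean, noisy, truth_boundary = _load_inputs(config)

    t0 = time.perf_counter()
    smoothed, g = _smooth_and_edges(noisy, config)
    t1 = time.perf_counter()

    phi0 = init_binary_step(
        noisy.shape, _seed_mask(noisy.shape, config.init_margin), config.params.c0
    )
    hook, snap_store = _make_snapshot_hook(config, noisy)
    final, trace = evolve(
        phi0,
        g,
        config.params,
        snapshot_iters=config.snapshot_iters,
        snapshot_hook=hook,
    )
    contours = extract_zero_contour(final)
    t2 = time.perf_counter()

    region = config.psnr_region or _default_region(noisy.shape)
    score = psnr(crop_region(clean, region), crop_region(smoothed, region))
    report = EvalReport(
        model="before" if config.variant == "gaussian" else "after",
        noise_reduction_seconds=t1 - t0,
        edge_extraction_seconds=t2 - t1,
        psnr_db=score,
        psnr_region=region,
    )
    result = RunResult(
        contours=contours,
        report=report,
        trace=trace,
        final=final,
        clean=clean,
        noisy=noisy,
        smoothed=smoothed,
        truth_boundary=truth_boundary,
    )
    if config.out_dir is not None:
        _write_outputs(config, result, snap_store)
    return result


def _make_snapshot_hook(config: RunConfig, image: GrayImage):
    store: dict[int, LevelSet] = {}

    def hook(it: int, ls: LevelSet) -> None:
        store[it] = LevelSet(ls.phi.copy())

    return hook, store


def _overlay(image: GrayImage, contours: list[Contour]) -> np.ndarray:
    """RGB overlay: grayscale base with the contour burnt in red."""
    base = np.clip(image.pixels * (255.0 / image.value_range), 0, 255)
    rgb = np.stack([base] * 3, axis=-1).astype(np.uint8)
    for contour in contours:
        rr = np.clip(np.rint(contour.points[:, 0]).astype(int), 0, image.height - 1)
        cc = np.clip(np.rint(contour.points[:, 1]).astype(int), 0, image.width - 1)
        rgb[rr, cc] = (255, 0, 0)
    return rgb


def _write_outputs(config: RunConfig, result: RunResult, snapshots) -> None:
    import imageio.v3 as iio

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.variant
    result.trace.to_csv(out / f"trace_{tag}.csv")
    with open(out / f"contours_{tag}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["contour", "row", "col"])
        for idx, contour in enumerate(result.contours):
            for r, c in contour.points:
                writer.writerow([idx, f"{r:.4f}", f"{c:.4f}"])
    write_gray(out / f"smoothed_{tag}.png", result.smoothed)
    iio.imwrite(
        out / f"overlay_{tag}_final.png",
        _overlay(result.noisy, result.contours),
    )
    for it, ls in snapshots.items():
        iio.imwrite(
            out / f"overlay_{tag}_iter{it:04d}.png",
            _overlay(result.noisy, extract_zero_contour(ls)),
        )
    with open(out / f"report_{tag}.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("Model",) + REPORT_COLUMNS)
        writer.writerow(result.report.row())


def compare_models(config: RunConfig) -> tuple[EvalReport, EvalReport]:
    """Run the Gaussian ("before") and bilateral ("after") variants.

    Both runs share the same input image, initial level set and evolution
    parameters; only the smoothing filter behind g differs.
    """
    before = run_segmentation(replace(config, variant="gaussian"))
    after = run_segmentation(replace(config, variant="bilateral"))
    if config.out_dir is not None:
        _write_comparison(config, before.report, after.report)
    return before.report, after.report


def _format_table(before: EvalReport, after: EvalReport) -> str:
    lines = [
        "| Model | " + " | ".join(REPORT_COLUMNS) + " |",
        "|---|---|---|---|---|",
    ]
    for rep in (before, after):
        label = "Before improvement" if rep.model == "before" else "After improvement"
        lines.append(
            f"| {label} | {rep.noise_reduction_seconds:.4f} | "
            f"{rep.edge_extraction_seconds:.4f} | {rep.total_seconds:.4f} | "
            f"{rep.psnr_db:.4f} |"
        )
    return "\n".join(lines)


def _write_comparison(
    config: RunConfig, before: EvalReport, after: EvalReport
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "comparison.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("Model",) + REPORT_COLUMNS)
        writer.writerow(before.row())
        writer.writerow(after.row())
    (out / "comparison.md").write_text(_format_table(before, after) + "\n")
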