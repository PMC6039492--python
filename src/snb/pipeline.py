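"""End-to-end orchestration: per-cell QC and maps, cohort pooling, mixture fit.

``run_cell`` applies the per-cell chain in acquisition order — photobleach QC,
background threshold, optional exclusion mask, per-pixel N&B maps, brightness
histogram, Gaussian peak, expression level — and returns a flat record.
Rejected cells carry a machine-readable rejection code and contribute nothing
downstream.  ``run_cohort`` pools accepted cells within an expression window
into an accumulated histogram, runs the constrained log-normal mixture fit
against a monomer anchor, and emits per-cell and per-component tables.

All fits are deterministically initialized, so identical inputs and
configuration produce byte-identical CSV outputs regardless of the order in
which cells are processed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nb, stoichiometry as st
from .stack import ImageStack, read_stack

__all__ = ["RunConfig", "CellRecord", "CohortReport", "run_cell", "run_cohort"]

log = logging.getLogger("snb.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    calibration: st.CalibrationReference = field(default_factory=st.CalibrationReference)
    expression_window: tuple[float, float] = (st.EXPRESSION_LOW, st.EXPRESSION_HIGH)
    threshold_method: str = "otsu"
    threshold_level: float | None = None
    bin_width: float | None = None
    min_pixels: int = 200
    variance_ddof: int = 1
    detrend: bool = False
    smooth_box: int = 3
    include_monomer_component: bool = False
    seed: int = 0
    output_dir: Path | None = None

    def __post_init__(self) -> None:
        lo, hi = self.expression_window
        if not lo < hi:
            raise ValueError("expression window low must be < high")


@dataclass
class CellRecord:
    """Per-cell analysis outcome; stoichiometry fields are None when the
    cell is rejected."""

    roi_id: str
    accepted: bool
    reject_code: str = ""
    photobleach_fraction: float = float("nan")
    n_pixels: int = 0
    expression: float | None = None
    regime: str | None = None
    peak_brightness: float | None = None
    subunits_per_complex: float | None = None
    brightness: st.CellBrightness | None = field(default=None, repr=False)

    def to_row(self) -> dict:
        row = asdict(self)
        row.pop("brightness")
        return row


@dataclass
class CohortReport:
    """Cohort-level outcome: per-cell table, accumulated-histogram mixture
    fit, and species fractions for the expression window."""

    cells: pd.DataFrame
    mixture: st.MixtureFit | None
    fractions: dict[str, float]
    window: tuple[float, float]
    n_accepted: int
    n_in_window: int

    def component_table(self) -> pd.DataFrame:
        if self.mixture is None:
            return pd.DataFrame(
                columns=["role", "mode", "shape", "area", "fraction", "mode_fixed"]
            )
        rows = [
            {
                "role": c.role,
                "mode": c.mode,
                "shape": c.shape,
                "area": c.area,
                "fraction": self.fractions.get(c.role, 0.0),
                "mode_fixed": c.mode_fixed,
            }
            for c in self.mixture.components
        ]
        return pd.DataFrame(rows)


def _load_mask(path: str | Path) -> np.ndarray:
    """Read a boolean exclusion mask from a single-page TIFF/PNG."""
    from skimage.io import imread

    arr = imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def run_cell(
    stack: ImageStack | str | Path,
    config: RunConfig,
    exclusion_mask: np.ndarray | str | Path | None = None,
    roi_id: str | None = None,
) -> CellRecord:
    """Analyze one cell's stack: QC -> threshold -> exclusions -> maps ->
    histogram -> Gaussian peak -> expression."""
    if not isinstance(stack, ImageStack):
        path = Path(stack)
        roi_id = roi_id or path.stem
        stack = read_stack(path)
    roi_id = roi_id or "cell"

    qc = nb.photobleach_fraction(stack)
    if not qc.accepted:
        code = "QC_NONPOSITIVE_FIT" if np.isnan(qc.photobleach_fraction) else "QC_PHOTOBLEACH"
        log.warning("%s rejected: %s (%s)", roi_id, qc.reason, code)
        return CellRecord(
            roi_id=roi_id,
            accepted=False,
            reject_code=code,
            photobleach_fraction=qc.photobleach_fraction,
        )

    maps = nb.compute_nb_maps(stack, ddof=config.variance_ddof, detrend=config.detrend)
    mask = nb.threshold_mask(
        maps.mean_map, method=config.threshold_method, level=config.threshold_level  # type: ignore[arg-type]
    )
    if exclusion_mask is not None:
        if not isinstance(exclusion_mask, np.ndarray):
            exclusion_mask = _load_mask(exclusion_mask)
        mask = nb.apply_exclusions(mask, exclusion_mask)
    mask &= maps.valid_mask
    if not mask.any():
        log.warning("%s rejected: empty mask after thresholding (MASK_EMPTY)", roi_id)
        return CellRecord(
            roi_id=roi_id,
            accepted=False,
            reject_code="MASK_EMPTY",
            photobleach_fraction=qc.photobleach_fraction,
        )

    expression = st.expression_level(maps.mean_map, mask, config.calibration)
    # peak fitting uses a boxcar-smoothed brightness map: averaging shrinks
    # the skew of the per-pixel variance noise that otherwise drags the
    # fitted histogram peak below the true brightness
    smoothed = nb.smooth_brightness(maps.brightness_map, config.smooth_box)
    try:
        hist = st.roi_brightness_histogram(
            smoothed,
            mask,
            bin_width=config.bin_width,
            calibration=config.calibration,
            min_pixels=config.min_pixels,
            roi_id=roi_id,
            expression=expression,
        )
    except ValueError as exc:
        log.warning("%s rejected: %s (TOO_FEW_PIXELS)", roi_id, exc)
        return CellRecord(
            roi_id=roi_id,
            accepted=False,
            reject_code="TOO_FEW_PIXELS",
            photobleach_fraction=qc.photobleach_fraction,
        )
    peak = st.fit_gaussian_peak(hist, calibration=config.calibration)
    if not peak.converged:
        log.warning("%s: Gaussian fit fell back to the modal bin (FIT_FALLBACK)", roi_id)
    values = maps.brightness_map[mask]
    values = values[np.isfinite(values)]
    return CellRecord(
        roi_id=roi_id,
        accepted=True,
        photobleach_fraction=qc.photobleach_fraction,
        n_pixels=int(mask.sum()),
        expression=expression,
        regime=st.classify_expression_regime(expression),
        peak_brightness=peak.peak_brightness,
        subunits_per_complex=st.subunits_per_complex(peak.peak_brightness, config.calibration),
        brightness=st.CellBrightness(roi_id=roi_id, expression=expression, values=values),
    )


def run_cohort(
    cell_records: Sequence[CellRecord],
    config: RunConfig,
    monomer: st.LogNormalComponent | None = None,
) -> CohortReport:
    """Pool accepted cells, fit the constrained mixture in the configured
    expression window, and tabulate results.

    ``monomer`` is the log-normal anchor from a monomeric calibration sample;
    if omitted, an anchor at the calibration eps0 is used (the free dye peak).
    Cell order does not affect any output.
    """
    if not cell_records:
        raise ValueError("empty cohort")
    records = sorted(cell_records, key=lambda r: r.roi_id)
    accepted = [r for r in records if r.accepted]
    if not accepted:
        raise ValueError("no accepted cells in the cohort")
    table = pd.DataFrame([r.to_row() for r in records])

    lo, hi = config.expression_window
    in_window = [
        r for r in accepted if r.brightness is not None and lo <= r.brightness.expression < hi
    ]
    mixture = None
    fractions: dict[str, float] = {}
    if in_window:
        hist = st.accumulate_histograms(
            [r.brightness for r in in_window],  # type: ignore[misc]
            window=config.expression_window,
            bin_width=config.bin_width,
            calibration=config.calibration,
        )
        if monomer is None:
            monomer = st.LogNormalComponent(
                mode=config.calibration.epsilon0, shape=0.3, area=1.0, role="monomer"
            )
        mixture = st.fit_lognormal_mixture(
            hist,
            monomer,
            expression_window=config.expression_window,
            n_cells=len(in_window),
            include_monomer=config.include_monomer_component,
        )
        if mixture.fallback_two_component:
            log.warning("mixture fit degenerated to two components (FIT_FALLBACK_2COMP)")
        fractions = mixture.fractions
    return CohortReport(
        cells=table,
        mixture=mixture,
        fractions=fractions,
        window=config.expression_window,
        n_accepted=len(accepted),
        n_in_window=len(in_window),
    )


def write_reports(report: CohortReport, config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write per-cell CSV, component CSV, and a JSON run manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out_dir / "cells.csv",
        "components": out_dir / "mixture_components.csv",
        "manifest": out_dir / "manifest.json",
    }
    report.cells.to_csv(paths["cells"], index=False)
    report.component_table().to_csv(paths["components"], index=False)
    manifest = {
        "seed": config.seed,
        "expression_window": list(report.window),
        "n_accepted": report.n_accepted,
        "n_in_window": report.n_in_window,
        "fractions": report.fractions,
        "calibration": asdict(config.calibration),
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return paths
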