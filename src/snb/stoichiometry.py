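"""From brightness maps to stoichiometry and oligomeric species fractions.

Per cell, the histogram of per-pixel molecular brightness values is fitted
with a Gaussian; its centre is the brightness of the major receptor
population, and dividing by the calibrated monomer brightness eps0 gives the
number of subunits per diffusing complex.  The ROI expression level is the
median mean-map intensity divided by eps0, in subunits per effective volume,
and cells fall into three regimes: low (< 90), physiological [90, 600), and
high (>= 600 subunits/V_eff).

Across cells within an expression window, all pixel brightness values are
pooled into an accumulated histogram (normalized to unit area) and decomposed
into a constrained sum of log-normal components: a dimer component whose peak
is fixed at twice the monomer anchor, a tetramer at four times the anchor,
and a larger-oligomer component with a free peak position.  Species fractions
are the areas under the individual components divided by the total area.

Log-normals are parameterized by their mode m and log-space SD sigma:
density(x) = area / (x sigma sqrt(2 pi)) * exp(-(ln x - mu)^2 / (2 sigma^2))
with mu = ln m + sigma^2, so the stated peak positions are anchored exactly
and component areas have a closed form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import lmfit
import numpy as np

__all__ = [
    "CalibrationReference",
    "BrightnessHistogram",
    "GaussianPeakFit",
    "LogNormalComponent",
    "MixtureFit",
    "CellBrightness",
    "roi_brightness_histogram",
    "fit_gaussian_peak",
    "subunits_per_complex",
    "expression_level",
    "classify_expression_regime",
    "accumulate_histograms",
    "fit_monomer_reference",
    "fit_lognormal_mixture",
    "species_fractions",
    "expression_scale_external",
]

#: default expression window bounds, subunits per effective volume
EXPRESSION_LOW = 90.0
EXPRESSION_HIGH = 600.0

Role = Literal["monomer", "dimer", "tetramer", "larger"]


@dataclass(frozen=True)
class CalibrationReference:
    """Monomer brightness calibration.

    Defaults are the free-dye reference: 0.048 +/- 0.001 counts per 40 us
    dwell per molecule, with a 0.355 fL effective observation volume.
    """

    epsilon0: float = 0.048
    epsilon0_sem: float = 0.001
    effective_volume_fl: float = 0.355
    dwell_time_us: float = 40.0

    def __post_init__(self) -> None:
        if self.epsilon0 <= 0:
            raise ValueError("epsilon0 must be positive")


@dataclass
class BrightnessHistogram:
    """Histogram of per-pixel molecular brightness values.

    ``counts`` may be raw pixel counts or unit-area densities; ``n_pixels``
    always records the number of pixels pooled.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_pixels: int
    roi_id: str = ""
    expression: float = float("nan")

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if len(self.bin_edges) != len(self.counts) + 1:
            raise ValueError("need len(edges) == len(counts) + 1")
        if not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError("bin edges must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("histogram counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def normalized(self) -> "BrightnessHistogram":
        """Unit-area copy (density normalization)."""
        area = float(np.sum(self.counts * np.diff(self.bin_edges)))
        if area == 0:
            raise ValueError("cannot normalize an empty histogram")
        return BrightnessHistogram(
            bin_edges=self.bin_edges.copy(),
            counts=self.counts / area,
            n_pixels=self.n_pixels,
            roi_id=self.roi_id,
            expression=self.expression,
        )


@dataclass
class GaussianPeakFit:
    """Gaussian fit of a brightness histogram; the centre is the brightness
    of the major receptor population in the ROI."""

    peak_brightness: float
    width: float
    amplitude: float
    fit_rmse: float
    subunits_per_complex: float | None = None
    converged: bool = True


@dataclass
class LogNormalComponent:
    """One log-normal component of the brightness mixture."""

    mode: float
    shape: float
    area: float
    role: Role
    mode_fixed: bool = False

    @property
    def amplitude(self) -> float:
        """Peak height of the component density."""
        return float(
            self.area
            * np.exp(-self.shape**2 / 2.0)
            / (self.mode * self.shape * np.sqrt(2.0 * np.pi))
        )

    def density(self, x: np.ndarray) -> np.ndarray:
        return _lognormal_density(np.asarray(x, dtype=float), self.area, self.mode, self.shape)


@dataclass
class MixtureFit:
    """Constrained log-normal decomposition of an accumulated histogram."""

    components: list[LogNormalComponent]
    fractions: dict[str, float]
    expression_window: tuple[float, float]
    n_cells: int
    goodness: float
    converged: bool = True
    fallback_two_component: bool = False


@dataclass
class CellBrightness:
    """Valid per-pixel brightness values of one cell, with its expression."""

    roi_id: str
    expression: float
    values: np.ndarray = field(repr=False)


def _lognormal_density(x: np.ndarray, area: float, mode: float, shape: float) -> np.ndarray:
    """Mode-parameterized log-normal: integrates to ``area``, peaks at ``mode``."""
    out = np.zeros_like(x, dtype=float)
    pos = x > 0
    mu = np.log(mode) + shape**2
    xp = x[pos]
    out[pos] = (
        area
        / (xp * shape * np.sqrt(2.0 * np.pi))
        * np.exp(-((np.log(xp) - mu) ** 2) / (2.0 * shape**2))
    )
    return out


def roi_brightness_histogram(
    brightness_map: np.ndarray,
    mask: np.ndarray,
    bin_width: float | None = None,
    calibration: CalibrationReference | None = None,
    min_pixels: int = 200,
    roi_id: str = "",
    expression: float = float("nan"),
) -> BrightnessHistogram:
    """Histogram of brightness values over the masked pixels.

    Negative brightness values are included (the per-pixel estimator is
    symmetric about the truth).  The default bin width is eps0/12.
    """
    brightness_map = np.asarray(brightness_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != brightness_map.shape:
        raise ValueError("mask and brightness map shapes differ")
    values = brightness_map[mask]
    values = values[np.isfinite(values)]
    if len(values) < min_pixels:
        raise ValueError(f"only {len(values)} valid pixels; need at least {min_pixels}")
    if bin_width is None:
        eps0 = (calibration or CalibrationReference()).epsilon0
        bin_width = eps0 / 12.0
    lo = np.floor(values.min() / bin_width) * bin_width
    hi = np.ceil(values.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return BrightnessHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        n_pixels=len(values),
        roi_id=roi_id,
        expression=expression,
    )


def _weighted_quantile(centers: np.ndarray, weights: np.ndarray, q: float) -> float:
    cum = np.cumsum(weights)
    if cum[-1] == 0:
        return float(centers[len(centers) // 2])
    return float(np.interp(q * cum[-1], cum, centers))


def fit_gaussian_peak(
    hist: BrightnessHistogram, calibration: CalibrationReference | None = None
) -> GaussianPeakFit:
    """Nonlinear least-squares Gaussian fit over the full histogram.

    Initialization: centre at the modal bin, width from the histogram IQR
    (IQR/1.349), amplitude at the modal height.  On non-convergence the modal
    bin centre is returned with a warning and ``converged=False``.
    """
    x = hist.bin_centers
    y = hist.counts
    if len(x) < 4:
        raise ValueError("histogram too coarse for a Gaussian fit")
    i_mode = int(np.argmax(y))
    mu0 = float(x[i_mode])
    a0 = float(y[i_mode])
    iqr = _weighted_quantile(x, y, 0.75) - _weighted_quantile(x, y, 0.25)
    sigma0 = max(iqr / 1.349, hist.bin_width)

    model = lmfit.models.GaussianModel()
    # lmfit's amplitude is the area; convert the height guess
    params = model.make_params(
        center=mu0, sigma=sigma0, amplitude=a0 * sigma0 * np.sqrt(2.0 * np.pi)
    )
    params["sigma"].set(min=hist.bin_width / 10.0)
    try:
        result = model.fit(y, params, x=x)
        converged = result.success
    except Exception:
        converged = False
    if not converged:
        warnings.warn("Gaussian peak fit did not converge; using the modal bin centre",
                      RuntimeWarning, stacklevel=2)
        peak, width, height, rmse = mu0, sigma0, a0, float("nan")
    else:
        peak = float(result.params["center"].value)
        width = float(result.params["sigma"].value)
        height = float(result.params["height"].value)
        rmse = float(np.sqrt(np.mean(result.residual**2)))
    subunits = peak / calibration.epsilon0 if calibration is not None else None
    return GaussianPeakFit(
        peak_brightness=peak,
        width=width,
        amplitude=height,
        fit_rmse=rmse,
        subunits_per_complex=subunits,
        converged=converged,
    )


def subunits_per_complex(peak_brightness: float, calibration: CalibrationReference) -> float:
    """Number of subunits per diffusing complex: peak brightness / eps0.

    Summaries report this to 2 decimals.
    """
    return peak_brightness / calibration.epsilon0


def expression_level(
    mean_map: np.ndarray, mask: np.ndarray, calibration: CalibrationReference
) -> float:
    """ROI expression in subunits per effective volume: median masked
    intensity divided by eps0."""
    mean_map = np.asarray(mean_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask selects no pixels")
    return float(np.median(mean_map[mask]) / calibration.epsilon0)


def classify_expression_regime(
    expression: float, low: float = EXPRESSION_LOW, high: float = EXPRESSION_HIGH
) -> str:
    """Expression regime: 'low' (< low), 'physiological' [low, high),
    'high' (>= high).  Window edges are closed-left, open-right."""
    if expression < 0:
        raise ValueError("expression must be non-negative")
    if expression < low:
        return "low"
    if expression < high:
        return "physiological"
    return "high"


def accumulate_histograms(
    cells: Sequence[CellBrightness],
    window: tuple[float, float] = (EXPRESSION_LOW, EXPRESSION_HIGH),
    bin_width: float | None = None,
    calibration: CalibrationReference | None = None,
) -> BrightnessHistogram:
    """Pool pixel brightness values from all cells whose expression lies in
    ``window`` (closed-left, open-right) and return a unit-area histogram."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window low must be < high")
    pooled = [c.values[np.isfinite(c.values)] for c in cells if lo <= c.expression < hi]
    if not pooled:
        raise ValueError(f"no cells with expression in [{lo}, {hi})")
    values = np.concatenate(pooled)
    if bin_width is None:
        eps0 = (calibration or CalibrationReference()).epsilon0
        bin_width = eps0 / 12.0
    lo_e = np.floor(values.min() / bin_width) * bin_width
    hi_e = np.ceil(values.max() / bin_width) * bin_width
    n_bins = max(int(round((hi_e - lo_e) / bin_width)), 1)
    edges = lo_e + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(values, bins=edges, density=True)
    return BrightnessHistogram(
        bin_edges=edges,
        counts=counts,
        n_pixels=len(values),
        roi_id=f"accumulated[{lo:g},{hi:g})",
        expression=float("nan"),
    )


def _positive_support(hist: BrightnessHistogram) -> tuple[np.ndarray, np.ndarray]:
    """Bin centres strictly above zero with their counts (log-normal support)."""
    x = hist.bin_centers
    keep = x > 0
    return x[keep], hist.counts[keep]


def fit_monomer_reference(hist_calibration: BrightnessHistogram) -> LogNormalComponent:
    """Single log-normal least-squares fit of the monomer calibration
    histogram; its mode anchors the dimer/tetramer peaks of the mixture."""
    x, y = _positive_support(hist_calibration)
    if len(x) < 4 or y.sum() == 0:
        raise ValueError("calibration histogram has no usable positive support")
    i_mode = int(np.argmax(y))
    mode0 = float(x[i_mode])
    area0 = float(np.sum(y) * hist_calibration.bin_width)

    params = lmfit.Parameters()
    params.add("area", value=area0, min=0.0)
    params.add("mode", value=mode0, min=float(x[0]) / 2.0, max=float(x[-1]))
    params.add("shape", value=0.3, min=0.05, max=1.5)

    def resid(p: lmfit.Parameters) -> np.ndarray:
        return _lognormal_density(x, p["area"].value, p["mode"].value, p["shape"].value) - y

    result = lmfit.minimize(resid, params, method="leastsq")
    if not result.success:
        raise RuntimeError("monomer reference log-normal fit did not converge")
    p = result.params
    return LogNormalComponent(
        mode=float(p["mode"].value),
        shape=float(p["shape"].value),
        area=float(p["area"].value),
        role="monomer",
        mode_fixed=False,
    )


def fit_lognormal_mixture(
    accumulated_hist: BrightnessHistogram,
    monomer: LogNormalComponent,
    n_components: int = 3,
    expression_window: tuple[float, float] = (EXPRESSION_LOW, EXPRESSION_HIGH),
    n_cells: int = 0,
    include_monomer: bool = False,
) -> MixtureFit:
    """Constrained log-normal mixture fit of an accumulated histogram.

    The dimer peak is fixed at 2x the monomer anchor mode and the tetramer
    at 4x; the larger-oligomer peak is free with a lower bound above the
    tetramer peak.  Shapes are free within [0.05, 1.5] (log-space SD) and
    areas are non-negative.  Fractions are component areas over the total
    area.  If the larger-oligomer component degenerates to zero area the fit
    is reported as a two-component (D/T) fallback.  ``include_monomer`` adds
    a fixed-mode monomer component for low-expression regimes.

    Negative-brightness bins are outside the log-normal support and are
    excluded from the fit.
    """
    if n_components != 3:
        raise ValueError("the decomposition is defined for 3 components (D/T/X)")
    x, y = _positive_support(accumulated_hist)
    if len(x) < 8:
        raise ValueError("accumulated histogram has too little positive support")
    m = monomer.mode
    bw = accumulated_hist.bin_width
    # pad with empty bins beyond the observed support: the density is known
    # to be zero there, which pins components that would otherwise drift
    # outside the data range at no residual cost
    x_hi = max(float(x[-1]), 9.0 * m)
    if x_hi > x[-1]:
        pad = np.arange(x[-1] + bw, x_hi + bw, bw)
        x = np.concatenate([x, pad])
        y = np.concatenate([y, np.zeros(len(pad))])
    total_area = float(np.sum(y) * bw)

    params = lmfit.Parameters()
    roles: list[tuple[str, float, bool]] = []
    if include_monomer:
        params.add("area_m", value=total_area / 10.0, min=0.0)
        params.add("shape_m", value=monomer.shape, min=0.05, max=1.5)
        roles.append(("monomer", m, True))
    params.add("area_d", value=total_area / 2.0, min=0.0)
    params.add("shape_d", value=0.4, min=0.05, max=1.5)
    roles.append(("dimer", 2.0 * m, True))
    params.add("area_t", value=total_area / 3.0, min=0.0)
    params.add("shape_t", value=0.3, min=0.05, max=1.5)
    roles.append(("tetramer", 4.0 * m, True))
    params.add("area_x", value=total_area / 6.0, min=0.0)
    params.add("shape_x", value=0.2, min=0.05, max=1.5)
    params.add("mode_x", value=8.0 * m, min=4.2 * m, max=max(float(x[-1]), 8.5 * m))

    suffix = {"monomer": "m", "dimer": "d", "tetramer": "t", "larger": "x"}

    def model_curve(p: lmfit.Parameters, xs: np.ndarray) -> np.ndarray:
        out = np.zeros_like(xs)
        for role, mode, _fixed in roles:
            s = suffix[role]
            out += _lognormal_density(xs, p[f"area_{s}"].value, mode, p[f"shape_{s}"].value)
        out += _lognormal_density(xs, p["area_x"].value, p["mode_x"].value, p["shape_x"].value)
        return out

    def resid(p: lmfit.Parameters) -> np.ndarray:
        return model_curve(p, x) - y

    result = lmfit.minimize(resid, params, method="leastsq")
    p = result.params
    converged = bool(result.success)
    if not converged:
        warnings.warn("log-normal mixture fit did not converge", RuntimeWarning, stacklevel=2)

    components = [
        LogNormalComponent(
            mode=mode,
            shape=float(p[f"shape_{suffix[role]}"].value),
            area=float(p[f"area_{suffix[role]}"].value),
            role=role,  # type: ignore[arg-type]
            mode_fixed=True,
        )
        for role, mode, _fixed in roles
    ]
    components.append(
        LogNormalComponent(
            mode=float(p["mode_x"].value),
            shape=float(p["shape_x"].value),
            area=float(p["area_x"].value),
            role="larger",
            mode_fixed=False,
        )
    )
    area_sum = sum(c.area for c in components)
    fallback = False
    if area_sum > 0 and components[-1].area / area_sum < 1e-6:
        # larger-oligomer component degenerated; report the D/T fallback
        components[-1].area = 0.0
        fallback = True
    goodness = float(np.sqrt(np.mean(resid(p) ** 2)))
    fit = MixtureFit(
        components=components,
        fractions={},
        expression_window=expression_window,
        n_cells=n_cells,
        goodness=goodness,
        converged=converged,
        fallback_two_component=fallback,
    )
    fit.fractions = species_fractions(fit)
    return fit


def species_fractions(fit: MixtureFit) -> dict[str, float]:
    """Normalized component areas; they sum to 1."""
    total = sum(c.area for c in fit.components)
    if total <= 0:
        raise ValueError("mixture fit has zero total area")
    return {c.role: c.area / total for c in fit.components}


def expression_scale_external(
    intensities: np.ndarray | Sequence[float],
    reference_mean_expression: float,
    reference_mean_intensity: float,
) -> np.ndarray:
    """Rescale external (e.g. immunofluorescence) intensities to the
    expression units of the fluctuation analysis, by the ratio of the
    reference mean expression to the reference mean intensity.

    A pure rescaling: the coefficient of variation is preserved exactly.
    """
    if reference_mean_intensity <= 0:
        raise ValueError("reference_mean_intensity must be positive")
    intensities = np.asarray(intensities, dtype=float)
    return intensities * (reference_mean_expression / reference_mean_intensity)
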