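"""Two-channel line-profile quantification of membrane enrichment.

The membrane-to-cytoplasm ratio of a reporter (e.g. a Rho1-activity
sensor or a formin-GFP fusion) is measured along a line drawn from
inside a cell, across its outer membrane, into the surrounding space:

1. the membrane position ``c`` is the global maximum of the membrane
   marker channel (ties broken toward the inside end);
2. the membrane window is the 0.8 um interval ``[c-0.4, c+0.4]``;
3. the background is the mean reporter intensity over the 2 um outside
   flank ``(c+0.4, c+2.4]`` and is subtracted from the whole profile;
4. the membrane term is the mean background-corrected reporter over the
   membrane window, the cytoplasm term the mean over the 2 um inside
   flank ``[c-2.4, c-0.4)``, and the ratio their quotient.

"Integrated intensity within the interval" is realized as the window
mean (integral divided by window length) so the membrane and cytoplasm
terms share units and the ratio is directly comparable across window
sizes; this is the central interpretive decision of the module.

Junctional peak intensity (e.g. phalloidin at cell-cell contacts) is
quantified by a least-squares Gaussian fit along a ~5 um line, the
fitted peak being normalized against a reference-region mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from skimage.measure import profile_line

from .errors import (
    ConfigError,
    GaussianFitError,
    NonPositiveCytoplasmError,
    WindowFitError,
)

__all__ = [
    "LineProfile",
    "MembraneEnrichment",
    "JunctionFit",
    "extract_line_profile",
    "locate_membrane",
    "membrane_cyto_ratio",
    "analyze_profiles",
    "fit_junction_gaussian",
    "normalize_junction_peak",
]

logger = logging.getLogger(__name__)

#: Half-width of the membrane window (um).
MEM_HALF_WIDTH = 0.4
#: Width of each flanking window (um).
FLANK_WIDTH = 2.0
#: Minimal distance of the membrane peak from either profile end (um).
MIN_MARGIN = MEM_HALF_WIDTH + FLANK_WIDTH
#: Absolute slack used when binning samples into windows, so a sample
#: sitting exactly on a window edge at dx = 0.1 um lands deterministically.
_EDGE_TOL = 1e-9


@dataclass
class LineProfile:
    """Spatially calibrated two-channel intensity profile.

    ``positions`` run from the inside end of the line (0) outward, in um,
    with uniform spacing ``dx``.  ``inside_to_outside`` records whether the
    stored sample order honors that orientation; :meth:`oriented` returns
    an inside-to-outside view either way.
    """

    positions: np.ndarray
    ch_membrane: np.ndarray
    ch_reporter: np.ndarray
    dx: float
    inside_to_outside: bool = True
    profile_id: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.ch_membrane = np.asarray(self.ch_membrane, dtype=float)
        self.ch_reporter = np.asarray(self.ch_reporter, dtype=float)
        n = self.positions.size
        if self.ch_membrane.size != n or self.ch_reporter.size != n:
            raise ConfigError("channel lengths differ from positions")
        if self.dx <= 0:
            raise ConfigError("dx must be positive")
        steps = np.diff(self.positions)
        if n < 2 or np.any(np.abs(steps - self.dx) > 1e-6):
            raise ConfigError("positions must be uniformly spaced at dx (1e-6 um)")
        if self.length < 2 * MIN_MARGIN - _EDGE_TOL:
            raise ConfigError(
                f"profile length {self.length:.2f} um too short; membrane "
                f"window plus flanks need at least {2 * MIN_MARGIN:.1f} um"
            )

    @property
    def length(self) -> float:
        return float(self.positions[-1] - self.positions[0])

    def oriented(self) -> "LineProfile":
        """Inside-to-outside copy (reverses samples if needed)."""
        if self.inside_to_outside:
            return self
        pos = self.positions[::-1]
        pos = pos[0] - pos  # re-anchor so position 0 is the inside end
        return LineProfile(
            positions=pos,
            ch_membrane=self.ch_membrane[::-1].copy(),
            ch_reporter=self.ch_reporter[::-1].copy(),
            dx=self.dx,
            inside_to_outside=True,
            profile_id=self.profile_id,
        )


@dataclass
class MembraneEnrichment:
    """Membrane/cytoplasm quantification of one profile."""

    center_um: float
    background: float
    mem_mean: float
    cyto_mean: float
    ratio: float


@dataclass
class JunctionFit:
    """Gaussian fit of a junctional intensity peak."""

    amplitude: float
    center_um: float
    sigma_um: float
    offset: float
    residual_rms: float

    @property
    def peak_value(self) -> float:
        return self.amplitude + self.offset


def extract_line_profile(
    image: np.ndarray,
    p0: tuple[float, float],
    p1: tuple[float, float],
    *,
    membrane_channel: int = 0,
    reporter_channel: int = 1,
    width_px: int = 8,
    pixel_size_um: float = 0.1,
    profile_id: str = "",
) -> LineProfile:
    """Sample a width-averaged two-channel profile along ``p0 -> p1``.

    Parameters
    ----------
    image
        ``(C, H, W)`` multichannel plane.
    p0, p1
        Line endpoints in pixel coordinates ``(row, col)``; ``p0`` is the
        inside end of the line.
    width_px
        Number of parallel samples averaged across the line (perpendicular
        width), bilinear interpolation.
    pixel_size_um
        Spatial calibration; samples are taken at 1-pixel steps, so the
        profile spacing is ``pixel_size_um``.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ConfigError("image must be a (C, H, W) multichannel plane")
    if width_px < 1:
        raise ConfigError("width_px must be >= 1")
    n_ch, h, w = image.shape
    for ch in (membrane_channel, reporter_channel):
        if not 0 <= ch < n_ch:
            raise ConfigError(f"channel {ch} out of range for {n_ch}-channel image")
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    norm = np.hypot(*d)
    if norm == 0:
        raise ConfigError("line endpoints coincide")
    # Footprint check: endpoints offset by half the perpendicular width
    # must stay inside the image, else samples fall off the data.
    perp = np.array([d[1], -d[0]]) / norm
    half = (width_px - 1) / 2.0
    for end in (p0, p1):
        for sgn in (-1.0, 1.0):
            r, c = end + sgn * half * perp
            if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
                raise WindowFitError("line footprint leaves the image bounds")
    profiles = [
        profile_line(
            image[ch],
            tuple(p0),
            tuple(p1),
            linewidth=width_px,
            order=1,
            mode="constant",
            reduce_func=np.mean,
        )
        for ch in (membrane_channel, reporter_channel)
    ]
    n = profiles[0].size
    positions = np.arange(n) * pixel_size_um
    return LineProfile(
        positions=positions,
        ch_membrane=profiles[0],
        ch_reporter=profiles[1],
        dx=pixel_size_um,
        inside_to_outside=True,
        profile_id=profile_id,
    )


def locate_membrane(profile: LineProfile) -> float:
    """Membrane position: global maximum of the membrane-marker channel.

    Ties are broken toward the smallest position (argmax convention).

    Raises
    ------
    WindowFitError
        If the peak sits within 2.4 um of either profile end, where the
        membrane window plus its flanks would not fit.
    """
    p = profile.oriented()
    idx = int(np.argmax(p.ch_membrane))
    c = float(p.positions[idx])
    if (
        c - p.positions[0] < MIN_MARGIN - _EDGE_TOL
        or p.positions[-1] - c < MIN_MARGIN - _EDGE_TOL
    ):
        raise WindowFitError(
            f"membrane peak at {c:.2f} um leaves no room for the "
            f"{MIN_MARGIN:.1f} um window+flank on one side"
        )
    return c


def membrane_cyto_ratio(profile: LineProfile) -> MembraneEnrichment:
    """Background-corrected membrane/cytoplasm ratio of the reporter.

    See the module docstring for window definitions.  Adding a constant
    to the reporter channel leaves the ratio unchanged (background
    subtraction), as does scaling all intensities by a positive factor.

    Raises
    ------
    NonPositiveCytoplasmError
        If the background-corrected cytoplasmic mean is <= 0; such a
        profile carries no usable ratio and must be excluded.
    """
    p = profile.oriented()
    c = locate_membrane(p)
    x = p.positions
    rel = x - c
    mem = np.abs(rel) <= MEM_HALF_WIDTH + _EDGE_TOL
    out = (rel > MEM_HALF_WIDTH + _EDGE_TOL) & (rel <= MEM_HALF_WIDTH + FLANK_WIDTH + _EDGE_TOL)
    ins = (rel < -(MEM_HALF_WIDTH + _EDGE_TOL)) & (rel >= -(MEM_HALF_WIDTH + FLANK_WIDTH) - _EDGE_TOL)
    background = float(p.ch_reporter[out].mean())
    corrected = p.ch_reporter - background
    mem_mean = float(corrected[mem].mean())
    cyto_mean = float(corrected[ins].mean())
    if cyto_mean <= 0:
        raise NonPositiveCytoplasmError(
            f"profile {p.profile_id!r}: corrected cytoplasmic mean "
            f"{cyto_mean:.4g} <= 0"
        )
    return MembraneEnrichment(
        center_um=c,
        background=background,
        mem_mean=mem_mean,
        cyto_mean=cyto_mean,
        ratio=mem_mean / cyto_mean,
    )


def analyze_profiles(profiles: list[LineProfile]) -> pd.DataFrame:
    """Run :func:`membrane_cyto_ratio` over many profiles.

    Profiles that fail (window does not fit, non-positive cytoplasm) are
    retained in the output with a ``status`` note and NaN values; the
    exclusion count is logged.
    """
    rows = []
    excluded = 0
    for i, p in enumerate(profiles):
        pid = p.profile_id or str(i)
        try:
            e = membrane_cyto_ratio(p)
            rows.append(
                dict(
                    profile_id=pid,
                    center_um=e.center_um,
                    background=e.background,
                    mem_mean=e.mem_mean,
                    cyto_mean=e.cyto_mean,
                    ratio=e.ratio,
                    status="ok",
                )
            )
        except (WindowFitError, NonPositiveCytoplasmError) as err:
            excluded += 1
            rows.append(
                dict(
                    profile_id=pid,
                    center_um=np.nan,
                    background=np.nan,
                    mem_mean=np.nan,
                    cyto_mean=np.nan,
                    ratio=np.nan,
                    status=type(err).__name__,
                )
            )
    if excluded:
        logger.info("analyze_profiles: excluded %d/%d profiles", excluded, len(profiles))
    return pd.DataFrame(rows)


def _gauss(x, amplitude, center, sigma, offset):
    return amplitude * np.exp(-((x - center) ** 2) / (2.0 * sigma**2)) + offset


def fit_junction_gaussian(
    positions: np.ndarray,
    intensities: np.ndarray,
    line_length: float | None = None,
) -> JunctionFit:
    """Least-squares Gaussian fit of a junctional intensity profile.

    Initialization: amplitude = max - min, center = argmax position,
    sigma = line_length / 4, offset = min.  Fails (raises) if the solver
    does not converge within 500 function evaluations or the fitted sigma
    exceeds the line length.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if positions.size < 8:
        raise ConfigError("junction fit needs at least 8 samples")
    if line_length is None:
        line_length = float(positions[-1] - positions[0])
    p0 = [
        float(intensities.max() - intensities.min()),
        float(positions[np.argmax(intensities)]),
        line_length / 4.0,
        float(intensities.min()),
    ]
    try:
        popt, _ = scipy.optimize.curve_fit(
            _gauss, positions, intensities, p0=p0, maxfev=500
        )
    except RuntimeError as err:
        raise GaussianFitError(f"junction fit did not converge: {err}") from err
    amplitude, center, sigma, offset = popt
    sigma = abs(float(sigma))
    if sigma > line_length:
        raise GaussianFitError(
            f"fitted sigma {sigma:.2f} um exceeds line length {line_length:.2f} um"
        )
    resid = intensities - _gauss(positions, *popt)
    return JunctionFit(
        amplitude=float(amplitude),
        center_um=float(center),
        sigma_um=sigma,
        offset=float(offset),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def normalize_junction_peak(peak_value: float, reference_mean: float) -> float:
    """Junction peak normalized against a reference-region mean intensity.

    The reference is the average staining intensity of a stereotypical
    ~50 x 50 um tissue area in the same embryo, removing embryo-to-embryo
    staining variation.
    """
    if reference_mean <= 0:
        raise ConfigError("reference_mean must be positive")
    return peak_value / reference_mean
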