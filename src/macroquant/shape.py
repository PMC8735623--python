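"""Cell-shape metrics: aspect ratio, density summaries, group change.

Maximal length is measured along the front-rear polarization axis and
maximal width along the orthogonal longest dimension; both arrive here
pre-measured (or simulated).  Protrusions are excluded from the length
by the measurer, so inputs are treated as protrusion-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import ConfigError

__all__ = ["aspect_ratio", "density_estimate", "group_shape_change"]


def aspect_ratio(max_length_um, max_width_um):
    """Length-to-width ratio; scale-invariant. Accepts scalars or arrays."""
    length = np.asarray(max_length_um, dtype=float)
    width = np.asarray(max_width_um, dtype=float)
    if np.any(width <= 0):
        raise ConfigError("max_width_um must be positive")
    out = length / width
    return float(out) if out.ndim == 0 else out


def density_estimate(
    values,
    bin_rule: str = "freedman-diaconis",
    bin_width: float | None = None,
) -> pd.DataFrame:
    """Histogram probability density of a sample.

    The density is normalized so that sum(density * bin_width) = 1.  The
    default bin width follows the Freedman-Diaconis rule; an explicit
    ``bin_width`` overrides it (useful for plot parity across groups).

    Returns a DataFrame with columns ``bin_center`` and ``density``.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 5:
        raise ConfigError("density estimate needs at least 5 values")
    if bin_width is not None:
        if bin_width <= 0:
            raise ConfigError("bin_width must be positive")
        lo, hi = values.min(), values.max()
        n_bins = max(1, int(np.ceil((hi - lo) / bin_width)))
        edges = lo + bin_width * np.arange(n_bins + 1)
        if edges[-1] <= hi:  # make the top edge inclusive
            edges[-1] = np.nextafter(hi, np.inf)
    elif bin_rule in ("freedman-diaconis", "fd"):
        edges = np.histogram_bin_edges(values, bins="fd")
    else:
        raise ConfigError(f"unknown bin rule {bin_rule!r}")
    density, edges = np.histogram(values, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame({"bin_center": centers, "density": density})


def group_shape_change(
    control: pd.DataFrame, test: pd.DataFrame
) -> tuple[float, float]:
    """Percent change of mean maximal length and width, test vs control.

    Returns ``(delta_length_pct, delta_width_pct)`` where each component
    is ``100 * (mean_test - mean_control) / mean_control``; positive means
    the test group is larger.
    """
    for name, df in (("control", control), ("test", test)):
        if df.empty:
            raise ConfigError(f"{name} group is empty")
        for col in ("max_length_um", "max_width_um"):
            if col not in df.columns:
                raise ConfigError(f"{name} group lacks column {col!r}")
    d_len = 100.0 * (
        test["max_length_um"].mean() - control["max_length_um"].mean()
    ) / control["max_length_um"].mean()
    d_wid = 100.0 * (
        test["max_width_um"].mean() - control["max_width_um"].mean()
    ) / control["max_width_um"].mean()
    return float(d_len), float(d_wid)
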