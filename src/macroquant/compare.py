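"""Group comparison: intensity normalization, outliers, effect arithmetic.

Per-embryo reporter intensities are summarized from ROI means, divided
by the per-batch control mean (removing imaging-session gain), screened
for outliers with an FDR-based rule, and compared between groups as
percent change.  The *effect fraction* expresses a perturbation's
reduction of a readout as a percentage of the reduction produced by a
reference perturbation:

    effect_fraction = 100 * (control - x) / (control - reference)

so that x = control gives 0% and x = reference gives 100%.

The outlier rule approximates ROUT (the FDR-based screen of GraphPad
Prism, whose internals are unpublished): residuals from the median are
standardized by the corrected MAD, converted to two-sided t tail
probabilities, and thresholded with a Benjamini-Hochberg step at the
stated maximum FDR Q.  It is an approximation, not a reimplementation.
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats

from .errors import ConfigError
from .tracks import ZoneDefinition

__all__ = [
    "embryo_mean_intensity",
    "batch_normalize",
    "rout_outliers",
    "percent_change",
    "effect_fraction",
    "printed_percent",
    "count_in_regions",
    "group_location_test",
    "LocationTestResult",
]


def embryo_mean_intensity(table: pd.DataFrame) -> pd.DataFrame:
    """Unweighted mean of ROI mean intensities per embryo.

    Expects columns ``embryo_id, group, batch, mean_intensity`` (one row
    per ROI / z-slice); returns one row per embryo with the same columns.
    """
    required = {"embryo_id", "group", "batch", "mean_intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ConfigError(f"intensity table lacks columns {sorted(missing)}")
    if table.empty:
        raise ConfigError("intensity table is empty")
    if table["mean_intensity"].lt(0).any():
        raise ConfigError("intensities must be non-negative")
    out = (
        table.groupby(["embryo_id", "group", "batch"], as_index=False, sort=True)[
            "mean_intensity"
        ]
        .mean()
    )
    return out


def batch_normalize(
    embryo_means: pd.DataFrame, control_group: str = "control"
) -> pd.DataFrame:
    """Divide each embryo mean by its batch's control-group mean.

    After normalization the control grand mean within every batch is
    exactly 1, and any per-batch multiplicative gain cancels.

    Raises
    ------
    ConfigError
        If some batch contains no control embryo.
    """
    df = embryo_means.copy()
    for batch, sub in df.groupby("batch"):
        ctrl = sub.loc[sub["group"] == control_group, "mean_intensity"]
        if ctrl.empty:
            raise ConfigError(f"batch {batch!r} has no {control_group!r} embryo")
        if ctrl.mean() <= 0:
            raise ConfigError(f"batch {batch!r} control mean is not positive")
        df.loc[sub.index, "mean_intensity"] = sub["mean_intensity"] / ctrl.mean()
    return df


def rout_outliers(values, q: float = 10.0) -> np.ndarray:
    """FDR-based outlier flags (ROUT-style approximation), deterministic.

    Robust center = median; robust scale = MAD * 1.4826 with the
    ``n / (n - 0.8)`` small-sample correction.  Standardized residuals
    get two-sided tail probabilities under a t distribution with n - 1
    degrees of freedom, and points are flagged by a Benjamini-Hochberg
    step at maximum FDR ``q`` percent.  When the robust scale is zero,
    points equal to the median are non-outliers (p = 1) and any deviating
    point is an unambiguous outlier (p = 0).

    Returns a boolean array aligned with ``values``.  ``q = 0`` flags
    nothing; the flagged set is monotone non-decreasing in ``q``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ConfigError("outlier screen needs at least 4 values")
    if not 0 <= q <= 100:
        raise ConfigError("q must be a percentage in [0, 100]")
    if q == 0:
        return np.zeros(n, dtype=bool)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    scale = 1.4826 * mad * n / (n - 0.8)
    if scale == 0:
        p = np.where(x == med, 1.0, 0.0)
    else:
        z = (x - med) / scale
        p = 2.0 * scipy.stats.t.sf(np.abs(z), df=n - 1)
    # Benjamini-Hochberg step-up on the sorted p-values.
    order = np.argsort(p, kind="stable")
    thresh = (q / 100.0) * (np.arange(1, n + 1) / n)
    passed = p[order] <= thresh
    flags = np.zeros(n, dtype=bool)
    if passed.any():
        k = int(np.max(np.nonzero(passed)[0]))
        flags[order[: k + 1]] = True
    return flags


def printed_percent(value: float) -> int:
    """Round to the nearest integer percent, halves away from zero."""
    return int(math.floor(value + 0.5)) if value >= 0 else int(math.ceil(value - 0.5))


def percent_change(reference: float, x: float, *, rounded: bool = False):
    """Percent reduction of ``x`` relative to ``reference``.

    ``100 * (reference - x) / reference``: positive for a reduction,
    negative for an increase.  With ``rounded=True`` the value is rounded
    to the nearest integer percent (halves away from zero), matching how
    such percentages are printed; the unrounded value is the default.
    """
    if reference == 0:
        raise ConfigError("reference must be non-zero")
    value = 100.0 * (reference - x) / reference
    return printed_percent(value) if rounded else value


def effect_fraction(
    control: float,
    reference_perturbation: float,
    x: float,
    *,
    rounded: bool = False,
):
    """Fraction of the reference perturbation's effect achieved by ``x``.

    ``100 * (control - x) / (control - reference_perturbation)``; 0% when
    x equals the control, 100% when it matches the reference perturbation.
    """
    span = control - reference_perturbation
    if span == 0:
        raise ConfigError("control equals reference_perturbation (zero span)")
    value = 100.0 * (control - x) / span
    return printed_percent(value) if rounded else value


def count_in_regions(
    centroids, regions: list[ZoneDefinition]
) -> pd.DataFrame:
    """Count centroids per half-open rectangular region.

    ``centroids`` is an iterable of ``(x_um, y_um)`` or
    ``(x_um, y_um, label)`` tuples.  Centroids falling in no region are
    tallied under the region name ``"unassigned"``.  Regions must not
    overlap.
    """
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            if a.overlaps(b):
                raise ConfigError(f"regions {a.name!r} and {b.name!r} overlap")
    counts: dict[tuple[str, str], int] = {}
    for row in centroids:
        x, y = float(row[0]), float(row[1])
        label = str(row[2]) if len(row) > 2 else ""
        hit = next((z.name for z in regions if z.contains(x, y)), "unassigned")
        counts[(label, hit)] = counts.get((label, hit), 0) + 1
    names = [z.name for z in regions] + ["unassigned"]
    labels = sorted({k[0] for k in counts}) or [""]
    rows = [
        dict(label=lab, region=name, count=counts.get((lab, name), 0))
        for lab in labels
        for name in names
    ]
    return pd.DataFrame(rows)


class LocationTestResult(NamedTuple):
    statistic: float
    pvalue: float
    method: str


_METHODS = ("t", "welch", "ks", "mannwhitney", "kruskal")


def group_location_test(a, b, method: str = "welch") -> LocationTestResult:
    """Two-sample location test, delegated to standard routines.

    ``method`` is one of ``t`` (Student), ``welch``, ``ks``
    (Kolmogorov-Smirnov), ``mannwhitney`` or ``kruskal``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ConfigError("each group needs at least 2 values")
    if method == "t":
        res = scipy.stats.ttest_ind(a, b, equal_var=True)
    elif method == "welch":
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
    elif method == "ks":
        res = scipy.stats.ks_2samp(a, b)
    elif method == "mannwhitney":
        res = scipy.stats.mannwhitneyu(a, b)
    elif method == "kruskal":
        res = scipy.stats.kruskal(a, b)
    else:
        raise ConfigError(f"unknown method {method!r}; choose from {_METHODS}")
    return LocationTestResult(float(res.statistic), float(res.pvalue), method)
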