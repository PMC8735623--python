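"""Synthetic data generators for every pipeline stage.

These generators emulate the statistical structure the analysis assumes,
so each estimator can be exercised against known ground truth:

* **Tracks** — constant-speed persistent random walks.  Each step has
  length ``speed * dt`` exactly; the turning angle between consecutive
  steps is von Mises distributed with mean 0 and concentration ``kappa``.
  In 2D the mean cosine of a von Mises angle has the closed form
  ``E[cos(dtheta)] = I1(kappa) / I0(kappa)`` (modified Bessel functions),
  so :func:`kappa_for_mean_cos` can calibrate a walk to any target
  persistence index in (0, 1).  Constant step speed makes speed recovery
  exact and keeps the persistence calibration independent of speed.

* **Line profiles** — a membrane-marker channel with a Gaussian peak on
  a constant floor, and a reporter channel built as outside background +
  inside cytoplasmic plateau + membrane Gaussian + optional Gaussian
  noise.  The inside/outside transition is a logistic of width
  ``sigma_mem`` centered at the membrane (a hard step would introduce
  discretization artifacts at the sampling grid).
  :func:`calibrate_profile_amplitude` solves for the membrane amplitude
  that makes the analysis pipeline return a chosen ratio.

* **Shapes and intensities** — independent normal draws around preset
  group means, emulating per-cell length/width measurements and
  per-embryo batch-normalized reporter intensities.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats

from .errors import CalibrationError, ConfigError
from .linescan import MIN_MARGIN, LineProfile, membrane_cyto_ratio
from .tracks import Trajectory

__all__ = [
    "TrackSimConfig",
    "ProfileSimConfig",
    "simulate_tracks",
    "kappa_for_mean_cos",
    "von_mises_mean_cos",
    "simulate_profiles",
    "calibrate_profile_amplitude",
    "simulate_shapes",
    "simulate_intensities",
]

#: Concentrations at or above this are treated as the kappa -> infinity
#: limit: zero turning, perfectly straight tracks.
KAPPA_STRAIGHT = 1e6


@dataclass(frozen=True)
class TrackSimConfig:
    """Parameters of the persistent-random-walk track simulator.

    Attributes
    ----------
    n_tracks, n_steps
        Number of tracks and of instantaneous velocities per track (each
        track has ``n_steps + 1`` positions).
    dt
        Frame interval in seconds.
    speed
        Constant step speed in um/min.
    kappa
        Von Mises turning-angle concentration (>= 0; 0 = uniform turning,
        >= :data:`KAPPA_STRAIGHT` = straight lines).
    dim
        2 or 3.  The calibration between kappa and persistence holds in
        2D; ``dim=3`` embeds the same planar walk at z = 0.
    """

    n_tracks: int
    n_steps: int
    dt: float = 40.0
    speed: float = 3.0
    kappa: float = 0.0
    dim: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tracks < 1 or self.n_steps < 1:
            raise ConfigError("n_tracks and n_steps must be >= 1")
        if not (np.isfinite(self.dt) and self.dt > 0):
            raise ConfigError("dt must be positive and finite")
        if not (np.isfinite(self.speed) and self.speed >= 0):
            raise ConfigError("speed must be non-negative and finite")
        if not (np.isfinite(self.kappa) and self.kappa >= 0):
            raise ConfigError("kappa must be non-negative and finite")
        if self.dim not in (2, 3):
            raise ConfigError("dim must be 2 or 3")


def simulate_tracks(config: TrackSimConfig) -> list[Trajectory]:
    """Simulate constant-speed persistent random walks.

    Every displacement has magnitude ``speed * dt`` exactly (um, with dt
    converted to minutes); the initial direction is uniform and each
    subsequent direction turns by a von Mises(0, kappa) angle.
    Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    step_um = config.speed * config.dt / 60.0
    times = np.arange(config.n_steps + 1) * config.dt
    out = []
    for i in range(config.n_tracks):
        theta0 = rng.uniform(-np.pi, np.pi)
        if config.n_steps > 1:
            if config.kappa >= KAPPA_STRAIGHT:
                turns = np.zeros(config.n_steps - 1)
            elif config.kappa == 0.0:
                # uniform turning; avoids vonmises pathologies at kappa=0
                turns = rng.uniform(-np.pi, np.pi, config.n_steps - 1)
            else:
                turns = rng.vonmises(0.0, config.kappa, config.n_steps - 1)
        else:
            turns = np.zeros(0)
        headings = theta0 + np.concatenate([[0.0], np.cumsum(turns)])
        steps = step_um * np.column_stack([np.cos(headings), np.sin(headings)])
        positions = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        if config.dim == 3:
            positions = np.column_stack([positions, np.zeros(len(positions))])
        out.append(
            Trajectory(track_id=f"sim-{i:04d}", times=times.copy(), positions=positions)
        )
    return out


def von_mises_mean_cos(kappa: float) -> float:
    """Closed-form E[cos(theta)] for theta ~ von Mises(0, kappa): I1/I0."""
    if kappa < 0:
        raise ConfigError("kappa must be non-negative")
    if kappa == 0:
        return 0.0
    # exponentially scaled Bessel ratio is overflow-safe for large kappa
    return float(scipy.special.i1e(kappa) / scipy.special.i0e(kappa))


def kappa_for_mean_cos(target: float) -> float:
    """Invert the 2D Bessel ratio: kappa with I1(kappa)/I0(kappa) = target.

    The ratio is strictly increasing from 0 (kappa=0) to 1 (kappa->inf),
    so monotone bracketing plus Brent's method converges for any target
    in (0, 1); the result satisfies ``|I1/I0 - target| < 1e-6``.
    """
    if not (0.0 < target < 1.0):
        raise ConfigError("target mean cosine must lie strictly in (0, 1)")
    hi = 1.0
    while von_mises_mean_cos(hi) < target:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - unreachable for target < 1
            raise CalibrationError("failed to bracket kappa")
    kappa = float(
        scipy.optimize.brentq(
            lambda k: von_mises_mean_cos(k) - target, 0.0, hi, xtol=1e-10
        )
    )
    if abs(von_mises_mean_cos(kappa) - target) >= 1e-6:
        raise CalibrationError("Bessel-ratio inversion did not reach 1e-6")
    return kappa


@dataclass(frozen=True)
class ProfileSimConfig:
    """Generative model of a two-channel membrane linescan.

    Positions run inside -> outside from 0 to ``length`` at spacing
    ``dx``.  The membrane sits at ``center``; both channels share the
    Gaussian width ``sigma_mem``.  The reporter's inside plateau is a
    logistic step of width ``sigma_mem`` centered at the membrane rather
    than a hard step, so that sub-sample shifts of the membrane do not
    produce jumps in the window means.
    """

    length: float = 8.0  # um; ~8 um lines in the assay
    dx: float = 0.1  # um per sample; 0.1 um XY resolution
    center: float = 4.0  # um
    sigma_mem: float = 0.25  # um
    bg_out: float = 20.0  # outside background B
    cyto_level: float = 100.0  # inside plateau C
    mem_amp: float = 50.0  # reporter membrane Gaussian amplitude A
    noise_sd: float = 0.0
    seed: int = 0
    mem_channel_amp: float = 100.0  # membrane-marker peak height
    mem_channel_floor: float = 10.0  # membrane-marker constant floor

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.sigma_mem <= 0 or self.cyto_level <= 0:
            raise ConfigError("dx, sigma_mem and cyto_level must be positive")
        if not (0 < self.center < self.length):
            raise ConfigError("center must lie strictly inside the line")
        if self.center < MIN_MARGIN or self.length - self.center < MIN_MARGIN:
            raise ConfigError(
                f"center must sit >= {MIN_MARGIN} um from both ends so the "
                "membrane window and its flanks fit"
            )
        if self.noise_sd < 0 or self.mem_amp < 0:
            raise ConfigError("noise_sd and mem_amp must be non-negative")

    @property
    def positions(self) -> np.ndarray:
        n = int(round(self.length / self.dx))
        return np.arange(n + 1) * self.dx


def _clean_channels(config: ProfileSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless membrane and reporter channels of the generative model."""
    x = config.positions
    gauss = np.exp(-((x - config.center) ** 2) / (2.0 * config.sigma_mem**2))
    membrane = config.mem_channel_floor + config.mem_channel_amp * gauss
    inside = scipy.special.expit((config.center - x) / config.sigma_mem)
    reporter = config.bg_out + config.cyto_level * inside + config.mem_amp * gauss
    return membrane, reporter


def simulate_profiles(config: ProfileSimConfig, n: int) -> list[LineProfile]:
    """Generate ``n`` profiles from the model, with fresh noise per profile.

    With ``noise_sd = 0`` all profiles are identical.  Reproducible for a
    fixed seed.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(config.seed)
    membrane, reporter_clean = _clean_channels(config)
    x = config.positions
    out = []
    for i in range(n):
        reporter = reporter_clean
        if config.noise_sd > 0:
            reporter = reporter + rng.normal(0.0, config.noise_sd, x.size)
        out.append(
            LineProfile(
                positions=x.copy(),
                ch_membrane=membrane.copy(),
                ch_reporter=np.asarray(reporter, dtype=float).copy(),
                dx=config.dx,
                inside_to_outside=True,
                profile_id=f"sim-{i:04d}",
            )
        )
    return out


def calibrate_profile_amplitude(
    target_ratio: float, config: ProfileSimConfig
) -> float:
    """Membrane amplitude for which the analysis returns ``target_ratio``.

    Runs :func:`membrane_cyto_ratio` on the noiseless generated profile
    as a function of the amplitude ``A`` and solves for the target by
    bracketing + Brent (the ratio is smooth and strictly increasing in
    ``A``).  The returned amplitude reproduces the target within 1e-4.

    Raises
    ------
    CalibrationError
        If the target is below the minimum achievable ratio (at A = 0).
    """
    if target_ratio <= 0:
        raise CalibrationError("target_ratio must be positive")

    def ratio_at(amp: float) -> float:
        cfg = replace(config, mem_amp=amp, noise_sd=0.0)
        return membrane_cyto_ratio(simulate_profiles(cfg, 1)[0]).ratio

    r0 = ratio_at(0.0)
    if target_ratio < r0 - 1e-12:
        raise CalibrationError(
            f"target ratio {target_ratio} below minimum achievable {r0:.4f} "
            "(amplitude cannot be negative)"
        )
    if abs(target_ratio - r0) < 1e-12:
        return 0.0
    hi = max(config.cyto_level, 1.0)
    while ratio_at(hi) < target_ratio:
        hi *= 2.0
        if hi > 1e12:
            raise CalibrationError("failed to bracket amplitude")
    amp = float(
        scipy.optimize.brentq(
            lambda a: ratio_at(a) - target_ratio, 0.0, hi, xtol=1e-10
        )
    )
    if abs(ratio_at(amp) - target_ratio) >= 1e-4:
        raise CalibrationError("amplitude calibration did not reach 1e-4")
    return amp


def simulate_shapes(
    mean_len: float,
    sd_len: float,
    mean_wid: float,
    sd_wid: float,
    n: int,
    seed: int = 0,
    group: str = "control",
) -> pd.DataFrame:
    """Per-cell maximal length/width samples, independent truncated normals.

    Draws are truncated at > 0.1 um (a cell dimension cannot vanish).
    Columns: ``cell_id, group, frame, max_length_um, max_width_um``.
    """
    if mean_len <= 0 or mean_wid <= 0:
        raise ConfigError("means must be positive")
    if sd_len < 0 or sd_wid < 0:
        raise ConfigError("sds must be non-negative")
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    lo = 0.1

    def draw(mean: float, sd: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        a = (lo - mean) / sd
        return scipy.stats.truncnorm.rvs(
            a, np.inf, loc=mean, scale=sd, size=n, random_state=rng
        )

    return pd.DataFrame(
        {
            "cell_id": [f"{group}-{i:04d}" for i in range(n)],
            "group": group,
            "frame": 0,
            "max_length_um": draw(mean_len, sd_len),
            "max_width_um": draw(mean_wid, sd_wid),
        }
    )


def simulate_intensities(
    group_means: list[float],
    group_sds: list[float],
    n_per_group: int,
    n_batches: int = 1,
    seed: int = 0,
    group_labels: list[str] | None = None,
) -> pd.DataFrame:
    """Per-embryo mean reporter intensities, normal per group, clipped at 0.

    Embryos are assigned round-robin to batches.  The first group is the
    control unless ``group_labels`` says otherwise.  Columns:
    ``embryo_id, group, batch, mean_intensity``.
    """
    if len(group_means) != len(group_sds) or not group_means:
        raise ConfigError("group_means and group_sds must be equal-length, non-empty")
    if n_per_group < 1 or n_batches < 1:
        raise ConfigError("n_per_group and n_batches must be >= 1")
    if group_labels is None:
        group_labels = ["control"] + [f"test{i}" for i in range(1, len(group_means))]
    if len(group_labels) != len(group_means):
        raise ConfigError("group_labels length mismatch")
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd in zip(group_labels, group_means, group_sds):
        if mean < 0 or sd < 0:
            raise ConfigError("means and sds must be non-negative")
        values = np.clip(rng.normal(mean, sd, n_per_group), 0.0, None)
        for j, v in enumerate(values):
            rows.append(
                dict(
                    embryo_id=f"{label}-{j:03d}",
                    group=label,
                    batch=j % n_batches,
                    mean_intensity=float(v),
                )
            )
    return pd.DataFrame(rows)
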