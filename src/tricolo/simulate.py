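"""Synthetic three-channel SMLM ground truth.

Everything downstream of the microscope is exercised against scenes produced
here: planted MCM–EdU–G4 triplets over Poisson background, two-state blinking
emission trains, sCMOS camera frames, and bead calibration fields with a known
chromatic map.  All coordinates are nanometres; areas at the user interface are
µm².  Every function is deterministic given its seed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GroundTruthScene",
    "EmissionTrain",
    "CameraModel",
    "simulate_triplet_scene",
    "simulate_blinking",
    "render_frames",
    "simulate_bead_field",
    "simulate_localization_table",
]

CHANNELS = (1, 2, 3)


@dataclass(frozen=True)
class GroundTruthScene:
    """Parameters of a planted-triplet nuclear field.

    The channel-1 points (MCM in the default role mapping) are homogeneous
    Poisson anchors; each anchor carries a channel-2 member at polar offset
    (r1_nm, θ) and a channel-3 member at (r2_nm, θ + dtheta_rad) with a single
    shared orientation θ ~ Uniform[−π, π] per triplet.  Background points are
    independent Poisson per channel.  The triplet geometry defaults are
    operator choices (documented in docs/methods.md), not measured values.
    """

    roi_size_um: float = 6.0
    triplet_density_per_um2: float = 5.0
    r1_nm: float = 100.0
    r2_nm: float = 150.0
    dtheta_rad: float = math.pi / 3
    background_per_um2: tuple[float, float, float] = (50.0, 50.0, 50.0)
    jitter_sd_nm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.roi_size_um) or self.roi_size_um <= 0:
            raise ValueError("roi_size_um must be finite and > 0")
        for name in ("triplet_density_per_um2", "r1_nm", "r2_nm", "jitter_sd_nm"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if len(self.background_per_um2) != 3:
            raise ValueError("background_per_um2 needs one density per channel")
        for v in self.background_per_um2:
            if not np.isfinite(v) or v < 0:
                raise ValueError("background densities must be finite and >= 0")
        if not np.isfinite(self.dtheta_rad):
            raise ValueError("dtheta_rad must be finite")

    @property
    def roi_size_nm(self) -> float:
        return self.roi_size_um * 1000.0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["background_per_um2"] = list(self.background_per_um2)
        return d


@dataclass
class EmissionTrain:
    """Blinking emission of one ground-truth emitter."""

    emitter_id: int
    channel: int
    x_nm: float
    y_nm: float
    on_frames: np.ndarray  # sorted frame indices
    photons_per_frame: float
    background_rate: float = 0.0
    n_bursts: int = 1

    def __post_init__(self) -> None:
        self.on_frames = np.asarray(self.on_frames, dtype=np.int64)
        if self.photons_per_frame <= 0:
            raise ValueError("photons_per_frame must be > 0")


@dataclass
class CameraModel:
    """sCMOS camera: per-pixel offset/gain/read-noise-variance calibration."""

    pixel_size_nm: float
    offset_map: np.ndarray
    gain_map: np.ndarray
    readnoise_var_map: np.ndarray
    n_frames: int = 2000

    def __post_init__(self) -> None:
        self.offset_map = np.asarray(self.offset_map, dtype=float)
        self.gain_map = np.asarray(self.gain_map, dtype=float)
        self.readnoise_var_map = np.asarray(self.readnoise_var_map, dtype=float)
        shapes = {self.offset_map.shape, self.gain_map.shape, self.readnoise_var_map.shape}
        if len(shapes) != 1:
            raise ValueError("camera calibration maps must share one shape")
        if np.any(self.gain_map <= 0):
            raise ValueError("gain must be > 0 everywhere")
        if np.any(self.readnoise_var_map < 0):
            raise ValueError("read-noise variance must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.offset_map.shape

    @classmethod
    def uniform(cls, shape=(64, 64), pixel_size_nm=110.0, offset=100.0, gain=2.0,
                readnoise_var=4.0, n_frames=2000) -> "CameraModel":
        """Spatially uniform calibration, convenient for simulations."""
        h, w = shape
        return cls(
            pixel_size_nm=pixel_size_nm,
            offset_map=np.full((h, w), float(offset)),
            gain_map=np.full((h, w), float(gain)),
            readnoise_var_map=np.full((h, w), float(readnoise_var)),
            n_frames=n_frames,
        )


def simulate_triplet_scene(scene: GroundTruthScene) -> pd.DataFrame:
    """Draw one planted-triplet scene.

    Returns a table with columns ``channel, x_nm, y_nm, triplet_id, in_roi``.
    Background points carry ``triplet_id = -1``.  Triplet members that fall
    outside the ROI square are kept but flagged ``in_roi = False``; the
    correlation stage decides inclusion.
    """
    rng = np.random.default_rng(scene.seed)
    L = scene.roi_size_nm
    area_um2 = scene.roi_size_um**2

    rows = []
    n_trip = rng.poisson(scene.triplet_density_per_um2 * area_um2)
    ax = rng.uniform(0.0, L, n_trip)
    ay = rng.uniform(0.0, L, n_trip)
    theta = rng.uniform(-math.pi, math.pi, n_trip)
    jit = scene.jitter_sd_nm
    m2x = ax + scene.r1_nm * np.cos(theta) + rng.normal(0.0, jit, n_trip) * (jit > 0)
    m2y = ay + scene.r1_nm * np.sin(theta) + rng.normal(0.0, jit, n_trip) * (jit > 0)
    th3 = theta + scene.dtheta_rad
    m3x = ax + scene.r2_nm * np.cos(th3) + rng.normal(0.0, jit, n_trip) * (jit > 0)
    m3y = ay + scene.r2_nm * np.sin(th3) + rng.normal(0.0, jit, n_trip) * (jit > 0)

    tid = np.arange(n_trip, dtype=np.int64)
    for ch, (xs, ys) in zip(CHANNELS, ((ax, ay), (m2x, m2y), (m3x, m3y))):
        rows.append(pd.DataFrame({
            "channel": ch, "x_nm": xs, "y_nm": ys, "triplet_id": tid,
        }))

    for ch, dens in zip(CHANNELS, scene.background_per_um2):
        n_bg = rng.poisson(dens * area_um2)
        rows.append(pd.DataFrame({
            "channel": ch,
            "x_nm": rng.uniform(0.0, L, n_bg),
            "y_nm": rng.uniform(0.0, L, n_bg),
            "triplet_id": np.full(n_bg, -1, dtype=np.int64),
        }))

    out = pd.concat(rows, ignore_index=True)
    out["in_roi"] = (
        (out.x_nm >= 0) & (out.x_nm < L) & (out.y_nm >= 0) & (out.y_nm < L)
    )
    return out


def simulate_blinking(
    points: pd.DataFrame,
    n_frames: int,
    mean_on_frames: float = 3.0,
    reactivation_prob: float = 0.0,
    mean_off_frames: float = 10.0,
    photons_per_frame: float = 1000.0,
    seed: int = 0,
) -> list[EmissionTrain]:
    """Two-state blinking: geometric on-bursts separated by geometric dark gaps.

    Every ground-truth point yields at least one burst (each labelled molecule
    is assumed to activate at least once during the acquisition).  With
    ``reactivation_prob = 0`` each emitter produces exactly one burst.
    """
    if mean_on_frames < 1:
        raise ValueError("mean_on_frames must be >= 1")
    if not (0 <= reactivation_prob < 1):
        raise ValueError("reactivation_prob must lie in [0, 1)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    p_on = 1.0 / mean_on_frames
    p_off = 1.0 / max(mean_off_frames, 1.0)

    trains: list[EmissionTrain] = []
    for eid, row in enumerate(points.itertuples(index=False)):
        start = int(rng.integers(0, n_frames))
        frames: list[int] = []
        n_bursts = 0
        while True:
            length = int(rng.geometric(p_on))
            stop = min(start + length, n_frames)
            frames.extend(range(start, stop))
            n_bursts += 1
            if stop >= n_frames or rng.random() >= reactivation_prob:
                break
            gap = int(rng.geometric(p_off))
            start = stop + gap
            if start >= n_frames:
                break
        trains.append(EmissionTrain(
            emitter_id=eid, channel=int(row.channel),
            x_nm=float(row.x_nm), y_nm=float(row.y_nm),
            on_frames=np.array(frames, dtype=np.int64),
            photons_per_frame=photons_per_frame,
            n_bursts=n_bursts,
        ))
    return trains


def _integrated_gaussian_1d(n_pix: int, center_px: float, sigma_px: float) -> np.ndarray:
    """Fraction of a unit-flux Gaussian integrated over each unit pixel."""
    from scipy.special import erf

    edges = np.arange(n_pix + 1, dtype=float)
    z = (edges - center_px) / (sigma_px * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def expected_photon_map(
    trains: list[EmissionTrain], camera: CameraModel, psf_sigma_nm: float,
    background_photons: float = 0.0,
) -> np.ndarray:
    """Noise-free expected photons per pixel per frame, shape (n_frames, H, W)."""
    if psf_sigma_nm <= 0:
        raise ValueError("psf_sigma must be > 0")
    h, w = camera.shape
    a = camera.pixel_size_nm
    sig = psf_sigma_nm / a
    mu = np.full((camera.n_frames, h, w), float(background_photons))
    for tr in trains:
        cx, cy = tr.x_nm / a, tr.y_nm / a
        if not (0 <= cx < w and 0 <= cy < h):
            import warnings

            warnings.warn(f"emitter {tr.emitter_id} outside field; skipped")
            continue
        ex = _integrated_gaussian_1d(w, cx, sig)
        ey = _integrated_gaussian_1d(h, cy, sig)
        spot = tr.photons_per_frame * np.outer(ey, ex)
        valid = tr.on_frames[(tr.on_frames >= 0) & (tr.on_frames < camera.n_frames)]
        for f in valid:
            mu[f] += spot
    return mu


def render_frames(
    trains: list[EmissionTrain],
    camera: CameraModel,
    psf_sigma_nm: float,
    background_photons: float = 0.0,
    seed: int = 0,
    poisson_noise: bool = True,
    read_noise: bool = True,
) -> np.ndarray:
    """Render raw sCMOS frames: offset + gain·Poisson(µ) + N(0, read-noise var).

    Pixel (i, j) spans [j·a, (j+1)·a) × [i·a, (i+1)·a) nm with a the pixel
    size; rows are y.  The PSF is the 2-D Gaussian integrated over pixel area.
    """
    rng = np.random.default_rng(seed)
    mu = expected_photon_map(trains, camera, psf_sigma_nm, background_photons)
    counts = rng.poisson(mu).astype(float) if poisson_noise else mu
    raw = camera.offset_map[None] + camera.gain_map[None] * counts
    if read_noise and np.any(camera.readnoise_var_map > 0):
        raw = raw + rng.normal(0.0, np.sqrt(camera.readnoise_var_map), size=raw.shape)
    return raw


def simulate_bead_field(
    n_beads: int,
    true_map,
    field_size_nm: float = 6600.0,
    loc_noise_sd_nm: float = 2.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired bead localizations for channel-registration calibration.

    Reference-channel bead positions are uniform in the field; the source
    channel observes the chromatically distorted positions, i.e. the numeric
    inverse of ``true_map`` (the source→reference correction polynomial)
    applied to the reference positions.  Independent Gaussian localization
    noise of ``loc_noise_sd_nm`` per axis is added in each channel.
    """
    if n_beads < 6:
        raise ValueError(
            "n_beads must be >= 6: a 2nd-degree 2D polynomial has 6 "
            "coefficients per axis"
        )
    rng = np.random.default_rng(seed)
    ref = rng.uniform(0.0, field_size_nm, size=(n_beads, 2))
    src = true_map.inverse_transform(ref)
    sd = float(loc_noise_sd_nm)
    src_obs = src + rng.normal(0.0, sd, src.shape) * (sd > 0)
    ref_obs = ref + rng.normal(0.0, sd, ref.shape) * (sd > 0)
    mk = lambda p: pd.DataFrame({"x_nm": p[:, 0], "y_nm": p[:, 1]})
    return mk(src_obs), mk(ref_obs)


def simulate_localization_table(
    trains: list[EmissionTrain],
    precision_loc_nm: float = 10.0,
    precision_scale_nm: float = 3.0,
    precision_shape: float = 4.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulate the localization stage at coordinate level.

    Each on-frame of each train yields one localization whose precision σ is
    drawn from a skew-Gaussian (the empirical shape of CRLB distributions) and
    whose position is the true position plus N(0, σ) per axis.  Used for
    cohort-scale studies where rendering and fitting every frame would add
    nothing but runtime; the frame-level path is exercised separately.
    """
    from scipy import stats

    rng = np.random.default_rng(seed)
    keep = [tr for tr in trains if len(tr.on_frames)]
    if not keep:
        return pd.DataFrame(columns=[
            "frame", "channel", "x_nm", "y_nm", "photons", "background",
            "crlb_x_nm", "crlb_y_nm", "n_merged", "emitter_id",
        ])
    counts = np.array([len(tr.on_frames) for tr in keep])
    total = int(counts.sum())
    sig = stats.skewnorm.rvs(precision_shape, loc=precision_loc_nm,
                             scale=precision_scale_nm, size=total,
                             random_state=rng)
    sig = np.clip(sig, 1.0, None)
    out = pd.DataFrame({
        "frame": np.concatenate([tr.on_frames for tr in keep]),
        "channel": np.repeat([tr.channel for tr in keep], counts),
        "x_nm": np.repeat([tr.x_nm for tr in keep], counts) + rng.normal(0.0, sig),
        "y_nm": np.repeat([tr.y_nm for tr in keep], counts) + rng.normal(0.0, sig),
        "photons": np.repeat([tr.photons_per_frame for tr in keep], counts),
        "background": np.repeat([tr.background_rate for tr in keep], counts),
        "crlb_x_nm": sig,
        "crlb_y_nm": sig,
        "n_merged": 1,
        "emitter_id": np.repeat([tr.emitter_id for tr in keep], counts),
    })
    return out.sort_values(["frame", "channel"], kind="stable").reset_index(drop=True)
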