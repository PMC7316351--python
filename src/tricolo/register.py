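"""Chromatic channel registration.

Multi-color SMLM channels are acquired sequentially through different emission
filters, so each color is warped by wavelength-dependent aberration.  A
2nd-degree 2-D polynomial (morph-type) map fitted on a bead calibration field
brings every source channel into the reference channel frame.

Basis convention: monomials ordered ``{1, x, y, x², x·y, y²}``; one
6-coefficient vector per output axis; coefficients stored in original
nanometre units (fitting is done on centered/rescaled coordinates for
conditioning and expanded back exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = ["ChannelMap", "fit_polynomial_map", "apply_map", "pair_beads"]

BASIS = ("1", "x", "y", "x^2", "x*y", "y^2")


def _design(xy: np.ndarray) -> np.ndarray:
    x, y = xy[:, 0], xy[:, 1]
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


@dataclass
class ChannelMap:
    """Quadratic warp from a source channel into the reference channel."""

    source_channel: str
    reference_channel: str
    coeffs_x: np.ndarray  # 6 monomial coefficients for x'
    coeffs_y: np.ndarray
    rms_residual_nm: float = 0.0
    n_beads: int = 0

    def __post_init__(self) -> None:
        self.coeffs_x = np.asarray(self.coeffs_x, dtype=float)
        self.coeffs_y = np.asarray(self.coeffs_y, dtype=float)
        if self.coeffs_x.shape != (6,) or self.coeffs_y.shape != (6,):
            raise ValueError("exactly 6 coefficients per axis (degree-2 2D basis)")
        if self.rms_residual_nm < 0:
            raise ValueError("rms_residual must be >= 0")

    @classmethod
    def identity(cls, source_channel="src", reference_channel="ref") -> "ChannelMap":
        e = np.array([0.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        n = np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
        return cls(source_channel, reference_channel, e, n)

    def transform(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        A = _design(xy)
        return np.column_stack([A @ self.coeffs_x, A @ self.coeffs_y])

    def jacobian(self, xy: np.ndarray) -> np.ndarray:
        """Per-point 2×2 Jacobian of the map."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        x, y = xy[:, 0], xy[:, 1]
        one = np.ones_like(x)
        zero = np.zeros_like(x)
        dx = np.stack([zero, one, zero, 2 * x, y, zero], axis=1)
        dy = np.stack([zero, zero, one, zero, x, 2 * y], axis=1)
        J = np.empty((len(x), 2, 2))
        J[:, 0, 0] = dx @ self.coeffs_x
        J[:, 0, 1] = dy @ self.coeffs_x
        J[:, 1, 0] = dx @ self.coeffs_y
        J[:, 1, 1] = dy @ self.coeffs_y
        return J

    def inverse_transform(self, xy: np.ndarray, tol: float = 1e-10,
                          max_iter: int = 50) -> np.ndarray:
        """Numeric inverse by Newton iteration (map must be near-identity)."""
        target = np.atleast_2d(np.asarray(xy, dtype=float))
        cur = target.copy()
        for _ in range(max_iter):
            resid = self.transform(cur) - target
            if np.max(np.abs(resid)) < tol:
                break
            J = self.jacobian(cur)
            cur = cur - np.linalg.solve(J, resid[..., None])[..., 0]
        return cur

    def to_json(self) -> str:
        return json.dumps({
            "source_channel": self.source_channel,
            "reference_channel": self.reference_channel,
            "basis": list(BASIS),
            "units": "nm",
            "coeffs_x": self.coeffs_x.tolist(),
            "coeffs_y": self.coeffs_y.tolist(),
            "rms_residual_nm": self.rms_residual_nm,
            "n_beads": self.n_beads,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChannelMap":
        d = json.loads(text)
        if tuple(d.get("basis", BASIS)) != BASIS:
            raise ValueError(f"unknown basis ordering {d.get('basis')}")
        return cls(d["source_channel"], d["reference_channel"],
                   np.array(d["coeffs_x"]), np.array(d["coeffs_y"]),
                   d.get("rms_residual_nm", 0.0), d.get("n_beads", 0))


def pair_beads(src: np.ndarray, ref: np.ndarray, gate_nm: float = 500.0
               ) -> tuple[np.ndarray, np.ndarray, int]:
    """Mutual-nearest-neighbor bead pairing within a distance gate.

    Returns matched (src, ref) arrays and the number of dropped beads.
    """
    ts, tr = cKDTree(src), cKDTree(ref)
    d_sr, i_sr = tr.query(src, distance_upper_bound=gate_nm)
    d_rs, i_rs = ts.query(ref, distance_upper_bound=gate_nm)
    pairs = []
    for i, j in enumerate(i_sr):
        if j < len(ref) and i_rs[j] == i:
            pairs.append((i, j))
    dropped = len(src) + len(ref) - 2 * len(pairs)
    if not pairs:
        return src[:0], ref[:0], dropped
    si, ri = map(np.array, zip(*pairs))
    return src[si], ref[ri], dropped


def _rescale_params(xy: np.ndarray) -> tuple[np.ndarray, float]:
    center = xy.mean(axis=0)
    scale = float(np.abs(xy - center).max())
    return center, (scale if scale > 0 else 1.0)


def _expand_to_original_units(beta: np.ndarray, center: np.ndarray,
                              scale: float) -> np.ndarray:
    """Expand coefficients on the centered/scaled basis to raw-nm monomials.

    With u=(x−cx)/s, v=(y−cy)/s, substitute into β·{1,u,v,u²,uv,v²} and collect
    on {1,x,y,x²,xy,y²}.  Exact in real arithmetic.
    """
    cx, cy = center
    s = scale
    b0, b1, b2, b3, b4, b5 = beta
    out = np.zeros(6)
    out[0] = (b0 - b1 * cx / s - b2 * cy / s
              + b3 * cx * cx / s**2 + b4 * cx * cy / s**2 + b5 * cy * cy / s**2)
    out[1] = b1 / s - 2 * b3 * cx / s**2 - b4 * cy / s**2
    out[2] = b2 / s - 2 * b5 * cy / s**2 - b4 * cx / s**2
    out[3] = b3 / s**2
    out[4] = b4 / s**2
    out[5] = b5 / s**2
    return out


def fit_polynomial_map(
    src_points,
    ref_points,
    source_channel: str = "src",
    reference_channel: str = "ref",
    gate_nm: float = 500.0,
    paired: bool = False,
) -> ChannelMap:
    """Least-squares fit of the source→reference quadratic map.

    ``x'`` and ``y'`` are fitted independently on the degree-2 monomial basis.
    Beads are matched by mutual nearest neighbor within ``gate_nm`` unless
    ``paired=True`` (rows already correspond).  The reported residual is the
    leave-one-out RMS per axis in nm.
    """
    src = _as_xy(src_points)
    ref = _as_xy(ref_points)
    if paired:
        if len(src) != len(ref):
            raise ValueError("paired=True requires equal-length tables")
    else:
        src, ref, _ = pair_beads(src, ref, gate_nm)
    n = len(src)
    if n < 6:
        raise ValueError(
            f"need >= 6 matched bead pairs to constrain the 6-term quadratic "
            f"basis, got {n}"
        )
    center, scale = _rescale_params(src)
    A = _design((src - center) / scale)
    rank = np.linalg.matrix_rank(A)
    if rank < 6:
        raise ValueError(
            "rank-deficient bead geometry (collinear or degenerate bead "
            "layout cannot constrain a 2D quadratic)"
        )
    beta_x, *_ = np.linalg.lstsq(A, ref[:, 0], rcond=None)
    beta_y, *_ = np.linalg.lstsq(A, ref[:, 1], rcond=None)

    # leave-one-out residuals via the hat matrix
    G = np.linalg.inv(A.T @ A)
    h = np.einsum("ij,jk,ik->i", A, G, A)
    rx = (ref[:, 0] - A @ beta_x) / (1.0 - h)
    ry = (ref[:, 1] - A @ beta_y) / (1.0 - h)
    rms = float(np.sqrt(np.mean(np.concatenate([rx, ry]) ** 2)))

    return ChannelMap(
        source_channel, reference_channel,
        _expand_to_original_units(beta_x, center, scale),
        _expand_to_original_units(beta_y, center, scale),
        rms_residual_nm=rms, n_beads=n,
    )


def _as_xy(points) -> np.ndarray:
    if isinstance(points, pd.DataFrame):
        return points[["x_nm", "y_nm"]].to_numpy(dtype=float)
    return np.atleast_2d(np.asarray(points, dtype=float))


def apply_map(channel_map: ChannelMap, localizations: pd.DataFrame,
              channel_column: str = "channel") -> pd.DataFrame:
    """Map a localization table into the reference channel frame.

    Precision and photometry columns pass through unchanged; tables already in
    the reference channel are returned untouched.
    """
    out = localizations.copy()
    if len(out) == 0:
        return out
    channels = set(map(str, out[channel_column].unique()))
    if channels == {str(channel_map.reference_channel)}:
        return out
    if channels != {str(channel_map.source_channel)}:
        raise ValueError(
            f"channel mismatch: table has {sorted(channels)}, map is "
            f"{channel_map.source_channel!r} -> {channel_map.reference_channel!r}"
        )
    xy = channel_map.transform(out[["x_nm", "y_nm"]].to_numpy(dtype=float))
    out["x_nm"] = xy[:, 0]
    out["y_nm"] = xy[:, 1]
    return out
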