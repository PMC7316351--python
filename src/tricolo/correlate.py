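"""Triple-correlation analysis of three-channel localization patterns.

The triple-correlation function (TCF)

    f(r1, r2) = <δρ1(R) δρ2(R+r1) δρ3(R+r2)>_R / (<ρ1><ρ2><ρ3>)

measures the normalized third moment of density fluctuations across three
channels at two displacement vectors, with δρ_i = ρ_i − <ρ_i> and <ρ_i> the
mean detection density inside the region of interest (a ~6×6 µm² square at the
nucleus center).  It is zero for any configuration in which one channel is
independent of the others, and peaks at the internal geometry of a recurring
three-species pattern.

The estimator visits each channel-1 coordinate, histograms channel-2 offsets
into annular-sector bins over (r1, θ) and channel-3 offsets over (r2, θ+Δθ),
converts counts to local densities by the in-ROI sector area, and averages the
fluctuation product δρ2·δρ3 over visited coordinates and θ.  Because triplets
are randomly oriented, f is reported after θ-averaging, re-indexed from
(r1, r2, Δθ) to (r1, r2, r3) with r3 the third side of the displacement
triangle.

The conditional local density

    C3(r1, r2) = <δρ1 δρ2 δρ3> / <δρ1(R) δρ2(R+r1)>

estimates the local density (per nm²) of the third species at r2 − r1 given a
channel-1/channel-2 pair correlating at r1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "RoiSelection",
    "TCFGrid",
    "select_roi",
    "compute_tcf",
    "angular_average",
    "compute_conditional_density",
    "sector_area_fractions",
]

DEFAULT_SIDE_NM = 6000.0
DEFAULT_R_EDGES = np.arange(0.0, 525.0, 25.0)  # 25 nm bins to 500 nm
DEFAULT_NTHETA = 12


@dataclass
class RoiSelection:
    """Per-channel localization subsets clipped to a square ROI."""

    center: tuple[float, float]
    side: float
    channels: dict  # label -> (N, 2) float array, nm
    mean_densities: dict  # label -> count per nm^2

    @property
    def origin(self) -> tuple[float, float]:
        return (self.center[0] - self.side / 2.0, self.center[1] - self.side / 2.0)

    @property
    def area_nm2(self) -> float:
        return self.side**2

    @property
    def labels(self) -> list:
        return list(self.channels)


@dataclass
class TCFGrid:
    """Binned TCF estimate over (r1, r2, Δθ) plus derived quantities.

    Δθ bins are circular shifts of the θ binning: ``ntheta`` uniform θ bins of
    width w = 2π/ntheta give Δθ values centered on multiples of w (wrapped to
    (−π, π]), each covering ±w/2.
    """

    r1_edges: np.ndarray
    r2_edges: np.ndarray
    ntheta: int
    f_values: np.ndarray          # (A, B, T)
    pair_counts: np.ndarray       # (A, B, T) raw triple counts
    g12: np.ndarray               # (A,) pairwise fluctuation <δρ1δρ2>/<ρ1>, per nm^2
    g12_counts: np.ndarray        # (A,) raw pair counts
    mean_densities: tuple         # (<ρ1>, <ρ2>, <ρ3>) per nm^2
    boundary_mode: str
    g12_se: np.ndarray | None = None      # (A,) standard error of g12
    f_angular: np.ndarray | None = None   # (A, B, R3)
    r3_edges: np.ndarray | None = None
    r3_convention: str | None = None
    c3_values: np.ndarray | None = None   # (A, B, T), per nm^2
    c3_mask: np.ndarray | None = None     # True where denominator below floor
    n_visited: int = 0

    @property
    def dtheta_centers(self) -> np.ndarray:
        w = 2.0 * math.pi / self.ntheta
        c = np.arange(self.ntheta) * w
        return np.where(c > math.pi, c - 2.0 * math.pi, c)

    @property
    def dtheta_width(self) -> float:
        return 2.0 * math.pi / self.ntheta

    def bin_index(self, r1: float, r2: float, dtheta: float) -> tuple[int, int, int]:
        """Index of the (r1, r2, Δθ) bin containing a geometry."""
        a = int(np.searchsorted(self.r1_edges, r1, side="right")) - 1
        b = int(np.searchsorted(self.r2_edges, r2, side="right")) - 1
        w = self.dtheta_width
        d = int(round(((dtheta + 2 * math.pi) % (2 * math.pi)) / w)) % self.ntheta
        return a, b, d


def select_roi(localizations, center=None, side: float = DEFAULT_SIDE_NM,
               channels=(1, 2, 3), channel_column: str = "channel") -> RoiSelection:
    """Clip three channels to a square ROI and compute mean densities.

    ``localizations`` is a table with a channel column, or a dict mapping
    channel label to an (N, 2) coordinate array.  ``center`` defaults to the
    per-axis median of the union of all channels.
    """
    if side <= 0:
        raise ValueError("side must be > 0")
    if isinstance(localizations, pd.DataFrame):
        pts = {c: localizations.loc[localizations[channel_column] == c,
                                    ["x_nm", "y_nm"]].to_numpy(dtype=float)
               for c in channels}
    else:
        pts = {c: np.atleast_2d(np.asarray(localizations[c], dtype=float))
               for c in channels}
    if len(pts) != 3:
        raise ValueError("exactly three channels required")
    union = np.concatenate([p for p in pts.values() if len(p)]) if any(
        len(p) for p in pts.values()) else np.zeros((0, 2))
    if center is None:
        if len(union) == 0:
            raise ValueError("cannot infer ROI center from empty data")
        center = tuple(np.median(union, axis=0))
    x0, y0 = center[0] - side / 2.0, center[1] - side / 2.0
    out, dens = {}, {}
    for c, p in pts.items():
        if len(p):
            keep = ((p[:, 0] >= x0) & (p[:, 0] < x0 + side)
                    & (p[:, 1] >= y0) & (p[:, 1] < y0 + side))
            p = p[keep]
        if len(p) == 0:
            raise ValueError(f"channel {c!r} empty inside the ROI; TCF undefined")
        out[c] = p
        dens[c] = len(p) / side**2
    return RoiSelection(center=tuple(center), side=float(side),
                        channels=out, mean_densities=dens)


# ---------------------------------------------------------------------------
# geometry helpers


def sector_area_fractions(points: np.ndarray, origin, L: float,
                          r_edges: np.ndarray, ntheta: int,
                          n_phi: int = 720, n_rad: int = 3) -> np.ndarray:
    """In-ROI area fraction of each annular sector bin around each point.

    Quadrature of the exact square-intersection geometry: Gauss–Legendre nodes
    in radius (weighted by r, the area element) times a uniform angular grid
    (``n_phi`` must be a multiple of ``ntheta``).  Interior points whose whole
    disk of radius r_max lies inside the ROI get fraction 1 without work.
    """
    if n_phi % ntheta:
        raise ValueError("n_phi must be a multiple of ntheta")
    points = np.atleast_2d(points)
    n = len(points)
    A = len(r_edges) - 1
    frac = np.ones((n, A, ntheta))
    x0, y0 = origin
    px, py = points[:, 0] - x0, points[:, 1] - y0
    rmax = r_edges[-1]
    dist = np.minimum(np.minimum(px, L - px), np.minimum(py, L - py))
    edge = np.flatnonzero(dist < rmax)
    if len(edge) == 0:
        return frac

    # radial Gauss-Legendre nodes per bin
    gx, gw = np.polynomial.legendre.leggauss(n_rad)
    r_in, r_out = r_edges[:-1], r_edges[1:]
    mid, half = (r_in + r_out) / 2.0, (r_out - r_in) / 2.0
    rq = mid[:, None] + half[:, None] * gx[None, :]          # (A, Q)
    wq = half[:, None] * gw[None, :] * rq                     # r dr weights
    norm = wq.sum(axis=1)                                     # = (r_out²−r_in²)/2

    phi = -math.pi + (np.arange(n_phi) + 0.5) * (2.0 * math.pi / n_phi)
    cosf, sinf = np.cos(phi), np.sin(phi)
    rflat = rq.ravel()                                        # (A*Q,)

    chunk = max(1, int(2e6 // (len(rflat) * n_phi)) or 1)
    per = n_phi // ntheta
    for s in range(0, len(edge), chunk):
        idx = edge[s:s + chunk]
        cx = px[idx][:, None, None] + rflat[None, :, None] * cosf[None, None, :]
        cy = py[idx][:, None, None] + rflat[None, :, None] * sinf[None, None, :]
        inside = (cx >= 0) & (cx <= L) & (cy >= 0) & (cy <= L)
        fa = inside.reshape(len(idx), A, n_rad, ntheta, per).mean(axis=-1)
        frac[idx] = np.einsum("caqt,aq->cat", fa, wq) / norm[None, :, None]
    return frac


def _sector_counts(centers: np.ndarray, others: np.ndarray, r_edges: np.ndarray,
                   ntheta: int, L: float, origin, periodic: bool) -> np.ndarray:
    """Counts of ``others`` in each annular sector bin around each center."""
    A = len(r_edges) - 1
    n = len(centers)
    counts = np.zeros((n, A, ntheta))
    rmax = float(r_edges[-1])
    x0, y0 = origin
    c = centers - np.array([x0, y0])
    o = others - np.array([x0, y0])
    if periodic:
        o = np.mod(o, L)
        c = np.mod(c, L)
        tree = cKDTree(o, boxsize=L)
    else:
        tree = cKDTree(o)
    pairs = tree.query_ball_point(c, rmax)
    w = 2.0 * math.pi / ntheta
    for k, nb in enumerate(pairs):
        if not nb:
            continue
        d = o[nb] - c[k]
        if periodic:
            d -= L * np.round(d / L)
        r = np.hypot(d[:, 0], d[:, 1])
        keep = r < rmax
        if r_edges[0] > 0:
            keep &= r >= r_edges[0]
        if not np.any(keep):
            continue
        d, r = d[keep], r[keep]
        ir = np.searchsorted(r_edges, r, side="right") - 1
        phi = np.arctan2(d[:, 1], d[:, 0])
        it = np.minimum(((phi + math.pi) / w).astype(np.int64), ntheta - 1)
        np.add.at(counts[k], (ir, it), 1.0)
    return counts


# ---------------------------------------------------------------------------
# TCF estimator


def compute_tcf(roi: RoiSelection, r1_edges=None, r2_edges=None,
                ntheta: int = DEFAULT_NTHETA, boundary_mode: str = "analytic",
                min_sector_fraction: float = 0.05,
                n_phi: int = 720, n_rad: int = 3) -> TCFGrid:
    """Estimate f(r1, r2) on an (r1, r2, Δθ) grid by coordinate visiting.

    ``boundary_mode='analytic'`` normalizes every sector bin by its in-ROI
    area fraction (no point discarded); ``'periodic'`` wraps coordinates on
    the ROI torus and is intended for synthetic testing and the brute-force
    oracle.  Sector bins whose in-ROI fraction falls below
    ``min_sector_fraction`` are excluded from the average rather than
    amplified.
    """
    r1_edges = np.asarray(DEFAULT_R_EDGES if r1_edges is None else r1_edges, float)
    r2_edges = np.asarray(DEFAULT_R_EDGES if r2_edges is None else r2_edges, float)
    for e in (r1_edges, r2_edges):
        if len(e) < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if e[-1] > roi.side:
            raise ValueError("bins wider than the ROI")
    if boundary_mode not in ("analytic", "periodic"):
        raise ValueError("boundary_mode must be 'analytic' or 'periodic'")
    labels = roi.labels
    rho = tuple(roi.mean_densities[c] for c in labels)
    if any(r == 0 for r in rho):
        raise ValueError("mean density of every channel must be > 0")
    p1, p2, p3 = (roi.channels[c] for c in labels)
    L, origin = roi.side, roi.origin
    periodic = boundary_mode == "periodic"
    T = ntheta
    w = 2.0 * math.pi / T

    n2 = _sector_counts(p1, p2, r1_edges, T, L, origin, periodic)
    n3 = _sector_counts(p1, p3, r2_edges, T, L, origin, periodic)

    area2 = (0.5 * (r1_edges[1:] ** 2 - r1_edges[:-1] ** 2) * w)[None, :, None]
    area3 = (0.5 * (r2_edges[1:] ** 2 - r2_edges[:-1] ** 2) * w)[None, :, None]
    if periodic:
        frac2 = np.ones_like(n2)
        frac3 = np.ones_like(n3)
    else:
        frac2 = sector_area_fractions(p1, origin, L, r1_edges, T, n_phi, n_rad)
        frac3 = (frac2 if r1_edges.shape == r2_edges.shape
                 and np.array_equal(r1_edges, r2_edges)
                 else sector_area_fractions(p1, origin, L, r2_edges, T, n_phi, n_rad))

    m2 = (frac2 >= min_sector_fraction).astype(float)
    m3 = (frac3 >= min_sector_fraction).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = np.where(m2 > 0, n2 / (area2 * frac2) - rho[1], 0.0)
        d3 = np.where(m3 > 0, n3 / (area3 * frac3) - rho[2], 0.0)
    d2m, d3m = d2 * m2, d3 * m3

    A, B = len(r1_edges) - 1, len(r2_edges) - 1
    num = np.empty((A, B, T))
    wsum = np.empty((A, B, T))
    pair_counts = np.empty((A, B, T))
    for d in range(T):
        d3r = np.roll(d3m, -d, axis=2)
        m3r = np.roll(m3, -d, axis=2)
        n3r = np.roll(n3 * m3, -d, axis=2)
        num[:, :, d] = np.einsum("kat,kbt->ab", d2m, d3r)
        wsum[:, :, d] = np.einsum("kat,kbt->ab", m2, m3r)
        pair_counts[:, :, d] = np.einsum("kat,kbt->ab", n2 * m2, n3r)

    with np.errstate(divide="ignore", invalid="ignore"):
        f = num / wsum / (rho[1] * rho[2])
    f[wsum == 0] = np.nan

    g12_w = m2.sum(axis=(0, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        g12 = d2m.sum(axis=(0, 2)) / g12_w
        g12_var = (d2m**2).sum(axis=(0, 2)) / g12_w - g12**2
        g12_se = np.sqrt(np.maximum(g12_var, 0.0) / g12_w)
    g12[g12_w == 0] = np.nan
    g12_se[g12_w == 0] = np.nan
    g12_counts = (n2 * m2).sum(axis=(0, 2))

    return TCFGrid(
        r1_edges=r1_edges, r2_edges=r2_edges, ntheta=T,
        f_values=f, pair_counts=pair_counts, g12=g12, g12_counts=g12_counts,
        g12_se=g12_se, mean_densities=rho, boundary_mode=boundary_mode,
        n_visited=len(p1),
    )


def angular_average(grid: TCFGrid, r3_edges=None, convention: str = "minus") -> TCFGrid:
    """Re-index f from (r1, r2, Δθ) to (r1, r2, r3), weighting by triple counts.

    ``convention='minus'`` (default) uses the geometric third side
    r3² = r1² + r2² − 2·r1·r2·cosΔθ of the triangle spanned by the two
    displacement vectors; ``'plus'`` uses the + sign as sometimes printed.
    Target bins receiving no counts are left NaN (undefined, not zero).
    """
    if grid.f_values is None:
        raise ValueError("f_values must be computed first")
    if convention not in ("minus", "plus"):
        raise ValueError("convention must be 'minus' or 'plus'")
    sign = -1.0 if convention == "minus" else 1.0
    r1c = 0.5 * (grid.r1_edges[:-1] + grid.r1_edges[1:])
    r2c = 0.5 * (grid.r2_edges[:-1] + grid.r2_edges[1:])
    dth = grid.dtheta_centers
    r3 = np.sqrt(np.maximum(
        r1c[:, None, None] ** 2 + r2c[None, :, None] ** 2
        + sign * 2.0 * r1c[:, None, None] * r2c[None, :, None] * np.cos(dth)[None, None, :],
        0.0))
    if r3_edges is None:
        width = float(np.diff(grid.r1_edges).min())
        r3_edges = np.arange(0.0, r3.max() + width, width)
    r3_edges = np.asarray(r3_edges, float)
    R3 = len(r3_edges) - 1
    ir3 = np.clip(np.searchsorted(r3_edges, r3, side="right") - 1, 0, R3 - 1)
    ir3[(r3 < r3_edges[0]) | (r3 >= r3_edges[-1])] = -1

    A, B, T = grid.f_values.shape
    fnum = np.zeros((A, B, R3))
    fden = np.zeros((A, B, R3))
    wgt = np.where(np.isfinite(grid.f_values), grid.pair_counts, 0.0)
    fv = np.nan_to_num(grid.f_values)
    for d in range(T):
        tgt = ir3[:, :, d]
        ok = tgt >= 0
        np.add.at(fnum, (np.nonzero(ok)[0], np.nonzero(ok)[1], tgt[ok]),
                  (wgt[:, :, d] * fv[:, :, d])[ok])
        np.add.at(fden, (np.nonzero(ok)[0], np.nonzero(ok)[1], tgt[ok]),
                  wgt[:, :, d][ok])
    with np.errstate(divide="ignore", invalid="ignore"):
        fang = fnum / fden
    fang[fden == 0] = np.nan
    grid.f_angular = fang
    grid.r3_edges = r3_edges
    grid.r3_convention = convention
    return grid


def compute_conditional_density(grid: TCFGrid, roi: RoiSelection,
                                floor_frac: float = 1e-3,
                                z_floor: float = 3.0) -> TCFGrid:
    """Fill C3(r1, r2, Δθ) = <δρ1δρ2δρ3> / <δρ1δρ2> in count per nm².

    A conditional density is only defined given a pair that actually
    correlates at r1, so r1 bins are masked (and reported, never silently
    zeroed) when the pairwise denominator is below the absolute floor
    ``floor_frac × <ρ1><ρ2>`` (in <ρ1>-reduced units: |g12| < floor_frac·<ρ2>)
    or not significantly positive (g12 < ``z_floor`` × its standard error;
    set z_floor=0 to keep only the absolute floor).  The denominator can be
    negative where channels 1 and 2 anticorrelate; such bins are masked too.
    """
    if grid.f_values is None or grid.g12 is None:
        raise ValueError("f_values and the pairwise correlation are required")
    rho1, rho2, rho3 = grid.mean_densities
    den = grid.g12  # <δρ1δρ2>/<ρ1> per nm²
    mask1d = ~np.isfinite(den) | (np.abs(den) < floor_frac * rho2)
    if z_floor > 0 and grid.g12_se is not None:
        mask1d |= ~(den > z_floor * grid.g12_se)
    with np.errstate(divide="ignore", invalid="ignore"):
        c3 = grid.f_values * rho2 * rho3 / den[:, None, None]
    c3[mask1d, :, :] = np.nan
    grid.c3_values = c3
    grid.c3_mask = np.broadcast_to(mask1d[:, None, None], c3.shape).copy()
    return grid
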