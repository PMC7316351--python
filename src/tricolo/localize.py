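"""Frame stacks to localization tables.

The chain is: variance-weighted box filtering of each gain/offset-corrected
frame, rough local-maxima candidate detection, 7×7 2D-Gaussian MLE fitting
under the sCMOS likelihood, Cramér–Rao precision per fit, skew-Gaussian
modelling of the pooled precisions, blink merging of consecutive-frame
localizations, and Gaussian-kernel rendering for display.

sCMOS likelihood: the exact per-pixel model is a Poisson shot-noise count
convolved with Gaussian read noise of pre-calibrated per-pixel variance.  It
is realized here through the standard variance-shifted Poisson approximation:
the read-noise variance (in photon units, var/gain²) is added to both the
data and the model rate, after which the pixel is treated as Poisson.  All
fitting happens in pixel/photon units; tables are in nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize, stats
from scipy.spatial import cKDTree
from scipy.special import erf

__all__ = [
    "PrecisionModel",
    "variance_weighted_box_filter",
    "detect_candidates",
    "fit_mle",
    "compute_crlb",
    "fit_precision_distribution",
    "merge_blinks",
    "render_image",
    "localize_stack",
]

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))
LOC_COLUMNS = ["frame", "channel", "x_nm", "y_nm", "photons", "background",
               "crlb_x_nm", "crlb_y_nm", "n_merged"]


@dataclass(frozen=True)
class PrecisionModel:
    """Skew-Gaussian model of the localization-precision distribution."""

    shape: float
    location: float
    scale: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def pdf(self, x):
        return stats.skewnorm.pdf(x, self.shape, loc=self.location, scale=self.scale)

    def rvs(self, size, rng):
        return stats.skewnorm.rvs(self.shape, loc=self.location, scale=self.scale,
                                  size=size, random_state=rng)


# ---------------------------------------------------------------------------
# filtering and detection


def variance_weighted_box_filter(frame: np.ndarray, var: np.ndarray,
                                 psf_fwhm_nm: float, pixel_size_nm: float) -> np.ndarray:
    """Raw minus inverse-variance-weighted box mean.

    ``frame`` must already be offset/gain-corrected to photon units and
    ``var`` is the read-noise variance in photon² units.  The box side is
    round(4·FWHM / pixel size), forced odd.
    """
    box = int(round(4.0 * psf_fwhm_nm / pixel_size_nm))
    if box % 2 == 0:
        box += 1
    if box > min(frame.shape):
        raise ValueError(f"box size {box} exceeds frame shape {frame.shape}")
    w = 1.0 / np.maximum(var, 1e-12)
    num = ndimage.uniform_filter(frame * w, size=box, mode="reflect")
    den = ndimage.uniform_filter(w, size=box, mode="reflect")
    return frame - num / den


def detect_candidates(filtered: np.ndarray, threshold_sd: float = 4.0,
                      min_separation_px: float = 2.0) -> np.ndarray:
    """Strict 8-neighborhood local maxima above a robust-SD threshold.

    Threshold is in units of 1.4826·MAD of the filtered image.  Maxima closer
    than ``min_separation_px`` are deduplicated keeping the brighter.  Returns
    an (n, 2) integer array of (row, col) positions.
    """
    med = np.median(filtered)
    sd = 1.4826 * np.median(np.abs(filtered - med))
    thr = med + threshold_sd * sd
    mx = ndimage.maximum_filter(filtered, size=3, mode="constant", cval=-np.inf)
    peaks = np.argwhere((filtered >= mx) & (filtered > thr))
    if len(peaks) == 0:
        return peaks.reshape(0, 2)
    vals = filtered[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(-vals, kind="stable")
    peaks = peaks[order]
    tree = cKDTree(peaks.astype(float))
    close = tree.query_pairs(min_separation_px, output_type="ndarray")
    drop = np.zeros(len(peaks), bool)
    for i, j in close:  # i < j, earlier index is brighter
        if not drop[i]:
            drop[max(i, j)] = True
    return peaks[~drop]


# ---------------------------------------------------------------------------
# MLE fitting


def _profile(size: int, center: float, sigma: float):
    """Integrated 1D Gaussian per unit pixel and its derivative wrt center."""
    edges = np.arange(size + 1, dtype=float)
    s2 = sigma * math.sqrt(2.0)
    cdf = 0.5 * (1.0 + erf((edges - center) / s2))
    pdf = np.exp(-((edges - center) ** 2) / (2.0 * sigma * sigma)) / (
        sigma * math.sqrt(2.0 * math.pi))
    E = np.diff(cdf)
    dE = pdf[:-1] - pdf[1:]  # d/dcenter of the pixel integral
    return E, dE


def _model_and_grads(params: np.ndarray, size: int, sigma: float, k: int):
    """Expected photons µ (size×size) and dµ/dθ for k emitters + background."""
    b = params[3 * k]
    mu = np.full((size, size), b)
    grads = []
    for e in range(k):
        x, y, N = params[3 * e], params[3 * e + 1], params[3 * e + 2]
        Ex, dEx = _profile(size, x, sigma)
        Ey, dEy = _profile(size, y, sigma)
        mu += N * np.outer(Ey, Ex)
        grads.append(N * np.outer(Ey, dEx))   # d/dx
        grads.append(N * np.outer(dEy, Ex))   # d/dy
        grads.append(np.outer(Ey, Ex))        # d/dN
    grads.append(np.ones((size, size)))       # d/db
    return mu, grads


def _nll_and_grad(params, q_shift, v, size, sigma, k, mask):
    mu, grads = _model_and_grads(params, size, sigma, k)
    mu_shift = np.maximum(mu + v, 1e-12)
    nll = float(np.sum(mask * (mu_shift - q_shift * np.log(mu_shift))))
    resid = mask * (1.0 - q_shift / mu_shift)
    g = np.array([float(np.sum(resid * dg)) for dg in grads])
    return nll, g


@dataclass
class FitResult:
    """One fitted patch: k emitters, photons, background, precision."""

    k: int
    params: np.ndarray            # [x, y, N]*k + [b], pixel/photon units
    log_likelihood: float
    converged: bool
    crlb: np.ndarray | None = None  # (k, 3): x, y, N in pixel/photon units
    singular: bool = False

    @property
    def background(self) -> float:
        return float(self.params[3 * self.k])

    def emitter(self, e: int = 0):
        return self.params[3 * e], self.params[3 * e + 1], self.params[3 * e + 2]


def _fit_k(q, v, sigma, k, init, mask, max_iter=100, tol=1e-8):
    size = q.shape[0]
    q_shift = q + v
    bounds = []
    for _ in range(k):
        bounds += [(-1.0, size + 1.0), (-1.0, size + 1.0), (1e-3, None)]
    bounds += [(0.0, None)]
    res = optimize.minimize(
        _nll_and_grad, np.asarray(init, float), jac=True,
        args=(q_shift, v, size, sigma, k, mask),
        method="L-BFGS-B", bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol * 1e-2, "gtol": 1e-10},
    )
    ll = -res.fun
    return FitResult(k=k, params=res.x, log_likelihood=ll,
                     converged=bool(res.success or res.status == 0))


def fit_mle(patch: np.ndarray, patch_var: np.ndarray, psf_sigma_px: float,
            max_emitters: int = 1, llr_threshold: float = 24.0,
            mask: np.ndarray | None = None) -> FitResult:
    """MLE fit of 1..max_emitters integrated-Gaussian PSFs to a photon patch.

    ``patch`` in photons, ``patch_var`` the per-pixel read-noise variance in
    photon² units.  Flagged (invalid) pixels are excluded through ``mask``.
    Model order is selected by the log-likelihood-ratio rule
    2·ΔlogL > ``llr_threshold``.
    """
    if max_emitters not in (1, 2):
        raise ValueError("max_emitters must be 1 or 2")
    q = np.asarray(patch, float)
    v = np.asarray(patch_var, float)
    size = q.shape[0]
    if q.shape != v.shape or q.shape[0] != q.shape[1]:
        raise ValueError("patch and variance must be square and congruent")
    mask = np.ones_like(q) if mask is None else np.asarray(mask, float)

    border = np.median(np.concatenate([q[0], q[-1], q[:, 0], q[:, -1]]))
    b0 = max(border, 0.0)
    n0 = max(float((mask * (q - b0)).sum()), 10.0)
    yy, xx = np.mgrid[0:size, 0:size] + 0.5
    wpos = np.maximum(q - b0, 0.0) * mask
    if wpos.sum() > 0:
        x0 = float((wpos * xx).sum() / wpos.sum())
        y0 = float((wpos * yy).sum() / wpos.sum())
    else:
        x0 = y0 = size / 2.0
    fit1 = _fit_k(q, v, psf_sigma_px, 1, [x0, y0, n0, b0], mask)
    best = fit1
    if max_emitters == 2:
        mu1, _ = _model_and_grads(fit1.params, size, psf_sigma_px, 1)
        resid = (q - mu1) * mask
        iy, ix = np.unravel_index(np.argmax(resid), resid.shape)
        x1, y1, n1 = fit1.emitter(0)
        init2 = [x1, y1, max(n1 * 0.7, 1.0), ix + 0.5, iy + 0.5,
                 max(float(resid[iy, ix]) * 2 * math.pi * psf_sigma_px**2, 10.0),
                 fit1.background]
        fit2 = _fit_k(q, v, psf_sigma_px, 2, init2, mask)
        inside = all(-0.5 <= fit2.params[3 * e + i] <= size + 0.5
                     for e in range(2) for i in (0, 1))
        if (fit2.converged and inside
                and 2.0 * (fit2.log_likelihood - fit1.log_likelihood) > llr_threshold):
            best = fit2
    best.crlb, best.singular = compute_crlb(best, v, psf_sigma_px, mask=mask)
    return best


def compute_crlb(fit: FitResult, patch_var: np.ndarray, psf_sigma_px: float,
                 mask: np.ndarray | None = None):
    """Cramér–Rao bounds from the Fisher information of the fitted model.

    Uses the same variance-shifted Poisson likelihood as the fit:
    I_ij = Σ_pixels ∂µ_i ∂µ_j / (µ + v).  Returns ((k, 3) array of
    (σx, σy, σN) in pixel/photon units, singular_flag).
    """
    v = np.asarray(patch_var, float)
    size = v.shape[0]
    mask = np.ones_like(v) if mask is None else np.asarray(mask, float)
    mu, grads = _model_and_grads(fit.params, size, psf_sigma_px, fit.k)
    mu_shift = np.maximum(mu + v, 1e-12)
    G = np.stack([g.ravel() for g in grads])
    W = (mask / mu_shift).ravel()
    info = (G * W) @ G.T
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return None, True
    d = np.diag(cov)
    if np.any(d <= 0) or not np.all(np.isfinite(d)):
        return None, True
    sd = np.sqrt(d)
    return sd[:-1].reshape(fit.k, 3), False


# ---------------------------------------------------------------------------
# precision distribution, merging, rendering


def fit_precision_distribution(precisions) -> PrecisionModel:
    """Maximum-likelihood skew-Gaussian fit of pooled precision values."""
    x = np.asarray(precisions, float)
    x = x[np.isfinite(x)]
    if len(x) < 50:
        raise ValueError(f"need >= 50 localizations, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate precision distribution (all values equal)")
    # moment-based start keeps the MLE off the |shape|→∞ ridge
    skew = float(stats.skew(x))
    a0 = float(np.clip(np.sign(skew) * 2.0 * abs(skew) ** (1 / 3) * 3, -20, 20))
    a, loc, scale = stats.skewnorm.fit(x, a0 if a0 else 1.0,
                                       loc=float(np.median(x)),
                                       scale=float(np.std(x)))
    return PrecisionModel(shape=float(a), location=float(loc), scale=float(scale))


def merge_blinks(localizations: pd.DataFrame, factor: float = 2.5,
                 max_gap_frames: int = 1) -> pd.DataFrame:
    """Collapse blinking events into single localizations.

    Localizations in consecutive frames (gap ≤ ``max_gap_frames``) are linked
    to a running blink chain when their Euclidean distance to the chain's
    inverse-variance centroid is within ``factor`` times the combined
    precision sqrt(cx² + cy²), cx² = crlb_x² + chain_crlb_x² (per axis).
    Each chain collapses to the inverse-variance-weighted mean; merged
    crlb = (Σ 1/crlb²)^(−1/2); photons are summed; ``n_merged`` counts chain
    members.  Channels are merged independently.

    Rows arriving with ``n_merged > 1`` are collapsed blink events already and
    pass through untouched; together with greedy nearest-first link
    assignment this makes the operation exactly idempotent.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if len(localizations) == 0:
        return localizations.copy()
    out = []
    has_channel = "channel" in localizations.columns
    groups = localizations.groupby("channel", sort=False) if has_channel \
        else [(None, localizations)]
    for ch, tab in groups:
        out.append(_merge_one_channel(tab, factor, max_gap_frames))
    merged = pd.concat(out, ignore_index=True)
    return merged.sort_values(["frame", "x_nm", "y_nm"],
                              kind="stable").reset_index(drop=True)


def _merge_one_channel(tab: pd.DataFrame, factor: float, max_gap: int) -> pd.DataFrame:
    tab = tab.sort_values("frame", kind="stable")
    frames = tab["frame"].to_numpy()
    x = tab["x_nm"].to_numpy(float)
    y = tab["y_nm"].to_numpy(float)
    sx = tab["crlb_x_nm"].to_numpy(float)
    sy = tab["crlb_y_nm"].to_numpy(float)
    photons = tab["photons"].to_numpy(float)
    bg = tab["background"].to_numpy(float)
    nm_in = tab["n_merged"].to_numpy() if "n_merged" in tab.columns \
        else np.ones(len(tab), dtype=int)

    inert = nm_in > 1  # collapsed blink events: pass through untouched
    chains: list[dict] = []
    active: list[int] = []
    for f in np.unique(frames):
        active = [c for c in active if chains[c]["last"] >= f - max_gap]
        idx = np.flatnonzero((frames == f) & ~inert)
        cand = []
        if active and len(idx):
            cxs = np.array([chains[c]["swx_x"] / chains[c]["swx"] for c in active])
            cys = np.array([chains[c]["swy_y"] / chains[c]["swy"] for c in active])
            cvx = np.array([1.0 / chains[c]["swx"] for c in active])
            cvy = np.array([1.0 / chains[c]["swy"] for c in active])
            for i in idx:
                d2 = (x[i] - cxs) ** 2 + (y[i] - cys) ** 2
                tau2 = factor**2 * (sx[i] ** 2 + cvx + sy[i] ** 2 + cvy)
                for jj in np.flatnonzero(d2 <= tau2):
                    cand.append((d2[jj], i, active[jj]))
        cand.sort()
        used_i, used_c = set(), set()
        for _, i, c in cand:
            if i in used_i or c in used_c:
                continue
            used_i.add(i)
            used_c.add(c)
            _chain_add(chains[c], f, i, x[i], y[i], sx[i], sy[i], photons[i],
                       bg[i], nm_in[i])
        for i in idx:
            if i not in used_i:
                ch = {"swx": 0.0, "swx_x": 0.0, "swy": 0.0, "swy_y": 0.0,
                      "first": f, "last": f, "n": 0, "photons": 0.0,
                      "bg": 0.0, "rows": 0, "row0": i}
                _chain_add(ch, f, i, x[i], y[i], sx[i], sy[i], photons[i],
                           bg[i], nm_in[i])
                chains.append(ch)
                active.append(len(chains) - 1)

    # single-member chains keep their original row values bit-exactly
    def _x(c):
        return x[c["row0"]] if c["rows"] == 1 else c["swx_x"] / c["swx"]

    def _y(c):
        return y[c["row0"]] if c["rows"] == 1 else c["swy_y"] / c["swy"]

    def _sx(c):
        return sx[c["row0"]] if c["rows"] == 1 else 1.0 / math.sqrt(c["swx"])

    def _sy(c):
        return sy[c["row0"]] if c["rows"] == 1 else 1.0 / math.sqrt(c["swy"])

    rec = {
        "frame": [c["first"] for c in chains],
        "x_nm": [_x(c) for c in chains],
        "y_nm": [_y(c) for c in chains],
        "photons": [c["photons"] for c in chains],
        "background": [c["bg"] / c["rows"] for c in chains],
        "crlb_x_nm": [_sx(c) for c in chains],
        "crlb_y_nm": [_sy(c) for c in chains],
        "n_merged": [c["n"] for c in chains],
    }
    df = pd.DataFrame(rec)
    if inert.any():
        passthrough = pd.DataFrame({
            "frame": frames[inert], "x_nm": x[inert], "y_nm": y[inert],
            "photons": photons[inert], "background": bg[inert],
            "crlb_x_nm": sx[inert], "crlb_y_nm": sy[inert],
            "n_merged": nm_in[inert],
        })
        df = pd.concat([df, passthrough], ignore_index=True)
    if "channel" in tab.columns:
        df.insert(1, "channel", tab["channel"].iloc[0])
    return df


def _chain_add(ch, f, row, x, y, sx, sy, photons, bg, n):
    wx, wy = 1.0 / sx**2, 1.0 / sy**2
    ch.setdefault("row0", row)
    ch["swx"] += wx
    ch["swx_x"] += wx * x
    ch["swy"] += wy
    ch["swy_y"] += wy * y
    ch["last"] = f
    ch["n"] += int(n)
    ch["rows"] += 1
    ch["photons"] += photons
    ch["bg"] += bg


def render_image(localizations: pd.DataFrame, canvas_pixel_nm: float = 10.0,
                 kernel_sigma_nm: float = 10.0, extent=None) -> tuple[np.ndarray, tuple]:
    """Render coordinates on a canvas convolved with a Gaussian kernel.

    The kernel is normalized, so total intensity equals the number of
    localizations (up to mass clipped at the canvas border; the default
    extent pads by 5 kernel sigmas to avoid it).  Returns (image, origin_nm).
    """
    if len(localizations) == 0:
        return np.zeros((1, 1)), (0.0, 0.0)
    x = localizations["x_nm"].to_numpy(float)
    y = localizations["y_nm"].to_numpy(float)
    pad = 5.0 * kernel_sigma_nm
    if extent is None:
        x0, x1 = x.min() - pad, x.max() + pad
        y0, y1 = y.min() - pad, y.max() + pad
    else:
        (x0, x1), (y0, y1) = extent
    nx = max(int(np.ceil((x1 - x0) / canvas_pixel_nm)), 1)
    ny = max(int(np.ceil((y1 - y0) / canvas_pixel_nm)), 1)
    hist, _, _ = np.histogram2d(y, x, bins=(ny, nx),
                                range=((y0, y0 + ny * canvas_pixel_nm),
                                       (x0, x0 + nx * canvas_pixel_nm)))
    img = ndimage.gaussian_filter(hist, kernel_sigma_nm / canvas_pixel_nm,
                                  mode="constant")
    return img, (x0, y0)


# ---------------------------------------------------------------------------
# stack orchestration


def localize_stack(frames: np.ndarray, camera, psf_sigma_nm: float,
                   threshold_sd: float = 4.0, max_emitters: int = 1,
                   fit_box: int = 7, channel=1,
                   llr_threshold: float = 24.0,
                   min_photons: float = 100.0) -> pd.DataFrame:
    """Run filter → detect → fit on every frame of a raw stack.

    Returns the native localization table (nm, photons).  Non-converged or
    singular fits are excluded; patches crossing the field edge are fitted
    with the missing pixels flagged out of the likelihood.  Fits below
    ``min_photons`` are rejected as noise peaks: at typical backgrounds the
    7×7 signal-to-background of a 100-photon spot is already near the
    detection limit, so dimmer "fits" are overwhelmingly spurious candidates.
    """
    a = camera.pixel_size_nm
    sigma_px = psf_sigma_nm / a
    fwhm_nm = FWHM_PER_SIGMA * psf_sigma_nm
    var_ph = camera.readnoise_var_map / camera.gain_map**2
    half = fit_box // 2
    h, w = camera.shape
    rows = []
    for fi, raw in enumerate(frames):
        q = (raw - camera.offset_map) / camera.gain_map
        filt = variance_weighted_box_filter(q, var_ph, fwhm_nm, a)
        for cy, cx in detect_candidates(filt, threshold_sd):
            y0, x0 = cy - half, cx - half
            ys, xs = slice(max(y0, 0), min(y0 + fit_box, h)), \
                slice(max(x0, 0), min(x0 + fit_box, w))
            patch = np.zeros((fit_box, fit_box))
            pvar = np.full((fit_box, fit_box), 1.0)
            mask = np.zeros((fit_box, fit_box))
            oy, ox = ys.start - y0, xs.start - x0
            patch[oy:oy + ys.stop - ys.start, ox:ox + xs.stop - xs.start] = q[ys, xs]
            pvar[oy:oy + ys.stop - ys.start, ox:ox + xs.stop - xs.start] = var_ph[ys, xs]
            mask[oy:oy + ys.stop - ys.start, ox:ox + xs.stop - xs.start] = 1.0
            fit = fit_mle(patch, pvar, sigma_px, max_emitters, llr_threshold, mask)
            if not fit.converged or fit.singular or fit.crlb is None:
                continue
            for e in range(fit.k):
                ex, ey, en = fit.emitter(e)
                gx, gy = x0 + ex, y0 + ey
                if not (0 <= gx < w and 0 <= gy < h) or en < min_photons:
                    continue
                if abs(ex - fit_box / 2) > half + 0.5 or abs(ey - fit_box / 2) > half + 0.5:
                    continue
                rows.append({
                    "frame": fi, "channel": channel,
                    "x_nm": gx * a, "y_nm": gy * a,
                    "photons": en, "background": fit.background,
                    "crlb_x_nm": fit.crlb[e, 0] * a,
                    "crlb_y_nm": fit.crlb[e, 1] * a,
                    "log_likelihood": fit.log_likelihood,
                    "n_merged": 1,
                })
    if not rows:
        return pd.DataFrame(columns=LOC_COLUMNS + ["log_likelihood"])
    return pd.DataFrame(rows)
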