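"""Independent brute-force reference implementations used only by tests.

Pure-Python nested loops, no shared code with the package's vectorized
estimators.
"""

from __future__ import annotations

import math

import numpy as np


def tcf_loops(p1, p2, p3, r1_edges, r2_edges, ntheta, L):
    """Direct nested-loop TCF estimator on the periodic square [0, L)².

    Visits each channel-1 point, bins channel-2/3 wrapped offsets into
    annular sectors, forms local-density fluctuations against the ROI mean
    density, and averages the product over visited points and θ bins.
    Returns (f, pair_counts, g12) with shapes (A, B, T), (A, B, T), (A,).
    """
    A, B, T = len(r1_edges) - 1, len(r2_edges) - 1, ntheta
    w = 2.0 * math.pi / T
    rho2 = len(p2) / L**2
    rho3 = len(p3) / L**2
    area2 = [0.5 * (r1_edges[a + 1] ** 2 - r1_edges[a] ** 2) * w for a in range(A)]
    area3 = [0.5 * (r2_edges[b + 1] ** 2 - r2_edges[b] ** 2) * w for b in range(B)]

    num = [[[0.0] * T for _ in range(B)] for _ in range(A)]
    pc = [[[0.0] * T for _ in range(B)] for _ in range(A)]
    g12_sum = [0.0] * A
    n_terms = 0

    def bin_counts(center, others, edges, nbins):
        counts = [[0] * T for _ in range(nbins)]
        rmax = edges[-1]
        for q in others:
            dx = q[0] - center[0]
            dx -= L * round(dx / L)
            dy = q[1] - center[1]
            dy -= L * round(dy / L)
            r = math.hypot(dx, dy)
            if r >= rmax or r < edges[0]:
                continue
            a = None
            for i in range(nbins):
                if edges[i] <= r < edges[i + 1]:
                    a = i
                    break
            if a is None:
                continue
            t = min(int((math.atan2(dy, dx) + math.pi) / w), T - 1)
            counts[a][t] += 1
        return counts

    for k in p1:
        n2 = bin_counts(k, p2, r1_edges, A)
        n3 = bin_counts(k, p3, r2_edges, B)
        d2 = [[n2[a][t] / area2[a] - rho2 for t in range(T)] for a in range(A)]
        d3 = [[n3[b][t] / area3[b] - rho3 for t in range(T)] for b in range(B)]
        for a in range(A):
            for t in range(T):
                g12_sum[a] += d2[a][t]
            for b in range(B):
                for d in range(T):
                    s = 0.0
                    c = 0.0
                    for t in range(T):
                        s += d2[a][t] * d3[b][(t + d) % T]
                        c += n2[a][t] * n3[b][(t + d) % T]
                    num[a][b][d] += s
                    pc[a][b][d] += c
        n_terms += T

    f = np.array(num) / n_terms / (rho2 * rho3)
    g12 = np.array(g12_sum) / n_terms
    return f, np.array(pc), g12


def c3_loops(f, g12, rho2, rho3):
    """Conditional density from loop-computed moments: f·ρ2·ρ3 / g12."""
    return f * rho2 * rho3 / np.asarray(g12)[:, None, None]


def weighted_box_mean_loops(frame, var, box):
    """Per-pixel inverse-variance-weighted box mean with reflect padding."""
    h = box // 2
    fp = np.pad(frame, h, mode="symmetric")
    wp = np.pad(1.0 / var, h, mode="symmetric")
    out = np.zeros_like(frame, dtype=float)
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            num = den = 0.0
            for a in range(box):
                for b in range(box):
                    num += fp[i + a, j + b] * wp[i + a, j + b]
                    den += wp[i + a, j + b]
            out[i, j] = num / den
    return out


def expected_patch(params, size, sigma):
    """Independent integrated-Gaussian model µ for a [x,y,N,b] patch."""
    from scipy.special import erf

    x, y, N, b = params
    s2 = sigma * math.sqrt(2.0)
    e = np.arange(size + 1, dtype=float)
    Ex = np.diff(0.5 * (1 + erf((e - x) / s2)))
    Ey = np.diff(0.5 * (1 + erf((e - y) / s2)))
    return b + N * np.outer(Ey, Ex)


def fisher_fd(params, size, sigma, var, eps=1e-5):
    """Finite-difference Fisher information of the variance-shifted Poisson
    model, built on the independent ``expected_patch``."""
    params = np.asarray(params, float)
    mu = expected_patch(params, size, sigma) + var
    grads = []
    for i in range(4):
        hi, lo = params.copy(), params.copy()
        hi[i] += eps
        lo[i] -= eps
        grads.append((expected_patch(hi, size, sigma)
                      - expected_patch(lo, size, sigma)) / (2 * eps))
    I = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            I[i, j] = np.sum(grads[i] * grads[j] / mu)
    return I


def false_triplet_rate_loops(g4, mcm, edu, r_assoc):
    """Fraction of G4 points with both an MCM and an EdU point in range."""
    n = 0
    for g in g4:
        has_m = any(math.hypot(g[0] - m[0], g[1] - m[1]) <= r_assoc for m in mcm)
        has_e = any(math.hypot(g[0] - e[0], g[1] - e[1]) <= r_assoc for e in edu)
        n += has_m and has_e
    return n / max(len(g4), 1)
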