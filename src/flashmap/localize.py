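"""Single-molecule spot detection and sub-pixel localization.

Candidates are local maxima of a box-smoothed frame above a robust
(MAD-based) threshold; each candidate ROI is fit by maximum likelihood with
a pixel-integrated symmetric 2-D Gaussian plus constant background under
Poisson noise.  The per-axis localization precision is reported with the
standard background-corrected formula

    sqrt( sigma_a^2 / N * (16/9 + 8 pi sigma_a^2 b / (N a^2)) ),
    sigma_a^2 = sigma_psf^2 + a^2 / 12,

with the fitted photon count N, background b (photons/pixel), PSF width
sigma_psf and pixel size a.

Pixel coordinate convention: pixel (row j, col i) covers the unit square
[i, i+1) x [j, j+1), so a spot at the centre of pixel (0, 0) has position
(0.5, 0.5) px; nm positions are px * pixel_size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import minimize

from .tables import LocalizationTable

__all__ = [
    "SpotFit",
    "detect_candidates",
    "fit_spot",
    "localize_movie",
    "link_blinks",
    "precision_formula",
]


def precision_formula(
    n_photons: float | np.ndarray,
    background: float | np.ndarray,
    sigma_psf: float | np.ndarray,
    pixel_size: float,
) -> float | np.ndarray:
    """Per-axis localization precision (nm) for an MLE Gaussian fit."""
    sigma_a2 = np.asarray(sigma_psf, dtype=float) ** 2 + pixel_size**2 / 12.0
    n = np.asarray(n_photons, dtype=float)
    b = np.asarray(background, dtype=float)
    var = sigma_a2 / n * (16.0 / 9.0 + 8.0 * np.pi * sigma_a2 * b / (n * pixel_size**2))
    return np.sqrt(var)


@dataclass
class SpotFit:
    """Result of fitting one candidate ROI.

    Positions are in pixels relative to the ROI's top-left corner; callers
    convert to frame/nm coordinates.  ``converged`` is False when the
    optimizer hit its iteration budget or the fit left its bounds, in which
    case (x, y) fall back to the background-subtracted centroid.
    """

    x: float
    y: float
    photons: float
    background: float
    sigma: float  # PSF sd in px
    converged: bool


def detect_candidates(
    frame: np.ndarray, threshold_k: float, psf_sigma_px: float = 1.2
) -> list[tuple[int, int]]:
    """Local-maximum candidate detection on one frame.

    The frame is 3x3 box-smoothed; local maxima exceeding
    ``median + threshold_k * robust_sd`` (robust sd = 1.4826 * MAD) are
    kept; maxima closer than ``2 * ceil(psf_sigma_px)`` pixels are merged
    keeping the brighter one (ties: smaller row, then smaller column).
    Returns (row, col) pixel coordinates.
    """
    img = np.asarray(frame, dtype=float)
    smooth = ndimage.uniform_filter(img, size=3, mode="nearest")
    med = np.median(smooth)
    mad = np.median(np.abs(smooth - med))
    thr = med + threshold_k * 1.4826 * mad
    is_max = (ndimage.maximum_filter(smooth, size=3, mode="nearest") == smooth) & (
        smooth > thr
    )
    rows, cols = np.nonzero(is_max)
    if len(rows) == 0:
        return []
    vals = smooth[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    rows, cols, vals = rows[order], cols[order], vals[order]
    min_sep = 2 * int(np.ceil(psf_sigma_px))
    kept: list[tuple[int, int]] = []
    for r, c in zip(rows, cols):
        if all((r - kr) ** 2 + (c - kc) ** 2 >= min_sep**2 for kr, kc in kept):
            kept.append((int(r), int(c)))
    kept.sort()
    return kept


def _model_terms(shape: tuple[int, int], x: float, y: float, sigma: float):
    """1-D integrated-Gaussian masses and their derivatives for an ROI."""
    from scipy.special import erf

    h, w = shape
    ex = np.arange(w + 1, dtype=float)
    ey = np.arange(h + 1, dtype=float)
    s2 = np.sqrt(2.0) * sigma
    ux = (ex - x) / s2
    uy = (ey - y) / s2
    gx = 0.5 * (erf(ux[1:]) - erf(ux[:-1]))
    gy = 0.5 * (erf(uy[1:]) - erf(uy[:-1]))
    kx = np.exp(-(ux**2)) / np.sqrt(np.pi)
    ky = np.exp(-(uy**2)) / np.sqrt(np.pi)
    dgx_dx = (kx[:-1] - kx[1:]) / s2
    dgy_dy = (ky[:-1] - ky[1:]) / s2
    dgx_ds = (ux[:-1] * kx[:-1] - ux[1:] * kx[1:]) / sigma
    dgy_ds = (uy[:-1] * ky[:-1] - uy[1:] * ky[1:]) / sigma
    return gx, gy, dgx_dx, dgy_dy, dgx_ds, dgy_ds


def _nll_and_grad(theta: np.ndarray, roi: np.ndarray) -> tuple[float, np.ndarray]:
    """Poisson negative log-likelihood and gradient for (x, y, N, b, sigma)."""
    x, y, n, b, sigma = theta
    gx, gy, dgx_dx, dgy_dy, dgx_ds, dgy_ds = _model_terms(roi.shape, x, y, sigma)
    psf = np.outer(gy, gx)
    mu = b + n * psf
    mu = np.maximum(mu, 1e-12)
    nll = float(np.sum(mu - roi * np.log(mu)))
    w = 1.0 - roi / mu
    grad = np.empty(5)
    grad[0] = np.sum(w * n * np.outer(gy, dgx_dx))
    grad[1] = np.sum(w * n * np.outer(dgy_dy, gx))
    grad[2] = np.sum(w * psf)
    grad[3] = np.sum(w)
    grad[4] = np.sum(w * n * (np.outer(gy, dgx_ds) + np.outer(dgy_ds, gx)))
    return nll, grad


def _centroid(roi: np.ndarray) -> tuple[float, float]:
    img = roi - roi.min()
    total = img.sum()
    if total <= 0:
        h, w = roi.shape
        return w / 2.0, h / 2.0
    jj, ii = np.mgrid[0 : roi.shape[0], 0 : roi.shape[1]]
    return (
        float(np.sum(img * (ii + 0.5)) / total),
        float(np.sum(img * (jj + 0.5)) / total),
    )


def fit_spot(
    roi: np.ndarray,
    pixel_size: float,
    psf_sigma_init: float,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> SpotFit:
    """MLE fit of one ROI: integrated 2-D Gaussian + flat background.

    ``psf_sigma_init`` is the nominal PSF sd in nm; the fitted sd is bounded
    to [0.5, 3] times it.  Non-convergence within ``max_iter`` iterations
    returns ``converged=False`` with the centroid as fallback position.
    """
    roi = np.asarray(roi, dtype=float)
    h, w = roi.shape
    if roi.sum() <= 0:
        return SpotFit(w / 2, h / 2, 0.0, 0.0, psf_sigma_init / pixel_size, False)
    s0 = psf_sigma_init / pixel_size
    edge = np.concatenate([roi[0], roi[-1], roi[1:-1, 0], roi[1:-1, -1]])
    b0 = max(float(np.median(edge)), 1e-3)
    n0 = max(float(roi.sum() - b0 * roi.size), 10.0)
    cx, cy = _centroid(roi)
    theta0 = np.array([cx, cy, n0, b0, s0])
    bounds = [
        (0.5, w - 0.5),
        (0.5, h - 0.5),
        (1e-3, None),
        (1e-9, None),
        (0.5 * s0, 3.0 * s0),
    ]
    res = minimize(
        _nll_and_grad,
        theta0,
        args=(roi,),
        jac=True,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": tol},
    )
    x, y, n, b, sigma = res.x
    converged = bool(res.success) and n > 0
    if not converged:
        x, y = _centroid(roi)
    return SpotFit(float(x), float(y), float(n), float(b), float(sigma), converged)


def roi_half_size(psf_sigma: float, pixel_size: float) -> int:
    """ROI half-width: ceil(2 sigma_psf / a) + 1 (captures >95% of the PSF)."""
    return int(np.ceil(2.0 * psf_sigma / pixel_size)) + 1


def localize_movie(
    stack: np.ndarray,
    sidecar: dict,
    threshold_k: float = 5.0,
    max_iter: int = 50,
) -> LocalizationTable:
    """Detect and fit spots in every frame of a rendered stack.

    The sidecar provides the pixel size, PSF width, and per-round frame
    ranges; rounds are assigned from the ranges.  Unconverged fits are
    dropped and counted in the table's ``counters``.
    """
    a = float(sidecar["pixel_size"])
    psf_sigma = float(sidecar["psf_sigma"])
    ranges = sidecar["frame_ranges"]
    n_expected = ranges[-1][1]
    if len(stack) != n_expected:
        raise ValueError(
            f"sidecar frame ranges cover {n_expected} frames, stack has {len(stack)}"
        )
    m = roi_half_size(psf_sigma, a)
    sigma_px = psf_sigma / a
    round_of_frame = np.empty(n_expected, dtype=np.int64)
    for r, (lo, hi) in enumerate(ranges):
        round_of_frame[lo:hi] = r
    rows = []
    n_dropped = 0
    h_px, w_px = stack.shape[1:]
    for f in range(len(stack)):
        frame = stack[f]
        for r, c in detect_candidates(frame, threshold_k, sigma_px):
            if not (m <= r < h_px - m and m <= c < w_px - m):
                continue
            roi = frame[r - m : r + m + 1, c - m : c + m + 1]
            fit = fit_spot(roi, a, psf_sigma, max_iter=max_iter)
            if not fit.converged:
                n_dropped += 1
                continue
            sigma_nm = fit.sigma * a
            rows.append(
                (
                    f,
                    round_of_frame[f],
                    (c - m + fit.x) * a,
                    (r - m + fit.y) * a,
                    fit.photons,
                    precision_formula(fit.photons, fit.background, sigma_nm, a),
                    sigma_nm,
                    fit.background,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "frame",
            "round",
            "x",
            "y",
            "photons",
            "loc_precision",
            "sigma_psf_fit",
            "background",
        ],
    )
    return LocalizationTable(
        df=df,
        pixel_size=a,
        counters={"fits_dropped": n_dropped, "fits_kept": len(df)},
    )


def link_blinks(
    table: LocalizationTable, max_gap: int = 1, max_dist: float = 100.0
) -> LocalizationTable:
    """Merge localizations of one binding event into a single record.

    Within a round, localizations in consecutive frames (allowing up to
    ``max_gap`` dark frames) within ``max_dist`` nm of each other are
    chained and merged to their precision-weighted (inverse-variance) mean;
    photons are summed; merged precision is the inverse-variance combination
    ``1 / sqrt(sum(1 / prec_i**2))``.  Linking is greedy in frame order then
    record index, so the result is deterministic.
    """
    df = table.df
    if len(df) == 0:
        return table.replace()
    merged_rows = []
    extra_int = [c for c in ("species", "site") if c in df.columns]
    for rnd, sub in df.groupby("round", sort=True):
        sub = sub.sort_values(["frame"], kind="stable")
        frames = sub["frame"].to_numpy()
        xs = sub["x"].to_numpy()
        ys = sub["y"].to_numpy()
        phot = sub["photons"].to_numpy()
        prec = sub["loc_precision"].to_numpy()
        extras = {c: sub[c].to_numpy() for c in extra_int}
        chains: list[list[int]] = []
        open_chains: list[int] = []  # indices into chains
        for i in range(len(sub)):
            f = frames[i]
            best = -1
            best_d = max_dist
            for ci in open_chains:
                last = chains[ci][-1]
                if frames[last] >= f:  # same frame: one loc per event per frame
                    continue
                if f - frames[last] > max_gap + 1:
                    continue
                d = float(np.hypot(xs[i] - xs[last], ys[i] - ys[last]))
                if d <= best_d:
                    best_d = d
                    best = ci
            if best >= 0:
                chains[best].append(i)
            else:
                chains.append([i])
                open_chains.append(len(chains) - 1)
            open_chains = [
                ci for ci in open_chains if f - frames[chains[ci][-1]] <= max_gap + 1
            ]
        for chain in chains:
            idx = np.array(chain)
            wgt = 1.0 / prec[idx] ** 2
            wsum = wgt.sum()
            row = {
                "frame": int(frames[idx[0]]),
                "round": int(rnd),
                "x": float(np.sum(xs[idx] * wgt) / wsum),
                "y": float(np.sum(ys[idx] * wgt) / wsum),
                "photons": float(phot[idx].sum()),
                "loc_precision": float(1.0 / np.sqrt(wsum)),
                "n_frames": int(len(idx)),
            }
            for c in extra_int:
                row[c] = int(extras[c][idx[0]])
            merged_rows.append(row)
    out = pd.DataFrame(merged_rows)
    counters = dict(table.counters)
    counters["linked_from"] = len(df)
    counters["linked_to"] = len(out)
    return LocalizationTable(
        df=out,
        pixel_size=table.pixel_size,
        drift_corrected=table.drift_corrected,
        aligned=table.aligned,
        counters=counters,
    )
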