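"""Independent reference implementations used to check the package.

Everything here is deliberately naive (brute force, direct Monte Carlo,
fine-grid numerical integration) and shares no code with the package paths
it validates.
"""

from __future__ import annotations

import numpy as np


def brute_force_nn(
    xy_a: np.ndarray, xy_b: np.ndarray, r_max: float, same: bool
) -> np.ndarray:
    """Exhaustive O(n^2) per-A nearest-neighbor distances, filtered at r_max."""
    out = []
    for i, p in enumerate(xy_a):
        d = np.sqrt((xy_b[:, 0] - p[0]) ** 2 + (xy_b[:, 1] - p[1]) ** 2)
        if same:
            d[i] = np.inf
        m = d.min()
        if m <= r_max:
            out.append(m)
    return np.asarray(out)


def brute_force_all_pairs(
    xy_a: np.ndarray, xy_b: np.ndarray, r_max: float, same: bool
) -> np.ndarray:
    """Exhaustive all-cross-pair distances <= r_max, in (i, j) scan order."""
    out = []
    for i, p in enumerate(xy_a):
        d = np.sqrt((xy_b[:, 0] - p[0]) ** 2 + (xy_b[:, 1] - p[1]) ** 2)
        for j, dij in enumerate(d):
            if same and i == j:
                continue
            if dij <= r_max:
                out.append(dij)
    return np.asarray(out)


def renewal_event_counts(
    n_sites: int,
    frames: int,
    mean_dark: float,
    mean_bright: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Events per site for alternating geometric dark/bright dwells (dark first)."""
    counts = np.zeros(n_sites, dtype=int)
    active = np.arange(n_sites)
    clock = np.zeros(n_sites, dtype=int)
    while len(active):
        d = rng.geometric(1.0 / mean_dark, len(active))
        b = rng.geometric(1.0 / mean_bright, len(active))
        start = clock[active] + d
        ok = start <= frames - 1
        counts[active[ok]] += 1
        clock[active] = start + b
        active = active[ok]
    return counts


def mc_nn_median(
    delta: float,
    density_per_nm: float,
    frames: int,
    mean_dark: float,
    mean_bright: float,
    photons_per_frame: float,
    psf_sigma: float,
    n_draws: int,
    rng: np.random.Generator,
    r_max: float = 500.0,
    window: float = 600.0,
) -> float:
    """Monte-Carlo nearest-neighbor median between two labelled line layers.

    Each draw realises the generative model around one query localization:
    target sites arrive as a 1-D Poisson process on a parallel line at
    distance ``delta``; every site blinks with the telegraph kinetics, each
    event yielding one localization with photon-dependent Gaussian error;
    the query localization gets its own error draw.  The returned value is
    the median of the per-draw nearest-neighbor distances under ``r_max``.
    """
    meds = np.empty(n_draws)
    for i in range(n_draws):
        n_b = rng.poisson(density_per_nm * 2 * window)
        site_x = rng.uniform(-window, window, n_b)
        k = renewal_event_counts(n_b, frames, mean_dark, mean_bright, rng)
        total = int(k.sum())
        if total == 0:
            meds[i] = np.inf
            continue
        loc_site_x = np.repeat(site_x, k)
        n_frames_ev = np.minimum(rng.geometric(1.0 / mean_bright, total), frames)
        photons = np.maximum(rng.poisson(n_frames_ev * photons_per_frame), 1).astype(
            float
        )
        sig = psf_sigma / np.sqrt(photons)
        lx = loc_site_x + rng.normal(0.0, 1.0, total) * sig
        ly = delta + rng.normal(0.0, 1.0, total) * sig
        n_frames_q = min(rng.geometric(1.0 / mean_bright), frames)
        photons_q = max(rng.poisson(n_frames_q * photons_per_frame), 1)
        sig_q = psf_sigma / np.sqrt(photons_q)
        qx, qy = rng.normal(0.0, sig_q), rng.normal(0.0, sig_q)
        meds[i] = float(np.sqrt((lx - qx) ** 2 + (ly - qy) ** 2).min())
    meds = meds[np.isfinite(meds) & (meds <= r_max)]
    return float(np.median(meds))


def mc_contamination_fraction(
    eps: float,
    n_sites_per_species: int,
    frames: int,
    mean_dark: float,
    mean_bright: float,
    rng: np.random.Generator,
) -> float:
    """One Monte-Carlo replicate of the round-1 contamination fraction.

    Two species, two rounds: in round 1 all of species 1's sites are active
    and each species-0 site survives erasure with probability ``eps``.  The
    returned fraction is (events from species 0) / (all round-1 events).
    """
    n0 = int(rng.binomial(n_sites_per_species, eps))
    ev0 = renewal_event_counts(n0, frames, mean_dark, mean_bright, rng).sum()
    ev1 = renewal_event_counts(
        n_sites_per_species, frames, mean_dark, mean_bright, rng
    ).sum()
    total = ev0 + ev1
    return float(ev0) / total if total else 0.0


def fine_grid_psf_image(
    shape: tuple[int, int],
    x: float,
    y: float,
    sigma: float,
    n_photons: float,
    background: float,
    oversample: int = 21,
) -> np.ndarray:
    """Noiseless expected camera image by sub-pixel midpoint integration.

    Independent of the package's erf-based pixel integration: the Gaussian
    density is averaged over an ``oversample`` x ``oversample`` grid per
    pixel.  Coordinates in pixels; pixel (j, i) covers [i, i+1) x [j, j+1).
    """
    h, w = shape
    t = (np.arange(oversample) + 0.5) / oversample
    img = np.empty((h, w))
    for j in range(h):
        for i in range(w):
            xs = i + t
            ys = j + t
            gx = np.exp(-((xs - x) ** 2) / (2 * sigma**2))
            gy = np.exp(-((ys - y) ** 2) / (2 * sigma**2))
            img[j, i] = np.outer(gy, gx).mean() / (2 * np.pi * sigma**2)
    return background + n_photons * img
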