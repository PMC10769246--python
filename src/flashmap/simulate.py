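"""Sequential-round FLASH-PAINT acquisition simulator.

Each species' docking sites blink in its own imaging round via transient
imager binding (two-state telegraph kinetics at frame resolution); after a
round the species is chemically erased, leaving a residual active fraction
``eraser_residual`` (epsilon) per site per round, compounding geometrically,
so species ``s`` contaminates round ``r > s`` with per-site probability
``epsilon**(r - s)``.  Stage drift is a Gaussian random walk plus a linear
component.  Two fidelity levels are produced: *list mode* converts blink
events directly to noisy localizations; *frame mode* renders 16-bit camera
frames (integrated Gaussian PSF, Poisson photon and background noise) for
the full localization path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import BindingSiteSet
from .tables import LocalizationTable

__all__ = [
    "ImagingParams",
    "BlinkEvents",
    "DriftTrajectory",
    "simulate_rounds",
    "simulate_drift",
    "events_to_localizations",
    "render_movie",
    "contamination_probability",
]


@dataclass(frozen=True)
class ImagingParams:
    """Acquisition parameters of one sequential-round experiment.

    Defaults follow the acquisition they emulate: seven rounds of 30,000
    frames at 25 ms exposure on a camera with 108 nm effective pixels.
    ``mean_dark_frames`` / ``mean_bright_frames`` are the means of the
    geometric dwell times (frames) of the imager-unbound and imager-bound
    states of a docking site; ``photons_per_frame`` is the expected photon
    yield of a bound imager per frame; ``eraser_residual`` is the fraction
    of a species' adapters still active after one erasure.
    """

    n_rounds: int = 7
    frames_per_round: int = 30_000
    exposure_ms: float = 25.0
    mean_dark_frames: float = 500.0
    mean_bright_frames: float = 3.0
    photons_per_frame: float = 800.0
    background_photons: float = 5.0
    psf_sigma: float = 130.0
    pixel_size: float = 108.0
    eraser_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.n_rounds < 1 or self.frames_per_round < 1:
            raise ValueError("n_rounds and frames_per_round must be >= 1")
        if min(
            self.exposure_ms,
            self.mean_dark_frames,
            self.mean_bright_frames,
            self.photons_per_frame,
            self.psf_sigma,
            self.pixel_size,
        ) <= 0:
            raise ValueError("rates and durations must be > 0")
        if self.background_photons < 0:
            raise ValueError("background_photons must be >= 0")
        if not 0 <= self.eraser_residual < 1:
            raise ValueError(
                "eraser_residual must be in [0, 1): residual 1 never terminates"
            )

    @property
    def n_frames_total(self) -> int:
        return self.n_rounds * self.frames_per_round

    def frame_range(self, rnd: int) -> tuple[int, int]:
        """Global [start, stop) frame range of one round."""
        return rnd * self.frames_per_round, (rnd + 1) * self.frames_per_round


def contamination_probability(eps: float, rnd: int, species: int) -> float:
    """Probability that a site of ``species`` is still active in round ``rnd``.

    Each erasure leaves a site's adapter active independently with
    probability ``eps``, so after ``rnd - species`` erasures the survival
    probability is ``eps ** (rnd - species)``; species added after ``rnd``
    are never active.
    """
    if species > rnd:
        return 0.0
    return float(eps) ** (rnd - species)


@dataclass(frozen=True)
class BlinkEvents:
    """Column-store of binding events (one imager binding at one site).

    ``site_index`` references the :class:`~flashmap.geometry.BindingSiteSet`
    that produced the events; ``start_frame`` is 0-based within the round.
    """

    site_index: np.ndarray
    round: np.ndarray
    start_frame: np.ndarray
    n_frames: np.ndarray
    total_photons: np.ndarray

    def __post_init__(self) -> None:
        for name in ("site_index", "round", "start_frame", "n_frames", "total_photons"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=np.int64)
            )

    def __len__(self) -> int:
        return len(self.site_index)

    def species(self, sites: BindingSiteSet) -> np.ndarray:
        return sites.species_id[self.site_index]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_index": self.site_index,
                "round": self.round,
                "start_frame": self.start_frame,
                "n_frames": self.n_frames,
                "total_photons": self.total_photons,
            }
        )


@dataclass(frozen=True)
class DriftTrajectory:
    """Per-global-frame stage displacement (nm), anchored at frame 0."""

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "dx", np.asarray(self.dx, dtype=float))
        object.__setattr__(self, "dy", np.asarray(self.dy, dtype=float))
        if len(self.dx) != len(self.dy):
            raise ValueError("dx and dy must have equal length")
        if not (np.all(np.isfinite(self.dx)) and np.all(np.isfinite(self.dy))):
            raise ValueError("drift must be finite")

    def __len__(self) -> int:
        return len(self.dx)

    def __neg__(self) -> "DriftTrajectory":
        return DriftTrajectory(-self.dx, -self.dy)

    @classmethod
    def zero(cls, n_frames: int) -> "DriftTrajectory":
        return cls(np.zeros(n_frames), np.zeros(n_frames))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame": np.arange(len(self)), "dx": self.dx, "dy": self.dy}
        )


def simulate_drift(
    n_frames_total: int,
    step_sigma: float,
    linear_velocity: tuple[float, float],
    seed: int | np.random.Generator,
) -> DriftTrajectory:
    """Random-walk plus linear stage drift, anchored so frame 0 is (0, 0)."""
    if step_sigma < 0:
        raise ValueError("step_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames_total, dtype=float)
    vx, vy = linear_velocity
    if step_sigma > 0:
        steps = rng.normal(0.0, step_sigma, size=(n_frames_total - 1, 2))
        walk = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    else:
        walk = np.zeros((n_frames_total, 2))
    return DriftTrajectory(walk[:, 0] + vx * t, walk[:, 1] + vy * t)


def _blink_trains(
    n_sites: int,
    frames: int,
    mean_dark: float,
    mean_bright: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Alternating geometric dark/bright renewal trains for ``n_sites`` sites.

    Returns (site_local_index, start_frame, n_frames) for all events, with
    the final event truncated at the round boundary.  Vectorised across
    sites: each site draws dwell pairs in batches until its clock passes the
    round length.
    """
    p_dark = 1.0 / mean_dark
    p_bright = 1.0 / mean_bright
    # expected events per site plus safety margin, drawn in batches
    per_site = frames / (mean_dark + mean_bright)
    batch = max(4, int(per_site + 4 * np.sqrt(max(per_site, 1.0)) + 4))
    sites_idx: list[np.ndarray] = []
    starts: list[np.ndarray] = []
    durs: list[np.ndarray] = []
    active = np.arange(n_sites)
    clock = np.zeros(n_sites, dtype=np.int64)
    while len(active):
        dark = rng.geometric(p_dark, size=(len(active), batch))
        bright = rng.geometric(p_bright, size=(len(active), batch))
        # event k of this batch starts after cumulative dark+bright history
        incr = dark + bright
        end = np.cumsum(incr, axis=1)
        start = clock[active, None] + end - bright
        valid = start < frames
        n_frames_ev = np.minimum(bright, frames - np.where(valid, start, 0))
        rows, cols = np.nonzero(valid)
        sites_idx.append(active[rows])
        starts.append(start[rows, cols])
        durs.append(n_frames_ev[rows, cols])
        clock[active] += end[:, -1]
        unfinished = valid[:, -1]  # last drawn event still inside the round
        active = active[unfinished]
    if not sites_idx:
        empty = np.empty(0, dtype=np.int64)
        return empty, empty, empty
    return (
        np.concatenate(sites_idx),
        np.concatenate(starts),
        np.concatenate(durs),
    )


def simulate_rounds(
    sites: BindingSiteSet,
    params: ImagingParams,
    seed: int | np.random.Generator,
) -> BlinkEvents:
    """Simulate blinking over all sequential rounds, including erasure residue.

    Round ``r`` images species ``r``: all of its sites are active, and each
    site of an earlier species ``s`` is independently active with probability
    ``eraser_residual ** (r - s)``.  Per active site, events arrive as an
    alternating renewal process (geometric dark and bright dwell times);
    event photon counts are Poisson with mean ``n_frames *
    photons_per_frame``.  Deterministic given the seed.
    """
    if sites.n_species < params.n_rounds:
        raise ValueError("n_rounds must not exceed the number of species")
    rng = np.random.default_rng(seed)
    eps = params.eraser_residual
    ev_site: list[np.ndarray] = []
    ev_round: list[np.ndarray] = []
    ev_start: list[np.ndarray] = []
    ev_dur: list[np.ndarray] = []
    for r in range(params.n_rounds):
        active_mask = sites.species_id == r
        if eps > 0:
            for s in range(r):
                p = contamination_probability(eps, r, s)
                if p <= 0:
                    continue
                sp_mask = sites.species_id == s
                survive = rng.random(len(sites)) < p
                active_mask = active_mask | (sp_mask & survive)
        active_idx = np.nonzero(active_mask)[0]
        if len(active_idx) == 0:
            continue
        local, start, dur = _blink_trains(
            len(active_idx),
            params.frames_per_round,
            params.mean_dark_frames,
            params.mean_bright_frames,
            rng,
        )
        order = np.lexsort((local, start))
        ev_site.append(active_idx[local[order]])
        ev_round.append(np.full(len(local), r, dtype=np.int64))
        ev_start.append(start[order])
        ev_dur.append(dur[order])
    if ev_site:
        site_index = np.concatenate(ev_site)
        rnd = np.concatenate(ev_round)
        start_frame = np.concatenate(ev_start)
        n_frames = np.concatenate(ev_dur)
    else:
        site_index = rnd = start_frame = n_frames = np.empty(0, dtype=np.int64)
    photons = rng.poisson(n_frames * params.photons_per_frame)
    return BlinkEvents(site_index, rnd, start_frame, n_frames, photons)


def events_to_localizations(
    events: BlinkEvents,
    sites: BindingSiteSet,
    drift: DriftTrajectory,
    params: ImagingParams,
    seed: int | np.random.Generator,
) -> LocalizationTable:
    """List-mode shortcut: one localization per blink event.

    The localization sits at the site's true position, displaced by the
    stage drift at the event's middle frame, plus isotropic Gaussian
    localization error of per-axis sd ``psf_sigma / sqrt(total_photons)``.
    Events with zero photons are dropped and counted.
    """
    if len(drift) < params.n_frames_total:
        raise ValueError("drift trajectory does not cover all frames")
    rng = np.random.default_rng(seed)
    keep = events.total_photons > 0
    n_dropped = int(np.sum(~keep))
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} zero-photon events", stacklevel=2)
    site = events.site_index[keep]
    rnd = events.round[keep]
    start = events.start_frame[keep]
    dur = events.n_frames[keep]
    photons = events.total_photons[keep].astype(float)
    gframe = rnd * params.frames_per_round + start + dur // 2
    sigma = params.psf_sigma / np.sqrt(photons)
    noise = rng.normal(size=(len(site), 2)) * sigma[:, None]
    df = pd.DataFrame(
        {
            "frame": gframe,
            "round": rnd,
            "x": sites.x[site] + drift.dx[gframe] + noise[:, 0],
            "y": sites.y[site] + drift.dy[gframe] + noise[:, 1],
            "photons": photons,
            "loc_precision": sigma,
            "species": sites.species_id[site],
            "site": site,
            "n_frames": dur,
        }
    )
    return LocalizationTable(
        df=df,
        pixel_size=params.pixel_size,
        counters={"events": len(events), "zero_photon_dropped": n_dropped},
    )


def _integrated_gaussian_1d(edges: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Pixel-integrated Gaussian mass between consecutive ``edges`` (px)."""
    u = (edges - mu) / (np.sqrt(2.0) * sigma)
    c = 0.5 * erf(u)
    return c[1:] - c[:-1]


def render_movie(
    events: BlinkEvents,
    sites: BindingSiteSet,
    drift: DriftTrajectory,
    params: ImagingParams,
    field_px: tuple[int, int],
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, dict]:
    """Render 16-bit camera frames from the blink events.

    Every frame a bright event contributes an integrated 2-D Gaussian
    (sd ``psf_sigma``) centred at its site's drifted position with expected
    total ``photons_per_frame``; the frame is then Poisson sampled on top of
    a flat Poisson background.  Returns the (n_frames, h, w) uint16 stack
    and a sidecar metadata dict (pixel size, PSF width, per-round frame
    ranges, clipped-emitter count).
    """
    w_px, h_px = field_px
    a = params.pixel_size
    sigma_px = params.psf_sigma / a
    half = int(np.ceil(4 * sigma_px)) + 1
    n_total = params.n_frames_total
    rng = np.random.default_rng(seed)

    # expand events to (global frame, site) bright pairs
    gstart = events.round * params.frames_per_round + events.start_frame
    frame_ids = np.repeat(gstart, events.n_frames) + _ragged_arange(events.n_frames)
    site_ids = np.repeat(events.site_index, events.n_frames)
    order = np.argsort(frame_ids, kind="stable")
    frame_ids = frame_ids[order]
    site_ids = site_ids[order]
    bounds = np.searchsorted(frame_ids, np.arange(n_total + 1))

    stack = np.empty((n_total, h_px, w_px), dtype=np.uint16)
    n_clipped = 0
    for f in range(n_total):
        lam = np.full((h_px, w_px), params.background_photons, dtype=float)
        for k in range(bounds[f], bounds[f + 1]):
            s = site_ids[k]
            cx = (sites.x[s] + drift.dx[f]) / a
            cy = (sites.y[s] + drift.dy[f]) / a
            if not (0 <= cx < w_px and 0 <= cy < h_px):
                n_clipped += 1
                continue
            i0 = max(int(np.floor(cx)) - half, 0)
            i1 = min(int(np.floor(cx)) + half + 1, w_px)
            j0 = max(int(np.floor(cy)) - half, 0)
            j1 = min(int(np.floor(cy)) + half + 1, h_px)
            gx = _integrated_gaussian_1d(np.arange(i0, i1 + 1, dtype=float), cx, sigma_px)
            gy = _integrated_gaussian_1d(np.arange(j0, j1 + 1, dtype=float), cy, sigma_px)
            lam[j0:j1, i0:i1] += params.photons_per_frame * np.outer(gy, gx)
        stack[f] = np.minimum(rng.poisson(lam), 65535).astype(np.uint16)

    sidecar = {
        "pixel_size": float(a),
        "psf_sigma": float(params.psf_sigma),
        "n_rounds": int(params.n_rounds),
        "frames_per_round": int(params.frames_per_round),
        "frame_ranges": [
            [int(r * params.frames_per_round), int((r + 1) * params.frames_per_round)]
            for r in range(params.n_rounds)
        ],
        "field_px": [int(w_px), int(h_px)],
        "background_photons": float(params.background_photons),
        "clipped_emitters": int(n_clipped),
    }
    return stack, sidecar


def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenated [0..c) ranges for each count c (vectorised)."""
    counts = np.asarray(counts, dtype=np.int64)
    if counts.sum() == 0:
        return np.empty(0, dtype=np.int64)
    ends = np.cumsum(counts)
    return np.arange(ends[-1]) - np.repeat(ends - counts, counts)


def write_movie(
    stack: np.ndarray, sidecar: dict, tiff_path: str | Path, sidecar_path: str | Path
) -> None:
    """Write a rendered stack as multi-page TIFF plus YAML sidecar."""
    import tifffile
    import yaml

    tifffile.imwrite(tiff_path, stack, photometric="minisblack")
    with open(sidecar_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=True)


def read_movie(tiff_path: str | Path, sidecar_path: str | Path) -> tuple[np.ndarray, dict]:
    """Read a TIFF stack and its YAML sidecar."""
    import tifffile
    import yaml

    stack = tifffile.imread(tiff_path)
    with open(sidecar_path) as fh:
        sidecar = yaml.safe_load(fh)
    return stack, sidecar
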