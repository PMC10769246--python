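"""Drift correction within rounds and rigid alignment across rounds.

Drift is estimated by redundant cross-correlation (RCC): each round's
frames are cut into equal temporal segments, each segment's localizations
are rendered as a blurred 2-D histogram, every segment pair's relative
shift is measured from the cross-correlation peak (sub-bin 3-point
quadratic interpolation per axis), and the overdetermined pairwise-shift
system is solved by least squares for per-segment displacements, anchored
at each round's first segment.  Per-frame drift is the piecewise-linear
interpolation through the segment mid-frames (linearly extrapolated at the
round edges).

Rounds image different species, so cross-round registration cannot reuse
RCC segments; instead each drift-corrected round's full rendering is
cross-correlated against a reference round and corrected by a rigid
translation (same instrument and field across rounds, so translation only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve

from .simulate import DriftTrajectory
from .tables import LocalizationTable

__all__ = [
    "RenderedImage",
    "RoundTransform",
    "render_histogram",
    "estimate_drift_rcc",
    "apply_drift",
    "align_rounds",
    "RegistrationError",
]


class RegistrationError(RuntimeError):
    pass


@dataclass(frozen=True)
class RenderedImage:
    """A 2-D histogram rendering of localizations.

    ``origin`` is the nm position of the image's (0, 0) bin corner; bin
    (j, i) covers [origin + i*bin, origin + (i+1)*bin) in x etc.
    """

    data: np.ndarray
    bin_size: float
    origin: tuple[float, float]
    blur_sigma: float = 0.0


def render_histogram(
    x: np.ndarray,
    y: np.ndarray,
    bin_size: float,
    blur_sigma: float = 0.0,
    extent: tuple[float, float, float, float] | None = None,
) -> RenderedImage:
    """Render localizations as a 2-D count histogram, optionally blurred.

    ``extent`` is (x0, x1, y0, y1) in nm; when omitted it is taken from the
    data padded by one bin.  Before blurring, the total intensity equals the
    number of rendered localizations.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if extent is None:
        if len(x) == 0:
            extent = (0.0, bin_size, 0.0, bin_size)
        else:
            extent = (
                float(x.min()) - bin_size,
                float(x.max()) + bin_size,
                float(y.min()) - bin_size,
                float(y.max()) + bin_size,
            )
    x0, x1, y0, y1 = extent
    nx = max(int(np.ceil((x1 - x0) / bin_size)), 1)
    ny = max(int(np.ceil((y1 - y0) / bin_size)), 1)
    hist, _, _ = np.histogram2d(
        y, x, bins=(ny, nx), range=((y0, y0 + ny * bin_size), (x0, x0 + nx * bin_size))
    )
    if blur_sigma > 0:
        hist = ndimage.gaussian_filter(hist, sigma=blur_sigma / bin_size, mode="constant")
    return RenderedImage(hist, bin_size, (x0, y0), blur_sigma)


def _quadratic_peak(c: np.ndarray, idx: int) -> float:
    """Sub-sample peak offset from 3-point quadratic interpolation."""
    if idx <= 0 or idx >= len(c) - 1:
        return 0.0
    denom = c[idx - 1] - 2 * c[idx] + c[idx + 1]
    if denom >= 0:  # flat or not a maximum
        return 0.0
    return float(0.5 * (c[idx - 1] - c[idx + 1]) / denom)


def xcorr_shift(
    a: np.ndarray, b: np.ndarray, bin_size: float
) -> tuple[float, float] | None:
    """Shift (sx, sy) in nm such that image ``b`` matches ``a`` displaced by it.

    Positive sx means ``b``'s structure sits at larger x than ``a``'s.
    Returns None when the correlation peak is degenerate (flat surface).
    """
    a = a - a.mean()
    b = b - b.mean()
    corr = fftconvolve(b, a[::-1, ::-1], mode="full")
    jmax, imax = np.unravel_index(np.argmax(corr), corr.shape)
    if corr[jmax, imax] <= 0:
        return None
    norm = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if norm == 0 or corr[jmax, imax] / norm < 1e-3:
        return None
    dy = jmax - (a.shape[0] - 1) + _quadratic_peak(corr[:, imax], jmax)
    dx = imax - (a.shape[1] - 1) + _quadratic_peak(corr[jmax, :], imax)
    return dx * bin_size, dy * bin_size


def _circular_shift(
    fa: np.ndarray,
    fb: np.ndarray,
    shape: tuple[int, int],
    bin_size: float,
    max_shift: float = 500.0,
) -> tuple[float, float] | None:
    """Pairwise shift from cached rFFTs via circular cross-correlation.

    Valid when the true shift is much smaller than the image (wrap-around
    aliasing negligible), which holds for stage drift over a field of view;
    the peak is searched within ``max_shift`` nm, which suppresses spurious
    far-field speckle peaks.  Peak indices above n/2 wrap to negative.
    """
    corr = np.fft.irfft2(fb * np.conj(fa), s=shape)
    ny, nx = shape
    w = int(np.ceil(max_shift / bin_size))
    jj = np.fft.fftfreq(ny, 1.0 / ny).astype(int)
    ii = np.fft.fftfreq(nx, 1.0 / nx).astype(int)
    mask = (np.abs(jj)[:, None] <= w) & (np.abs(ii)[None, :] <= w)
    cm = np.where(mask, corr, -np.inf)
    jmax, imax = np.unravel_index(np.argmax(cm), cm.shape)
    if not np.isfinite(cm[jmax, imax]) or cm[jmax, imax] <= 0:
        return None

    def _axis(c: np.ndarray, idx: int, n: int) -> float:
        prev, nxt = c[(idx - 1) % n], c[(idx + 1) % n]
        denom = prev - 2 * c[idx] + nxt
        frac = 0.0 if denom >= 0 else float(0.5 * (prev - nxt) / denom)
        pos = idx + frac
        return pos - n if pos > n / 2 else pos

    dy = _axis(corr[:, imax], jmax, ny)
    dx = _axis(corr[jmax, :], imax, nx)
    return dx * bin_size, dy * bin_size


def _segment_displacements(
    images: list[np.ndarray], bin_size: float
) -> np.ndarray:
    """Solve all pairwise shifts for per-segment displacements (segment 0 = 0).

    After the first least-squares solve, pairs whose residual exceeds both
    3x the median absolute residual and one bin are discarded and the
    system re-solved once: single bad correlation peaks otherwise leak into
    every interpolated frame.
    """
    n = len(images)
    shape = images[0].shape
    ffts = [np.fft.rfft2(img - img.mean()) for img in images]
    rows_a = []
    rhs = []
    for i in range(n):
        for j in range(i + 1, n):
            # shift of segment j's structure relative to segment i's,
            # i.e. the drift difference d_j - d_i
            s = _circular_shift(ffts[i], ffts[j], shape, bin_size)
            if s is None:
                warnings.warn(
                    f"degenerate correlation peak for segment pair ({i}, {j}); dropped",
                    stacklevel=2,
                )
                continue
            row = np.zeros(n)
            row[j] = 1.0
            row[i] = -1.0
            rows_a.append(row)
            rhs.append(s)
    if not rows_a:
        raise RegistrationError("no usable segment pairs for drift estimation")
    a_full = np.asarray(rows_a)
    rhs_arr = np.asarray(rhs)

    def _solve(a_rows: np.ndarray, b: np.ndarray) -> np.ndarray:
        sol, *_ = np.linalg.lstsq(a_rows[:, 1:], b, rcond=None)
        return np.vstack([[0.0, 0.0], sol])

    keep = np.ones(len(rhs_arr), dtype=bool)
    for _ in range(max(len(rhs_arr) // 4, 1)):
        disp = _solve(a_full[keep], rhs_arr[keep])
        resid = np.full(len(rhs_arr), -np.inf)
        resid[keep] = np.linalg.norm(
            rhs_arr[keep] - a_full[keep] @ disp, axis=1
        )
        cut = max(3.0 * np.median(resid[keep]), 2.0 * bin_size)
        worst = int(np.argmax(resid))
        if resid[worst] <= cut:
            break
        # drop the single worst pair, keeping every segment connected
        trial = keep.copy()
        trial[worst] = False
        degrees = np.abs(a_full[trial]).sum(axis=0)
        if np.all(degrees >= 1):
            keep = trial
        else:
            break
    return disp


def _interp_extrap(frames: np.ndarray, knots_f: np.ndarray, knots_v: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation with linear extrapolation at the edges."""
    out = np.interp(frames, knots_f, knots_v)
    if len(knots_f) >= 2:
        lo = frames < knots_f[0]
        hi = frames > knots_f[-1]
        s0 = (knots_v[1] - knots_v[0]) / (knots_f[1] - knots_f[0])
        s1 = (knots_v[-1] - knots_v[-2]) / (knots_f[-1] - knots_f[-2])
        out[lo] = knots_v[0] + s0 * (frames[lo] - knots_f[0])
        out[hi] = knots_v[-1] + s1 * (frames[hi] - knots_f[-1])
    return out


def estimate_drift_rcc(
    table: LocalizationTable,
    n_segments: int = 10,
    bin_size: float = 2.5,
    blur_sigma: float = 5.0,
    min_locs_per_segment: int = 50,
) -> DriftTrajectory:
    """Redundant cross-correlation drift estimation, per round.

    Returns a trajectory over all frames covered by the table's rounds,
    anchored at zero at the start of each round (inter-round offsets are
    recovered later by round alignment).
    """
    if n_segments < 2:
        raise ValueError("n_segments must be >= 2")
    df = table.df
    n_total = int(df["frame"].max()) + 1 if len(df) else 0
    dx = np.zeros(n_total)
    dy = np.zeros(n_total)
    pad = 3 * blur_sigma
    extent = (
        float(df["x"].min()) - pad,
        float(df["x"].max()) + pad,
        float(df["y"].min()) - pad,
        float(df["y"].max()) + pad,
    )
    for rnd in np.unique(df["round"]):
        sub = df[df["round"] == rnd]
        f_lo = int(sub["frame"].min())
        f_hi = int(sub["frame"].max()) + 1
        edges = np.linspace(f_lo, f_hi, n_segments + 1)
        seg_of = np.clip(
            np.searchsorted(edges, sub["frame"].to_numpy(), side="right") - 1,
            0,
            n_segments - 1,
        )
        images = []
        mids = []
        for s in range(n_segments):
            mask = seg_of == s
            if mask.sum() < min_locs_per_segment:
                raise RegistrationError(
                    f"segment {s} of round {rnd} has {int(mask.sum())} localizations "
                    f"(< {min_locs_per_segment})"
                )
            img = render_histogram(
                sub["x"].to_numpy()[mask],
                sub["y"].to_numpy()[mask],
                bin_size,
                blur_sigma,
                extent,
            )
            images.append(img.data)
            mids.append(0.5 * (edges[s] + edges[s + 1]))
        disp = _segment_displacements(images, bin_size)
        frames = np.arange(f_lo, f_hi)
        dx[frames] = _interp_extrap(frames, np.asarray(mids), disp[:, 0])
        dy[frames] = _interp_extrap(frames, np.asarray(mids), disp[:, 1])
        # anchor at the round's first frame
        dx[frames] -= dx[f_lo]
        dy[frames] -= dy[f_lo]
    return DriftTrajectory(dx, dy)


def apply_drift(table: LocalizationTable, drift: DriftTrajectory) -> LocalizationTable:
    """Subtract the drift at each record's frame from its coordinates."""
    if table.drift_corrected:
        raise RegistrationError("table is already drift-corrected")
    frames = table.df["frame"].to_numpy()
    if len(frames) and frames.max() >= len(drift):
        raise ValueError("drift trajectory does not cover all frames")
    out = table.df.copy()
    out["x"] = out["x"] - drift.dx[frames]
    out["y"] = out["y"] - drift.dy[frames]
    return LocalizationTable(
        df=out,
        pixel_size=table.pixel_size,
        drift_corrected=True,
        aligned=table.aligned,
        counters=dict(table.counters),
    )


@dataclass(frozen=True)
class RoundTransform:
    """Per-round rigid translations (nm); the reference round is (0, 0)."""

    reference_round: int
    tx: dict[int, float]
    ty: dict[int, float]


def align_rounds(
    table: LocalizationTable,
    reference_round: int = 0,
    bin_size: float = 2.5,
    blur_sigma: float = 5.0,
    min_correlation: float = 0.01,
    max_shift_nm: float = 2000.0,
) -> tuple[RoundTransform, LocalizationTable]:
    """Rigidly align every round's rendering to the reference round's.

    Each non-reference round is cross-correlated against the reference
    rendering on a common extent; the (sub-bin interpolated) peak shift is
    subtracted from the round's coordinates.  The peak is searched within
    ``max_shift_nm`` (inter-round shifts are residual drift, far smaller
    than the field); a round whose normalized correlation peak inside that
    window falls below ``min_correlation`` shares no structure with the
    reference and raises :class:`RegistrationError`.
    """
    df = table.df
    rounds = np.unique(df["round"])
    if reference_round not in rounds:
        raise ValueError(f"reference round {reference_round} not present")
    pad = 3 * blur_sigma
    extent = (
        float(df["x"].min()) - pad,
        float(df["x"].max()) + pad,
        float(df["y"].min()) - pad,
        float(df["y"].max()) + pad,
    )

    def _render(rnd: int) -> np.ndarray:
        sub = df[df["round"] == rnd]
        if len(sub) == 0:
            raise RegistrationError(f"round {rnd} is empty")
        return render_histogram(
            sub["x"].to_numpy(), sub["y"].to_numpy(), bin_size, blur_sigma, extent
        ).data

    ref_img = _render(int(reference_round))
    tx: dict[int, float] = {}
    ty: dict[int, float] = {}
    out = df.copy()
    for rnd in rounds:
        rnd = int(rnd)
        if rnd == reference_round:
            tx[rnd] = 0.0
            ty[rnd] = 0.0
            continue
        img = _render(rnd)
        a = ref_img - ref_img.mean()
        b = img - img.mean()
        corr = fftconvolve(b, a[::-1, ::-1], mode="full")
        # restrict the peak search to physically plausible shifts
        jj = np.arange(corr.shape[0]) - (a.shape[0] - 1)
        ii = np.arange(corr.shape[1]) - (a.shape[1] - 1)
        w = int(np.ceil(max_shift_nm / bin_size))
        windowed = corr.copy()
        windowed[np.abs(jj) > w, :] = -np.inf
        windowed[:, np.abs(ii) > w] = -np.inf
        jmax, imax = np.unravel_index(np.argmax(windowed), windowed.shape)
        norm = np.sqrt(np.sum(a * a) * np.sum(b * b))
        if norm == 0 or not np.isfinite(windowed[jmax, imax]) or (
            windowed[jmax, imax] / norm < min_correlation
        ):
            raise RegistrationError(
                f"round {rnd} shares no spatial overlap with round {reference_round}"
            )
        sy = jj[jmax] + _quadratic_peak(corr[:, imax], jmax)
        sx = ii[imax] + _quadratic_peak(corr[jmax, :], imax)
        sx *= bin_size
        sy *= bin_size
        mask = out["round"] == rnd
        out.loc[mask, "x"] = out.loc[mask, "x"] - sx
        out.loc[mask, "y"] = out.loc[mask, "y"] - sy
        tx[rnd] = sx
        ty[rnd] = sy
    aligned = LocalizationTable(
        df=out,
        pixel_size=table.pixel_size,
        drift_corrected=table.drift_corrected,
        aligned=True,
        counters=dict(table.counters),
    )
    return RoundTransform(int(reference_round), tx, ty), aligned
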