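"""Particle image velocimetry by windowed normalised cross-correlation.

Each interrogation window of the first frame is correlated against the same
window of the second frame (FFT correlation of mean-subtracted windows); the
correlation peak gives the displacement, refined to subpixel accuracy by a
three-point Gaussian fit.  A peak-to-second-peak ratio is stored per vector
as a signal-to-noise measure.

Spurious vectors are *flagged*, never modified or interpolated, by a filter
cascade applied in a fixed order: local normalised-median test, global
magnitude limit, SNR threshold, inside-cell mask, global standard-deviation
test.  Each stage iterates to a fixed point so the whole cascade is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import fft2, ifft2

__all__ = ["FlowGrid", "PivFilters", "piv_pair", "filter_cascade"]

REASONS = {0: "", 1: "median", 2: "global", 3: "snr", 4: "outside", 5: "std"}


@dataclass
class FlowGrid:
    """PIV vectors on the interrogation-window grid.

    ``x``/``y`` are window-centre pixel coordinates (2D arrays), ``u``/``v``
    displacements in px per frame pair (image convention: v positive down).
    """

    x: np.ndarray
    y: np.ndarray
    u: np.ndarray
    v: np.ndarray
    snr: np.ndarray
    valid: np.ndarray = None
    reason: np.ndarray = None
    window: int = 64
    dt: float = 1.0          # s between frames
    pixel_size: float = 1.0  # um / px

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones_like(self.u, dtype=bool)
        if self.reason is None:
            self.reason = np.zeros_like(self.u, dtype=int)

    @property
    def u_um_s(self) -> np.ndarray:
        return self.u * self.pixel_size / self.dt

    @property
    def v_um_s(self) -> np.ndarray:
        return self.v * self.pixel_size / self.dt

    def to_dataframe(self, frame: int = 0):
        import pandas as pd

        return pd.DataFrame({
            "frame": frame, "x": self.x.ravel(), "y": self.y.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(), "snr": self.snr.ravel(),
            "valid": self.valid.ravel(),
            "reason": [REASONS[r] for r in self.reason.ravel()],
        })


def _subpixel(corr: np.ndarray, i: int, j: int) -> tuple[float, float]:
    """Three-point Gaussian peak interpolation along each axis."""
    def offset(cm, c0, cp):
        cm, c0, cp = (max(v, 1e-12) for v in (cm, c0, cp))
        den = np.log(cm) - 2 * np.log(c0) + np.log(cp)
        if den >= 0:
            return 0.0
        return float((np.log(cm) - np.log(cp)) / (2 * den))

    di = dj = 0.0
    if 0 < i < corr.shape[0] - 1:
        di = offset(corr[i - 1, j], corr[i, j], corr[i + 1, j])
    if 0 < j < corr.shape[1] - 1:
        dj = offset(corr[i, j - 1], corr[i, j], corr[i, j + 1])
    return di, dj


def piv_pair(image_a: np.ndarray, image_b: np.ndarray, window: int = 64,
             overlap: int = 32, dt: float = 1.0, pixel_size: float = 1.0,
             snr_exclusion: int = 4) -> FlowGrid:
    """Correlate an image pair window by window.

    Returns the displacement field of the texture from frame A to frame B in
    pixels, with the search range limited to +-window/2.  ``snr_exclusion``
    is the half-width (px) masked around the main correlation peak before
    the second peak is read off; it should exceed the correlation-peak width
    (about 1.5x the tracer diameter).
    """
    a = np.asarray(image_a, dtype=float)
    b = np.asarray(image_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("images must have identical shapes")
    if window > min(a.shape):
        raise ValueError("interrogation window larger than the image")
    step = window - overlap
    if step <= 0:
        raise ValueError("overlap must be smaller than the window")
    rows = range(0, a.shape[0] - window + 1, step)
    cols = range(0, a.shape[1] - window + 1, step)
    half = window // 2
    X = np.empty((len(rows), len(cols)))
    Y = np.empty_like(X)
    U = np.empty_like(X)
    V = np.empty_like(X)
    S = np.empty_like(X)
    for ri, r0 in enumerate(rows):
        for ci, c0 in enumerate(cols):
            wa = a[r0:r0 + window, c0:c0 + window]
            wb = b[r0:r0 + window, c0:c0 + window]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            # circular correlation of B against A: peak at the displacement
            corr = np.real(ifft2(fft2(wb) * np.conj(fft2(wa))))
            corr = np.fft.fftshift(corr)
            # restrict to +-half-window shifts (whole plane after shift)
            i, j = np.unravel_index(np.argmax(corr), corr.shape)
            di, dj = _subpixel(corr, i, j)
            U[ri, ci] = j - half + dj
            V[ri, ci] = i - half + di
            peak = corr[i, j]
            excl = corr.copy()
            e = snr_exclusion
            i0, i1 = max(i - e, 0), min(i + e + 1, corr.shape[0])
            j0, j1 = max(j - e, 0), min(j + e + 1, corr.shape[1])
            excl[i0:i1, j0:j1] = -np.inf
            second = np.max(excl)
            S[ri, ci] = peak / second if second > 0 else np.inf
            X[ri, ci] = c0 + half
            Y[ri, ci] = r0 + half
    return FlowGrid(x=X, y=Y, u=U, v=V, snr=S, window=window, dt=dt,
                    pixel_size=pixel_size)


@dataclass
class PivFilters:
    """Thresholds of the vector filter cascade (fixture-tuned defaults)."""

    median_threshold: float = 3.0   # normalised-median test level
    median_eps: float = 0.2         # px, noise floor of the median test
    global_max: float = None        # px, unphysically strong vectors
    snr_min: float = 1.3
    std_threshold: float = 3.0      # sigmas around the global mean


def filter_cascade(grid: FlowGrid, cell_mask: np.ndarray = None,
                   thresholds: PivFilters = None) -> FlowGrid:
    """Apply the outlier filter cascade, flagging (never editing) vectors.

    Order: local median, global value, SNR, inside-cell mask, global std.
    ``cell_mask`` is a boolean image sampled at the window centres.  Returns
    a new FlowGrid sharing the vectors, with updated validity and reasons.
    """
    if thresholds is None:
        thresholds = PivFilters()
    valid = grid.valid.copy()
    reason = grid.reason.copy()
    U, V = grid.u, grid.v

    # 1. local normalised-median test, iterated to a fixed point
    for _ in range(U.size):
        eps = thresholds.median_eps
        n, m = U.shape
        flagged = False
        for i in range(n):
            for j in range(m):
                if not valid[i, j]:
                    continue
                ii0, ii1 = max(i - 1, 0), min(i + 2, n)
                jj0, jj1 = max(j - 1, 0), min(j + 2, m)
                sel = valid[ii0:ii1, jj0:jj1].copy()
                sel[i - ii0, j - jj0] = False
                if sel.sum() < 3:
                    continue
                un = U[ii0:ii1, jj0:jj1][sel]
                vn = V[ii0:ii1, jj0:jj1][sel]
                um, vm = np.median(un), np.median(vn)
                rm = np.median(np.hypot(un - um, vn - vm))
                r = np.hypot(U[i, j] - um, V[i, j] - vm) / (rm + eps)
                if r > thresholds.median_threshold:
                    valid[i, j] = False
                    reason[i, j] = 1
                    flagged = True
        if not flagged:
            break

    # 2. global value filter
    if thresholds.global_max is not None:
        bad = valid & (np.hypot(U, V) > thresholds.global_max)
        valid[bad] = False
        reason[bad] = 2

    # 3. signal-to-noise
    bad = valid & (grid.snr < thresholds.snr_min)
    valid[bad] = False
    reason[bad] = 3

    # 4. inside-cell mask
    if cell_mask is not None:
        inside = cell_mask[grid.y.astype(int), grid.x.astype(int)]
        bad = valid & ~inside
        valid[bad] = False
        reason[bad] = 4

    # 5. global standard-deviation filter (per component, with a small px
    # floor so clean fields are not eroded), iterated to a fixed point
    floor = 0.05
    while True:
        if valid.sum() < 2:
            break
        mu_u, mu_v = U[valid].mean(), V[valid].mean()
        sd_u, sd_v = U[valid].std(), V[valid].std()
        k = thresholds.std_threshold
        bad = valid & ((np.abs(U - mu_u) > k * sd_u + floor)
                       | (np.abs(V - mu_v) > k * sd_v + floor))
        if not bad.any():
            break
        valid[bad] = False
        reason[bad] = 5

    return FlowGrid(x=grid.x, y=grid.y, u=U, v=V, snr=grid.snr, valid=valid,
                    reason=reason, window=grid.window, dt=grid.dt,
                    pixel_size=grid.pixel_size)
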