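"""Relaxation-model fitting on ROI-mean signal curves.

Three models are fitted, always to the mean signal over an ROI at each
echo/inversion time (not voxelwise), by Nelder-Mead simplex least squares:

* transverse decay  S(TE) = S0 * exp(-TE / T2) + C   (spin echo)
* the same with T2* in place of T2                    (gradient echo)
* Look-Locker recovery  S(TI) = A - B * exp(-TI / T1*),
  corrected to T1 = T1* * (B/A - 1).

The offset C absorbs the Rician magnitude-noise floor and is constrained
non-negative.  Frames corrupted by respiratory motion are detected from
their background (outside-body) signal energy, which ghosting elevates,
and excluded before fitting.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .core import ImageSeries, SignalCurve

#: simplex termination: absolute parameter / RSS changes below these
XATOL = 1e-10
FATOL = 1e-12
MAXITER = 5000


@dataclass
class RelaxationFit:
    """Result of one ROI fit.

    ``params`` is (s0, tau, c) for transverse models and (a, b, t1_star)
    for the Look-Locker model; ``t1_corrected`` is populated only for the
    latter.
    """

    model: str  # "t2" | "t2star" | "t1_look_locker"
    params: tuple[float, ...]
    rss: float
    converged: bool
    n_used: int
    t1_corrected: float | None = None
    rejected: tuple[int, ...] = field(default_factory=tuple)
    identifiable: bool = True
    message: str = ""

    @property
    def tau(self) -> float:
        """The headline time constant in ms (T2, T2*, or corrected T1)."""
        if self.model == "t1_look_locker":
            return float("nan") if self.t1_corrected is None else self.t1_corrected
        return self.params[1]


# ---------------------------------------------------------------------------
# models


def transverse_model(te, s0, tau, c):
    """Monoexponential decay with noise-floor offset: s0*exp(-te/tau) + c."""
    if np.any(np.asarray(tau) <= 0):
        raise ValueError("tau must be > 0")
    return s0 * np.exp(-np.asarray(te, dtype=float) / tau) + c


def look_locker_model(ti, a, b, t1_star, magnitude: bool = False):
    """Three-parameter inversion recovery: a - b*exp(-ti/t1_star)."""
    if t1_star <= 0:
        raise ValueError("t1_star must be > 0")
    s = a - b * np.exp(-np.asarray(ti, dtype=float) / t1_star)
    return np.abs(s) if magnitude else s


def correct_t1(a: float, b: float, t1_star: float) -> float:
    """Correct the apparent (saturated) T1* to true T1: T1 = T1*(B/A - 1).

    Equals T1* exactly when B = 2A (perfect inversion, no readout
    saturation); B/A <= 1 is unphysical for inversion recovery.
    """
    if a == 0 or b / a <= 1:
        raise ValueError(f"non-physical Look-Locker amplitudes: B/A = {b / a if a else np.inf:.4g} <= 1")
    return t1_star * (b / a - 1.0)


# ---------------------------------------------------------------------------
# fitting


def _simplex(objective, x0):
    opts = {"xatol": XATOL, "fatol": FATOL, "maxiter": MAXITER, "maxfev": 4 * MAXITER}
    res = minimize(objective, x0, method="Nelder-Mead", options=opts)
    if not res.success:  # one restart from the stalled point re-expands the simplex
        res = minimize(objective, res.x, method="Nelder-Mead", options=opts)
    return res


def _loglinear_init(t, v):
    """Deterministic start for transverse fits: log-linear regression on the
    offset-subtracted signal."""
    c0 = float(np.min(v))
    y = v - c0
    pos = y > max(1e-12, 1e-6 * np.max(np.abs(v)))
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
        s00 = float(np.exp(intercept))
    else:
        tau0 = (t[-1] - t[0]) / 3.0
        s00 = float(np.max(v) - c0)
    tau0 = float(np.clip(tau0, 1e-3, 100 * (t[-1] - t[0] + t[0])))
    return max(s00, 1e-6), tau0, max(c0, 0.0)


def fit_transverse(curve: SignalCurve, model: str = "t2") -> RelaxationFit:
    """Fit (s0, tau, c) to an ROI-mean decay curve by simplex least squares.

    tau > 0 and c >= 0 are enforced by reflection (the objective is
    evaluated at |tau|, |c|); initialization is the log-linear regression
    start, so fits are deterministic.
    """
    if model not in ("t2", "t2star"):
        raise ValueError("model must be 't2' or 't2star'")
    t, v = curve.usable_points()
    if t.size < 4:
        raise ValueError(f"need >= 4 usable points, have {t.size}")
    if np.any(t < 0):
        raise ValueError("negative echo times")
    if np.ptp(v) == 0:
        raise ValueError("flat signal curve: all values equal, decay model unidentifiable")

    def objective(p):
        s0, tau, c = abs(p[0]), abs(p[1]), abs(p[2])
        if tau < 1e-12:
            return np.inf
        r = s0 * np.exp(-t / tau) + c - v
        return float(r @ r)

    x0 = np.array(_loglinear_init(t, v))
    res = _simplex(objective, x0)
    s0, tau, c = (abs(float(x)) for x in res.x)
    # identifiability: the decaying component must clear the residual noise
    # at the first sampled time, and the fitted S0 must stay within a sane
    # extrapolation bound — with only one echo above the noise floor the
    # optimizer can match it with an arbitrarily steep decay and absurd S0
    resid_rms = np.sqrt(res.fun / t.size)
    amp = s0 * np.exp(-t[0] / tau)
    identifiable = bool(
        amp >= 5.0 * max(resid_rms, 1e-12)
        and s0 <= 1e3 * float(np.max(np.abs(v)))
    )
    msg = res.message
    if tau < t[0]:
        msg = f"tau {tau:.3g} ms below first sampling time {t[0]:.3g} ms; " + msg
    if not identifiable:
        msg = "non-identifiable: decay amplitude below noise at first sample; " + msg
    return RelaxationFit(
        model=model,
        params=(s0, tau, c),
        rss=float(res.fun),
        converged=bool(res.success),
        n_used=int(t.size),
        rejected=curve.rejected,
        identifiable=identifiable,
        message=msg,
    )


def _restore_sign(values: np.ndarray, k: int) -> np.ndarray:
    out = values.copy()
    out[:k] = -out[:k]
    return out


def fit_look_locker(curve: SignalCurve, magnitude: bool = True) -> RelaxationFit:
    """Fit (a, b, t1_star) to a Look-Locker recovery curve and correct T1.

    Magnitude data (the scanner default) lose the sign of the early,
    inverted samples; candidate sign restorations around the signal minimum
    are fitted and the lowest-RSS solution kept.  An optimum with
    B/A <= 1 is flagged non-physical (converged=False, no corrected T1).
    """
    t, v = curve.usable_points()
    if t.size < 5:
        raise ValueError(f"need >= 5 usable points after rejection, have {t.size}")

    def fit_signed(vs):
        a0 = float(vs[-1])
        x0 = np.array([a0, 2.0 * a0, float(np.median(t))])

        def objective(p):
            a, b, t1s = p[0], p[1], abs(p[2])
            if t1s < 1e-9:
                return np.inf
            r = a - b * np.exp(-t / t1s) - vs
            return float(r @ r)

        return _simplex(objective, x0)

    if magnitude:
        kmin = int(np.argmin(v))
        candidates = sorted({max(kmin - 1, 0), kmin, min(kmin + 1, t.size - 1), min(kmin + 2, t.size)})
    else:
        candidates = [0]
    best, best_k = None, 0
    for k in candidates:
        res = fit_signed(_restore_sign(v, k) if magnitude else v)
        if best is None or res.fun < best.fun:
            best, best_k = res, k
    a, b, t1_star = float(best.x[0]), float(best.x[1]), abs(float(best.x[2]))
    converged = bool(best.success)
    t1c: float | None = None
    msg = best.message
    if a <= 0 or b / a <= 1:
        converged = False
        msg = f"non-physical optimum (B/A = {b / a if a else np.inf:.4g} <= 1); " + msg
    else:
        t1c = correct_t1(a, b, t1_star)
    return RelaxationFit(
        model="t1_look_locker",
        params=(a, b, t1_star),
        rss=float(best.fun),
        converged=converged,
        n_used=int(t.size),
        t1_corrected=t1c,
        rejected=curve.rejected,
        message=msg,
    )


# ---------------------------------------------------------------------------
# ROI extraction and motion-frame rejection


def estimate_noise_sigma(series: ImageSeries, background_mask: np.ndarray) -> float:
    """Channel noise scale from a signal-free region of magnitude data.

    For pure noise the Rician magnitude satisfies E[M^2] = 2 sigma^2, so
    sigma = sqrt(mean(M^2) / 2) over the background voxels of all frames.
    """
    bg = np.asarray(background_mask, dtype=bool)
    if not bg.any():
        raise ValueError("background region is empty")
    return float(np.sqrt((series.data[bg, :] ** 2).mean() / 2.0))


def extract_roi_curve(
    series: ImageSeries,
    mask: np.ndarray,
    restrict: np.ndarray | None = None,
    rejected=(),
    noise_sigma: float | None = None,
) -> SignalCurve:
    """Mean signal over the ROI at each frame time.

    ``restrict`` (e.g. a septal wedge for cardiac T2*) is intersected with
    the mask before averaging.

    With ``noise_sigma`` given, the Rician noise-floor bias of magnitude
    data is removed via the second moment, E[M^2] = S^2 + 2 sigma^2: each
    frame value becomes sqrt(max(mean(M^2) - 2 sigma^2, 0)).  This is the
    pipeline's standard path for short time constants, where the plain
    magnitude mean flattens the decay tail and biases tau low.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.data.shape[:2]:
        raise ValueError("mask shape does not match series grid")
    if restrict is not None:
        mask = mask & np.asarray(restrict, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("empty ROI (mask or septal intersection selects no voxels)")
    roi = series.data[mask, :]
    if noise_sigma is None:
        values = roi.mean(axis=0)
    else:
        values = np.sqrt(np.maximum((roi**2).mean(axis=0) - 2.0 * noise_sigma**2, 0.0))
    return SignalCurve(series.times, values, n_voxels=n, rejected=tuple(rejected))


def reject_corrupted_frames(
    series: ImageSeries,
    body_mask: np.ndarray,
    k: float = 5.0,
) -> tuple[tuple[int, ...], np.ndarray]:
    """Detect motion-ghosted frames from phase-encode background energy.

    Ghosting replicates tissue signal along the phase-encode direction,
    so the score is the mean squared signal in the background voxels that
    share image columns with the body (the "ghost band"); corruption
    elevates it, while background outside the band sees almost nothing.
    Frames scoring above median + k * (1.4826 * MAD) are rejected, where
    the MAD is taken one-sided over the scores at or below the median so
    the spread estimate is immune to the very outliers being tested for;
    the 1.4826 constant makes k a Gaussian-sigma threshold.
    Returns (rejected indices, scores).
    """
    if series.n_frames < 3:
        raise ValueError("need >= 3 frames for rejection statistics")
    body = np.asarray(body_mask, dtype=bool)
    bg = ~body
    if not bg.any():
        raise ValueError("background region is empty")
    cols = body.any(axis=0)
    band = bg & cols[None, :]
    if not band.any():  # body spans no columns (or all): fall back to full bg
        band = bg
    scores = (series.data[band, :] ** 2).mean(axis=0)
    med = float(np.median(scores))
    low = med - scores[scores <= med]
    mad = float(np.median(low))
    if mad == 0:
        warnings.warn("zero MAD of background-energy scores; no frames rejected")
        return (), scores
    rejected = tuple(int(i) for i in np.nonzero(scores > med + k * 1.4826 * mad)[0])
    return rejected, scores
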