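"""Relaxation-time to dry-tissue-iron calibration.

The calibration is the standard single-constant reciprocal form

    iron = K_dry * (1/tau - 1/tau0)

where tau is the measured T2 or T2* (ms), tau0 is the relaxation time of
non-loaded tissue (taken as the mean of the non-loaded control group, a
fixed input rather than a fitted parameter), and K_dry (mg/g per ms^-1)
is fitted by least squares in iron space.  Because the model is linear
through the origin in x = 1/tau - 1/tau0, the fit is closed form.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CalibrationModel:
    mode: str  # "t2" | "t2star"
    tau0: float  # ms
    k_dry: float  # mg/g per ms^-1
    fit_pairs: tuple[tuple[float, float], ...] = field(default_factory=tuple)
    rss: float = 0.0

    def __post_init__(self):
        if self.mode not in ("t2", "t2star"):
            raise ValueError("mode must be 't2' or 't2star'")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
        if self.k_dry < 0:
            raise ValueError("k_dry must be >= 0")


def fit_calibration(pairs, tau0: float, mode: str = "t2star") -> CalibrationModel:
    """Least-squares K_dry for iron = K_dry * (1/tau - 1/tau0).

    ``pairs`` is an iterable of (tau ms, iron mg/g dry); ``tau0`` is the
    externally supplied baseline (non-loaded group mean).  The minimizer
    of sum (k*x_i - iron_i)^2 with x = 1/tau - 1/tau0 is
    k = sum(x*iron) / sum(x^2).
    """
    pairs = [(float(t), float(fe)) for t, fe in pairs]
    if len(pairs) < 2:
        raise ValueError("need >= 2 (tau, iron) pairs")
    tau = np.array([p[0] for p in pairs])
    iron = np.array([p[1] for p in pairs])
    if np.any(tau <= 0):
        raise ValueError("all tau must be > 0")
    x = 1.0 / tau - 1.0 / tau0
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("degenerate calibration: all tau equal tau0 (x = 0)")
    k = float(x @ iron) / sxx
    k = max(k, 0.0)
    rss = float(np.sum((k * x - iron) ** 2))
    return CalibrationModel(mode=mode, tau0=float(tau0), k_dry=k, fit_pairs=tuple(pairs), rss=rss)


def predict_iron(model: CalibrationModel, tau) -> np.ndarray | float:
    """Predicted dry-tissue iron (mg/g) at relaxation time ``tau`` (ms).

    Predictions for tau > tau0 are clamped at zero with a warning (longer
    relaxation than the non-loaded baseline carries no iron information).
    """
    scalar = np.isscalar(tau)
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0")
    pred = model.k_dry * (1.0 / tau - 1.0 / model.tau0)
    if np.any(pred < 0):
        warnings.warn("tau exceeds tau0; predicted iron clamped at 0")
        pred = np.maximum(pred, 0.0)
    return float(pred[0]) if scalar else pred


def invert_calibration(model: CalibrationModel, iron) -> np.ndarray | float:
    """Relaxation time at a given iron concentration: tau = 1/(iron/K + 1/tau0).

    Exact algebraic inverse of ``predict_iron`` for iron >= 0.
    """
    scalar = np.isscalar(iron)
    iron = np.atleast_1d(np.asarray(iron, dtype=float))
    if np.any(iron < 0):
        raise ValueError("iron must be >= 0")
    if model.k_dry == 0 and np.any(iron > 0):
        raise ValueError("k_dry = 0: no tau maps to iron > 0")
    with np.errstate(divide="ignore"):
        tau = 1.0 / (iron / model.k_dry + 1.0 / model.tau0) if model.k_dry else np.full_like(iron, model.tau0)
    return float(tau[0]) if scalar else tau


def save_calibration(model: CalibrationModel, path) -> None:
    """Persist as a small plain-text key: value file."""
    lines = [
        f"mode: {model.mode}",
        f"tau0_ms: {model.tau0!r}",
        f"k_dry: {model.k_dry!r}",
        f"n_pairs: {len(model.fit_pairs)}",
        f"rss: {model.rss!r}",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_calibration(path) -> CalibrationModel:
    kv = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                key, val = line.split(":", 1)
                kv[key.strip()] = val.strip()
    return CalibrationModel(
        mode=kv["mode"],
        tau0=float(kv["tau0_ms"]),
        k_dry=float(kv["k_dry"]),
        rss=float(kv.get("rss", 0.0)),
    )
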