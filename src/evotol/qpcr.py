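"""Mechanistic quantification of qPCR amplification curves (MAK2 model).

MAK2 describes amplification with two parameters: the initial target amount
D0 (in fluorescence units) and a characteristic PCR constant k.  The
fluorescence after cycle n follows the recurrence

    F_0 = D0
    F_n = F_{n-1} + k * ln(1 + F_{n-1} / k)

which reduces to perfect doubling while F << k and saturates as F grows.
Fitting the recurrence to the pre-plateau portion of a raw amplification
curve yields D0 directly, without standard curves or cycle-threshold
heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "AmplificationCurve",
    "MAK2Fit",
    "mak2_forward",
    "fit_mak2",
    "normalize_expression",
]


@dataclass(frozen=True)
class AmplificationCurve:
    """Background-subtracted fluorescence per cycle for one well."""

    well: str
    cycles: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.cycles, dtype=int)
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "cycles", c)
        object.__setattr__(self, "fluorescence", f)
        if len(c) != len(f):
            raise ValueError("cycles and fluorescence must have equal length")
        if len(c) < 10:
            raise ValueError("an amplification curve needs at least 10 cycles")
        if np.any(np.diff(c) != 1):
            raise ValueError("cycles must be consecutive integers")


@dataclass(frozen=True)
class MAK2Fit:
    """Fitted MAK2 parameters for one curve."""

    well: str
    d0: float
    k: float
    window_last_cycle: int
    rss: float
    converged: bool
    no_amplification: bool = False


def mak2_forward(d0: float, k: float, n_cycles: int) -> np.ndarray:
    """Fluorescence trajectory of the MAK2 recurrence over ``n_cycles`` cycles.

    Returns the length-``n_cycles`` array (F_1 ... F_n); strictly increasing
    whenever d0 > 0, identically zero when d0 = 0.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if d0 < 0:
        raise ValueError("d0 must be nonnegative")
    out = np.empty(n_cycles, dtype=float)
    f = float(d0)
    for i in range(n_cycles):
        f = f + k * np.log1p(f / k)
        out[i] = f
    return out


def fit_mak2(curve: AmplificationCurve, *, window_fraction: float = 0.85,
             noise_floor: float = 0.0, n_starts_d0: int = 7, n_starts_k: int = 4,
             xtol: float = 1e-12, ftol: float = 1e-12) -> MAK2Fit:
    """Fit (D0, k) to the pre-plateau region of an amplification curve.

    The fitted window runs from the first cycle up to (and including) the
    first cycle whose fluorescence exceeds ``window_fraction`` of the curve
    maximum, excluding the plateau where the recurrence no longer holds.
    A multistart nonlinear least squares over log-spaced (D0, k) initial
    values is used; the best residual sum of squares wins.

    A curve whose maximum does not exceed ``noise_floor`` is reported as
    no-amplification with D0 = 0 (no exception).
    """
    f = curve.fluorescence
    fmax = float(np.max(f))
    if fmax <= noise_floor or fmax <= 0:
        return MAK2Fit(curve.well, 0.0, float("nan"), int(curve.cycles[-1]), 0.0,
                       converged=True, no_amplification=True)
    cut = int(np.argmax(f >= window_fraction * fmax))
    y = f[: cut + 1]
    n = len(y)
    if n < 5:  # degenerate window; use everything
        y = f
        n = len(y)
        cut = n - 1

    def resid(logp):
        d0, k = np.exp(logp)
        return mak2_forward(d0, k, n) - y

    best = None
    for ld in np.linspace(np.log(fmax) - 20.0, np.log(fmax) - 4.0, n_starts_d0):
        for lk in np.linspace(np.log(fmax) - 2.0, np.log(fmax) + 2.0, n_starts_k):
            try:
                sol = least_squares(resid, x0=[ld, lk], xtol=xtol, ftol=ftol, gtol=1e-14)
            except Exception:
                continue
            rss = float(2.0 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol)
    if best is None:
        return MAK2Fit(curve.well, float("nan"), float("nan"),
                       int(curve.cycles[cut]), float("nan"), converged=False)
    rss, sol = best
    d0, k = np.exp(sol.x)
    return MAK2Fit(curve.well, float(d0), float(k), int(curve.cycles[cut]),
                   rss, converged=bool(sol.success))


def normalize_expression(d0_target: float, d0_reference: float) -> float:
    """Target D0 divided by a reference gene's D0 (relative expression)."""
    if d0_reference <= 0:
        return float("nan")
    return d0_target / d0_reference
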