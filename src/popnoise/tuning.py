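"""Double von Mises tuning-curve fits, OSI, and preferred-orientation tools.

The tuning model is the sum of two von Mises bumps constrained to lie 180
degrees apart, scaled by a free amplitude, plus a baseline:

    f(x) = A * [vM(x; t1, k1) + vM(x; t1 + 180, k2)] + mu

(the amplitude is required for the density-normalized von Mises terms to
reach firing rates well above 1 Hz). Goodness of fit is the coefficient of
determination (R^2) between fitted and observed condition means; units with
gof > 0.6 are retained for OSI analysis.

OSI = (R_optimal - R_orthogonal) / (R_optimal + R_orthogonal), where
R_optimal averages the fitted curve at the optimal and null directions and
R_orthogonal averages it at the two orthogonal directions. Reported as a
fraction in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .simulate import tuning_rate


@dataclass(frozen=True)
class TuningFit:
    """Fitted tuning-curve parameters and derived selectivity measures."""

    theta1_deg: float
    theta2_deg: float
    k1: float
    k2: float
    mu: float
    amplitude: float
    gof: float
    r_optimal: float
    r_orthogonal: float
    r_orthogonal_plus: float
    r_orthogonal_minus: float
    osi: float
    preferred_orientation_deg: float
    converged: bool = True

    def evaluate(self, direction_deg: float) -> float:
        """Fitted curve at one direction (Hz)."""
        return tuning_rate(
            direction_deg, self.theta1_deg, self.theta2_deg,
            self.k1, self.k2, self.mu, self.amplitude,
        )


def _model(x_rad: np.ndarray, t1: float, k1: float, k2: float, mu: float, amp: float) -> np.ndarray:
    from scipy.special import i0

    vm1 = np.exp(k1 * np.cos(x_rad - t1)) / (2.0 * np.pi * i0(k1))
    vm2 = np.exp(k2 * np.cos(x_rad - t1 - np.pi)) / (2.0 * np.pi * i0(k2))
    return amp * (vm1 + vm2) + mu


def _finish(t1_deg: float, k1: float, k2: float, mu: float, amp: float,
            gof: float, converged: bool = True) -> TuningFit:
    t1_deg = float(t1_deg) % 360.0
    t2_deg = (t1_deg + 180.0) % 360.0
    f = lambda d: tuning_rate(d, t1_deg, t2_deg, k1, k2, mu, amp)  # noqa: E731
    r_opt = 0.5 * (f(t1_deg) + f(t2_deg))
    r_plus = f(t1_deg + 90.0)
    r_minus = f(t1_deg - 90.0)
    r_orth = 0.5 * (r_plus + r_minus)
    osi = (r_opt - r_orth) / (r_opt + r_orth) if (r_opt + r_orth) > 0 else np.nan
    return TuningFit(
        theta1_deg=t1_deg,
        theta2_deg=t2_deg,
        k1=float(k1),
        k2=float(k2),
        mu=float(mu),
        amplitude=float(amp),
        gof=float(gof),
        r_optimal=float(r_opt),
        r_orthogonal=float(r_orth),
        r_orthogonal_plus=float(r_plus),
        r_orthogonal_minus=float(r_minus),
        osi=float(osi),
        preferred_orientation_deg=t1_deg % 180.0,
        converged=converged,
    )


def fit_double_von_mises(directions_deg, mean_rates) -> TuningFit:
    """Least-squares fit of the double von Mises model to condition means.

    Multi-start over initial ``theta1`` at the observed argmax direction and
    +/-30 degrees; the best (lowest residual) restart wins. Flat curves get
    the ``k1 = k2 = 0, gof = 0`` convention; if no restart converges the fit
    is flagged with ``gof = -inf``.
    """
    x_deg = np.asarray(directions_deg, dtype=float)
    y = np.asarray(mean_rates, dtype=float)
    if x_deg.size != y.size:
        raise ValueError("directions and rates must have equal length")
    if np.unique(x_deg % 360.0).size < 6:
        raise ValueError("need >= 6 distinct directions")
    if np.any(y < 0):
        raise ValueError("rates must be >= 0")

    if np.ptp(y) == 0:
        return _finish(float(x_deg[0]), 0.0, 0.0, float(y[0]), 0.0, gof=0.0)

    x_rad = np.deg2rad(x_deg)
    sst = float(np.sum((y - y.mean()) ** 2))

    def residuals(p):
        t1, k1, k2, mu, amp = p
        return _model(x_rad, t1, k1, k2, mu, amp) - y

    argmax_deg = float(x_deg[int(np.argmax(y))])
    amp0 = max(float(np.ptp(y)), 1e-3)
    mu0 = max(float(y.min()), 0.0)
    lower = [-np.inf, 0.0, 0.0, 0.0, 0.0]
    upper = [np.inf, 50.0, 50.0, np.inf, np.inf]

    best = None
    for dt in (0.0, 30.0, -30.0):
        p0 = [np.deg2rad(argmax_deg + dt), 2.0, 2.0, mu0, amp0]
        try:
            sol = least_squares(residuals, p0, bounds=(lower, upper), max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return _finish(argmax_deg, 0.0, 0.0, float(y.mean()), 0.0,
                       gof=-np.inf, converged=False)

    t1, k1, k2, mu, amp = best.x
    ssr = float(2.0 * best.cost)
    gof = 1.0 - ssr / sst if sst > 0 else 0.0
    return _finish(np.rad2deg(t1), k1, k2, mu, amp, gof=gof)


def osi_from_fit(fit: TuningFit) -> float:
    """Orientation selectivity index from a converged fit, in [0, 1]."""
    if not fit.converged:
        raise ValueError("fit did not converge")
    denom = fit.r_optimal + fit.r_orthogonal
    if denom <= 0:
        raise ValueError("OSI undefined: R_optimal + R_orthogonal <= 0")
    return (fit.r_optimal - fit.r_orthogonal) / denom


def osi_from_responses(directions_deg, mean_rates, theta1_deg: float) -> float:
    """OSI from raw condition means at the directions nearest theta1 and its
    null/orthogonal counterparts (alternative to fitted-curve evaluation)."""
    x = np.asarray(directions_deg, dtype=float) % 360.0
    y = np.asarray(mean_rates, dtype=float)

    def nearest(target):
        d = np.abs((x - target + 180.0) % 360.0 - 180.0)
        return y[int(np.argmin(d))]

    r_opt = 0.5 * (nearest(theta1_deg) + nearest(theta1_deg + 180.0))
    r_orth = 0.5 * (nearest(theta1_deg + 90.0) + nearest(theta1_deg - 90.0))
    denom = r_opt + r_orth
    if denom <= 0:
        raise ValueError("OSI undefined: R_optimal + R_orthogonal <= 0")
    return float((r_opt - r_orth) / denom)


def apply_gof_filter(fits: list[TuningFit], threshold: float = 0.6) -> list[TuningFit]:
    """Keep fits with goodness of fit strictly greater than ``threshold``."""
    return [f for f in fits if f.gof > threshold]


def delta_po(po_a_deg: float, po_b_deg: float) -> float:
    """Circular preferred-orientation difference, in [0, 90] degrees."""
    d = abs(po_a_deg - po_b_deg) % 180.0
    return min(d, 180.0 - d)
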