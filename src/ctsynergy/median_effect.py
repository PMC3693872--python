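"""Median-effect dose-response fitting.

The mass-action median-effect equation relates dose ``D`` to the fractions
affected/unaffected ``fa``/``fu``::

    fa / fu = (D / Dm) ** m

``Dm`` is the median-effect dose (the IC50: the dose giving fa = 0.5) and
``m`` the sigmoidicity of the curve (m = 1 hyperbolic, m > 1 sigmoidal).
Taking log10 of both sides gives the classic median-effect plot,
``log10(fa/fu) = m * log10(D) - m * log10(Dm)``, a straight line fit here
by ordinary least squares; its R² is the one conventionally reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ctsynergy.assay import DoseResponseTable
from ctsynergy.errors import InsufficientDataError, NonMonotoneResponseError

__all__ = ["MedianEffectFit", "fit_median_effect", "predict_fa", "dose_for_effect"]


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters.

    ``dm`` is in uM and equals the IC50; ``r2`` is the coefficient of
    determination of the linearized (log-log) fit; ``residuals`` are the
    log-domain residuals of that fit.
    """

    dm: float
    m: float
    r2: float | None = None
    n_points: int = 0
    residuals: tuple[float, ...] = field(default=())
    condition: str | None = None
    time: float | None = None

    def __post_init__(self):
        if not self.dm > 0:
            raise ValueError(f"dm must be > 0, got {self.dm}")
        if self.r2 is not None and not (0.0 <= self.r2 <= 1.0 + 1e-12):
            raise ValueError(f"r2 must lie in [0, 1], got {self.r2}")

    def predict_fa(self, dose: float) -> float:
        return predict_fa(self, dose)

    def dose_for_effect(self, fa: float) -> float:
        return dose_for_effect(self, fa)


def fit_median_effect(
    table: DoseResponseTable,
    pooling: str = "pooled-replicates",
    refine: bool = False,
) -> MedianEffectFit:
    """Fit the median-effect line by OLS on the log-transformed points.

    Regresses ``y = log10(fa / (1 - fa))`` on ``x = log10(D)`` over the
    nonzero doses; the slope is ``m`` and ``Dm = 10 ** (-intercept / m)``.
    With ``pooling='pooled-replicates'`` (default) every replicate
    contributes its own regression point; ``'replicate-means'`` regresses
    on per-dose mean fa instead.

    ``refine=True`` follows the linearized fit with nonlinear least
    squares on fa itself (initialized at the OLS solution).  The
    log-linearization is the classic reporting convention, but it
    amplifies noise at extreme fa; under additive absorbance noise the
    untransformed fit is the efficient estimator of (Dm, m).  The
    reported ``r2`` and ``residuals`` always refer to the linearized
    plot.

    Raises
    ------
    InsufficientDataError
        fewer than 2 distinct nonzero doses.
    NonMonotoneResponseError
        fitted slope <= 0 (response not increasing with dose).
    """
    doses, fas = table.fit_points(pooling)
    if len(set(doses)) < 2:
        raise InsufficientDataError(
            f"condition {table.condition!r}: need >= 2 distinct nonzero doses, got {len(set(doses))}"
        )
    x = np.log10(np.asarray(doses, dtype=float))
    fa = np.asarray(fas, dtype=float)
    y = np.log10(fa / (1.0 - fa))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise NonMonotoneResponseError(
            f"condition {table.condition!r}: median-effect slope {m:.4f} <= 0"
        )
    if m < 0.01:
        warnings.warn(
            f"condition {table.condition!r}: near-flat median-effect slope m={m:.4g}; "
            "Dm is poorly determined",
            stacklevel=2,
        )
    dm = float(10.0 ** (-res.intercept / m))
    r2 = float(res.rvalue**2)
    residuals = tuple((y - (res.slope * x + res.intercept)).tolist())
    if refine:
        dm, m = _refine_on_fa(x, fa, dm, m)
    return MedianEffectFit(
        dm=dm,
        m=m,
        r2=min(r2, 1.0),
        n_points=len(doses),
        residuals=residuals,
        condition=table.condition,
        time=table.time,
    )


def _refine_on_fa(log_dose: np.ndarray, fa: np.ndarray, dm0: float, m0: float) -> tuple[float, float]:
    """Nonlinear least squares of fa(D) = 1/(1 + (Dm/D)^m), log-parameterized."""
    from scipy.optimize import least_squares

    dose = 10.0**log_dose

    def resid(theta):
        dm, m = np.exp(theta)
        return 1.0 / (1.0 + (dm / dose) ** m) - fa

    sol = least_squares(resid, np.log([dm0, m0]), method="lm")
    dm, m = np.exp(sol.x)
    if not (dm > 0 and m > 0 and np.isfinite(dm)):
        return dm0, m0
    return float(dm), float(m)


def predict_fa(fit: MedianEffectFit, dose: float) -> float:
    """Fraction affected at a dose: ``fa = 1 / (1 + (Dm / D) ** m)``; fa(0) = 0."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    return 1.0 / (1.0 + (fit.dm / dose) ** fit.m)


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose producing effect level fa: ``Dx = Dm * (fa / (1 - fa)) ** (1 / m)``."""
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
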