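"""Distance and length dependence of end-to-end transfer rates.

Coherent mean transfer rates over homopolymer series are conventionally fit
with three laws: exponential in the traveled distance, k = k0 exp(-beta r)
with r = dx (N - 1); power law in the number of steps, k = k0' (N-1)^-eta;
and power law in the number of monomers, k = k0' N^-eta'.

Two fitting methods are provided.  ``method="linear"`` (default) is ordinary
nonlinear least squares on the rates themselves, which weights the fast
short-chain rates most — the convention under which the published exponent
values for this model were obtained.  ``method="log"`` is ordinary least
squares on ln k, which weights all chain lengths equally.  Exponent standard
errors come from the fit covariance in either case; both methods recover
exact-law synthetic data exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .parameters import ValidationError

__all__ = ["RateFit", "fit_exponential_distance", "fit_power_steps", "fit_power_N"]


@dataclass(frozen=True)
class RateFit:
    """Result of one rate-versus-length fit."""

    law: str                 # "exp_distance" | "power_steps" | "power_N"
    method: str              # "linear" | "log"
    exponent: float          # beta (1/Å) or eta / eta' (dimensionless)
    exponent_stderr: float
    prefactor: float         # k0 or k0', in the units of the input rates
    prefactor_stderr: float
    n_points: int
    residuals: np.ndarray    # log-space residuals of the fitted law

    def to_dict(self) -> dict:
        return {
            "law": self.law,
            "method": self.method,
            "exponent": self.exponent,
            "exponent_stderr": self.exponent_stderr,
            "prefactor": self.prefactor,
            "prefactor_stderr": self.prefactor_stderr,
            "n_points": self.n_points,
        }


def _validate(n_values, rates, min_n: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    n = np.asarray(n_values, dtype=float)
    k = np.asarray(rates, dtype=float)
    if n.shape != k.shape:
        raise ValidationError("n_values and rates must have the same length")
    if n.size < 3:
        raise ValidationError(f"need at least 3 points for a meaningful fit, got {n.size}")
    if np.any(k <= 0) or not np.all(np.isfinite(k)):
        raise ValidationError("all rates must be positive and finite")
    if np.any(n < min_n):
        raise ValidationError(f"fit requires N >= {min_n:g} for all points")
    return n, k


def _fit(x: np.ndarray, k: np.ndarray, law: str, method: str) -> RateFit:
    """Fit ln k = ln k0 - exponent * x by the requested method.

    ``x`` is the law's abscissa: r for the exponential law, ln(N-1) or ln N
    for the power laws — in this form every law is exponential in x and one
    routine serves all three.
    """
    log_k = np.log(k)
    if method == "log":
        res = stats.linregress(x, log_k)
        expo, se = -res.slope, res.stderr
        k0, k0_se = np.exp(res.intercept), np.exp(res.intercept) * res.intercept_stderr
    elif method == "linear":
        # scale to O(1) so the optimizer is well conditioned for rates ~1e13/s
        kscale = k.max()
        slope0, icept0 = np.polyfit(x, np.log(k / kscale), 1)
        popt, pcov = curve_fit(
            lambda xx, a, b: a * np.exp(-b * xx),
            x, k / kscale, p0=[np.exp(icept0), -slope0],
        )
        expo, se = popt[1], np.sqrt(pcov[1, 1])
        k0, k0_se = popt[0] * kscale, np.sqrt(pcov[0, 0]) * kscale
    else:
        raise ValidationError(f"method must be 'linear' or 'log', got {method!r}")
    resid = log_k - (np.log(k0) - expo * x)
    return RateFit(law=law, method=method, exponent=float(expo),
                   exponent_stderr=float(se), prefactor=float(k0),
                   prefactor_stderr=float(k0_se), n_points=int(x.size),
                   residuals=resid)


def fit_exponential_distance(n_values, rates, dx: float = 3.4,
                             method: str = "linear") -> RateFit:
    """Fit k = k0 exp(-beta r) with traveled distance r = dx (N - 1), Å.

    Returns beta in 1/Å with its standard error.
    """
    n, k = _validate(n_values, rates)
    return _fit(dx * (n - 1.0), k, "exp_distance", method)


def fit_power_steps(n_values, rates, method: str = "linear") -> RateFit:
    """Fit k = k0' (N-1)^-eta, with N-1 the number of base-pair steps."""
    n, k = _validate(n_values, rates, min_n=2)
    return _fit(np.log(n - 1.0), k, "power_steps", method)


def fit_power_N(n_values, rates, method: str = "linear") -> RateFit:
    """Fit k = k0' N^-eta' with the monomer count N as the size variable."""
    n, k = _validate(n_values, rates, min_n=2)
    return _fit(np.log(n), k, "power_N", method)
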