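"""Series computations over polymer length and sugar coupling.

These drive the length-dependence studies: end-to-end transfer rates
k_{alpha, 3N-1} over N = 2..10, their distance/power-law fits, and TWMF
trends versus N and t_S.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    expansion_coefficients,
    mean_probabilities_analytic,
    transfer_rates,
)
from .model import build_hamiltonian
from .parameters import ParameterSet, default_parameters, homopolymer_spec
from .rate_fits import RateFit, fit_exponential_distance, fit_power_N, fit_power_steps
from .spectral_content import twmf, wmf_per_site
from .spectrum import eigensystem

__all__ = [
    "end_to_end_rate",
    "end_to_end_rate_series",
    "fit_rate_series",
    "twmf_value",
    "twmf_table",
]


def _prepare(base: str, n: int, t_sugar: float, params: ParameterSet | None):
    p = (params or default_parameters()).with_t_sugar(t_sugar)
    h = build_hamiltonian(homopolymer_spec(base, n), p)
    return p, eigensystem(h)


def end_to_end_rate(
    base: str, n: int, t_sugar: float, alpha: int = 2,
    params: ParameterSet | None = None,
) -> float:
    """Mean transfer rate from site alpha to the last base pair (3N-1), 1/s."""
    p, es = _prepare(base, n, t_sugar, params)
    coeffs = expansion_coefficients(es, alpha)
    beta = 3 * n - 1
    means = mean_probabilities_analytic(es, coeffs)
    rates = transfer_rates(es, coeffs, alpha, p, means=means)
    return float(rates.rates[beta - 1])


def end_to_end_rate_series(
    base: str, n_values: Iterable[int], t_sugar: float, alpha: int = 2,
    params: ParameterSet | None = None,
) -> np.ndarray:
    """k_{alpha, 3N-1} for each N in ``n_values``, 1/s."""
    return np.array([end_to_end_rate(base, n, t_sugar, alpha, params)
                     for n in n_values])


def fit_rate_series(
    base: str = "G",
    n_values: Sequence[int] = tuple(range(2, 11)),
    t_sugar: float = 0.1,
    alpha: int = 2,
    dx: float = 3.4,
    params: ParameterSet | None = None,
) -> dict[str, RateFit]:
    """End-to-end rates over a homopolymer series plus all three length fits."""
    n = np.asarray(list(n_values))
    k = end_to_end_rate_series(base, n, t_sugar, alpha, params)
    return {
        "exp_distance": fit_exponential_distance(n, k, dx=dx),
        "power_steps": fit_power_steps(n, k),
        "power_N": fit_power_N(n, k),
    }


def twmf_value(
    base: str, n: int, t_sugar: float, alpha: int = 2,
    params: ParameterSet | None = None,
) -> float:
    """TWMF in Hz for one homopolymer / coupling / initial-site combination."""
    p, es = _prepare(base, n, t_sugar, params)
    coeffs = expansion_coefficients(es, alpha)
    means = mean_probabilities_analytic(es, coeffs)
    return twmf(wmf_per_site(es, coeffs, p), means)


def twmf_table(
    base: str,
    n_values: Iterable[int],
    ts_values: Iterable[float],
    alphas: Iterable[int] = (2, 3),
    params: ParameterSet | None = None,
) -> pd.DataFrame:
    """Long-format TWMF table over (t_S, N, alpha), frequencies in THz."""
    rows = []
    for ts in ts_values:
        for n in n_values:
            for alpha in alphas:
                rows.append({
                    "ts_ev": ts, "n_monomers": n, "alpha": alpha,
                    "twmf_thz": twmf_value(base, n, ts, alpha, params) / 1e12,
                })
    return pd.DataFrame(rows)
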