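"""Frequency content of the coherent carrier oscillations.

Every pair of eigenvalues (E_k, E_k') contributes an oscillation at
f_kk' = (E_k - E_k')/h to the site probabilities, with one-sided Fourier
amplitude 2 |C_k v_{beta k} C_k' v_{beta k'}| at site beta.  The Weighted
Mean Frequency (WMF) of a site is the weight-averaged frequency of these
lines, and the Total WMF (TWMF) weights each site's WMF by its mean
probability — a single number measuring how fast the hole sloshes through
the polymer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import mean_probabilities_analytic
from .parameters import ParameterSet, ValidationError
from .spectrum import EigenSystem

__all__ = [
    "SpectralContent",
    "oscillation_frequencies",
    "fourier_amplitudes",
    "wmf",
    "wmf_per_site",
    "twmf",
    "fft_crosscheck",
    "spectral_content",
]


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    """(k, k') index arrays over all pairs with k > k'."""
    kp, k = np.triu_indices(n, k=1)  # triu rows < cols, so kp < k
    return k, kp


def oscillation_frequencies(
    eigenvalues: np.ndarray, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise frequencies f_kk' = (E_k - E_k')/h over all k > k'.

    Returns ``(k_idx, kp_idx, f_hz)`` with 0-based eigenvalue indices.
    Degenerate pairs yield f = 0; with m distinct eigenvalues there are at
    most m(m-1)/2 distinct nonzero frequencies.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    k, kp = _pair_indices(ev.size)
    return k, kp, (ev[k] - ev[kp]) / params.planck_h


def fourier_amplitudes(
    es: EigenSystem, coeffs: np.ndarray, beta: int, params: ParameterSet
) -> tuple[np.ndarray, np.ndarray, float]:
    """Analytic one-sided amplitude spectrum of |C_beta(t)|^2.

    Returns ``(f_hz, amplitudes, dc)``: a line of amplitude
    2 |C_k v_{beta k} C_k' v_{beta k'}| at every pairwise frequency, plus the
    DC weight sum_k C_k^2 v_{beta k}^2.
    """
    w = np.asarray(coeffs) * es.eigenvectors[beta - 1, :]
    k, kp, f = oscillation_frequencies(es.eigenvalues, params)
    amp = 2.0 * np.abs(w[k] * w[kp])
    dc = float((w**2).sum())
    return f, amp, dc


def wmf(
    es: EigenSystem,
    coeffs: np.ndarray,
    beta: int,
    params: ParameterSet,
    exclude_degenerate: bool = False,
) -> float:
    """Weighted Mean Frequency of site beta, Hz.

    The weight of each pair k > k' is |C_k v_{beta k} C_k' v_{beta k'}|.  By
    default degenerate (zero-frequency) pairs are kept in the sum, entering
    the denominator with f = 0; ``exclude_degenerate=True`` drops them from
    both sums.  A site with zero total weight has WMF = 0 by convention.
    """
    f, amp, _ = fourier_amplitudes(es, coeffs, beta, params)
    weight = 0.5 * amp
    if exclude_degenerate:
        keep = f > 0.0
        f, weight = f[keep], weight[keep]
    total = weight.sum()
    if total == 0.0:
        return 0.0
    return float((weight * f).sum() / total)


def wmf_per_site(
    es: EigenSystem,
    coeffs: np.ndarray,
    params: ParameterSet,
    exclude_degenerate: bool = False,
) -> np.ndarray:
    """WMF for every site, Hz (vectorized over sites)."""
    w = es.eigenvectors * np.asarray(coeffs)[None, :]
    k, kp, f = oscillation_frequencies(es.eigenvalues, params)
    weights = np.abs(w[:, k] * w[:, kp])       # (3N, n_pairs)
    if exclude_degenerate:
        weights = weights[:, f > 0.0]
        f = f[f > 0.0]
    totals = weights.sum(axis=1)
    out = np.zeros(es.n_sites)
    nz = totals > 0.0
    out[nz] = (weights[nz] @ f) / totals[nz]
    return out


def twmf(wmf_sites: np.ndarray, mean_probabilities: np.ndarray) -> float:
    """Total WMF: per-site WMFs weighted by mean site probabilities, Hz."""
    return float(np.asarray(wmf_sites) @ np.asarray(mean_probabilities))


@dataclass(frozen=True)
class SpectralContent:
    """Frequency-domain summary of one dynamics run."""

    pair_k: np.ndarray
    pair_kp: np.ndarray
    frequencies_hz: np.ndarray
    amplitudes_per_site: np.ndarray   # (3N, n_pairs), 2|C v C' v'|
    wmf_per_site_hz: np.ndarray
    twmf_hz: float


def spectral_content(
    es: EigenSystem,
    coeffs: np.ndarray,
    params: ParameterSet,
    mean_probabilities: np.ndarray | None = None,
    exclude_degenerate: bool = False,
) -> SpectralContent:
    """Assemble the full frequency-domain characterization of a run."""
    if mean_probabilities is None:
        mean_probabilities = mean_probabilities_analytic(es, coeffs)
    w = es.eigenvectors * np.asarray(coeffs)[None, :]
    k, kp, f = oscillation_frequencies(es.eigenvalues, params)
    amps = 2.0 * np.abs(w[:, k] * w[:, kp])
    wmfs = wmf_per_site(es, coeffs, params, exclude_degenerate=exclude_degenerate)
    return SpectralContent(
        pair_k=k,
        pair_kp=kp,
        frequencies_hz=f,
        amplitudes_per_site=amps,
        wmf_per_site_hz=wmfs,
        twmf_hz=twmf(wmfs, mean_probabilities),
    )


def fft_crosscheck(
    probability_trace: np.ndarray, time_step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Numerical one-sided amplitude spectrum of a uniformly sampled trace.

    Returns ``(f_hz, amplitude)`` with the DC line at f = 0; dominant peaks
    should match the analytic lines of the eigenpair spectrum within one
    frequency bin.  Raises for a non-positive time step.
    """
    if time_step <= 0:
        raise ValidationError(f"time_step must be positive, got {time_step}")
    trace = np.asarray(probability_trace, dtype=float)
    n = trace.size
    if n < 2:
        raise ValidationError("trace must contain at least two samples")
    spec = np.fft.rfft(trace)
    freqs = np.fft.rfftfreq(n, d=time_step)
    amp = np.abs(spec) / n
    amp[1:] *= 2.0  # fold negative frequencies into the one-sided amplitude
    return freqs, amp
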