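"""Coherent time evolution of a hole created at one site of the fishbone.

A hole injected at site alpha (oxidation) evolves unitarily under the FWM
Hamiltonian.  Everything is evaluated analytically from the eigendecomposition
— the amplitude at site beta is

    C_beta(t) = sum_k C_k v_{beta k} exp(-i E_k t / hbar),   C_k = v_{alpha k},

so site probabilities |C_beta(t)|^2, their time averages, first-crossing
times, mean transfer rates k_{alpha beta} = <|C_beta|^2> / t_{alpha beta},
and dipole-moment traces all come from sums over eigenpairs; no ODE
integration is performed anywhere.

Time averages are degeneracy-aware: pairs of degenerate eigenvalues oscillate
at zero frequency, so their cross terms survive the average.  For an N-monomer
homopolymer these zero-frequency terms are what make the closed-form monomer
sums (psi, chi, omega, phi below) independent of the sugar coupling t_S.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .model import FishboneHamiltonian, SiteIndexMap
from .parameters import BOHR_PER_ANGSTROM, ParameterSet, ValidationError
from .spectrum import EigenSystem, eigensystem

__all__ = [
    "InitialCondition",
    "DynamicsResult",
    "TransferRates",
    "MonomerSums",
    "expansion_coefficients",
    "site_probabilities",
    "mean_probabilities_analytic",
    "mean_probabilities_numeric",
    "predicted_monomer_sums",
    "first_crossing_time",
    "transfer_rates",
    "dipole_moment",
    "default_time_grid",
    "simulate",
    "monomer_probability_sums",
]

#: Mean probabilities below this are treated as exactly zero (site unreachable).
UNREACHABLE_TOL = 1e-13


@dataclass(frozen=True)
class InitialCondition:
    """Hole created at site ``alpha`` (1-based): C_alpha(0)=1, all others 0."""

    alpha: int

    def validate(self, n_sites: int) -> None:
        if not 1 <= self.alpha <= n_sites:
            raise ValidationError(
                f"initial site alpha={self.alpha} out of range 1..{n_sites}"
            )


def expansion_coefficients(es: EigenSystem, initial: InitialCondition | int) -> np.ndarray:
    """Eigenbasis coefficients C_k for a hole created at one site.

    For the delta initial condition these are simply row alpha of the
    eigenvector matrix.
    """
    init = initial if isinstance(initial, InitialCondition) else InitialCondition(initial)
    init.validate(es.n_sites)
    return es.eigenvectors[init.alpha - 1, :].copy()


def _weights(es: EigenSystem, coeffs: np.ndarray) -> np.ndarray:
    """w[beta, k] = C_k v_{beta k}: the pair weights of the eigenexpansion."""
    return es.eigenvectors * np.asarray(coeffs)[None, :]


def site_probabilities(
    es: EigenSystem, coeffs: np.ndarray, times: np.ndarray, params: ParameterSet
) -> np.ndarray:
    """|C_beta(t)|^2 for every site on the requested time grid (seconds).

    Returns an array of shape (3N, n_times); each column sums to 1.
    """
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValidationError("time grid must not be empty")
    w = _weights(es, coeffs)
    phases = np.exp(-1j * np.outer(es.eigenvalues / params.hbar, times))
    amp = w @ phases
    return (amp.real**2 + amp.imag**2)


def mean_probabilities_analytic(es: EigenSystem, coeffs: np.ndarray) -> np.ndarray:
    """Degeneracy-aware closed-form time averages <|C_beta(t)|^2>.

    Only zero-frequency terms survive: within each degeneracy class g the
    cross terms persist, so the mean is sum_g (sum_{k in g} C_k v_{beta k})^2.
    With no degeneracies this reduces to sum_k C_k^2 v_{beta k}^2.
    """
    w = _weights(es, coeffs)
    mean = np.zeros(es.n_sites)
    for cls in es.degeneracy_classes:
        mean += w[:, list(cls)].sum(axis=1) ** 2
    return mean


def _frequency_extrema(es: EigenSystem, params: ParameterSet) -> tuple[float, float]:
    """(f_min, f_max) over nonzero pairwise frequencies, Hz; (0, 0) if none."""
    reps = np.array([es.eigenvalues[c[0]] for c in es.degeneracy_classes])
    if reps.size < 2:
        return 0.0, 0.0
    f_max = (reps[-1] - reps[0]) / params.planck_h
    f_min = np.diff(reps).min() / params.planck_h
    return float(f_min), float(f_max)


def default_time_grid(
    es: EigenSystem,
    params: ParameterSet,
    periods: float = 200.0,
    steps_per_fast_period: int = 40,
    max_samples: int = 200_000,
) -> np.ndarray:
    """Uniform grid resolving the fastest oscillation over ``periods`` slow periods.

    Step is 1/(steps_per_fast_period * f_max); total span covers ``periods``
    periods of the smallest nonzero pairwise frequency, capped at
    ``max_samples`` points.  A fully degenerate spectrum (constant dynamics)
    yields a short arbitrary grid.
    """
    f_min, f_max = _frequency_extrema(es, params)
    if f_max == 0.0:
        return np.linspace(0.0, 1e-15, 32)
    dt = 1.0 / (steps_per_fast_period * f_max)
    n = int(min(max_samples, np.ceil(periods / f_min / dt) + 1))
    return dt * np.arange(max(n, 32))


def mean_probabilities_numeric(
    es: EigenSystem,
    coeffs: np.ndarray,
    params: ParameterSet,
    t_total: float | None = None,
    n_samples: int = 32768,
) -> np.ndarray:
    """Trapezoidal time average of |C_beta(t)|^2 over [0, t_total].

    Converges to :func:`mean_probabilities_analytic` as ``t_total`` grows;
    the default window spans 200 periods of the slowest nonzero oscillation.
    """
    f_min, f_max = _frequency_extrema(es, params)
    if t_total is None:
        t_total = 1e-15 if f_min == 0.0 else 200.0 / f_min
    if t_total <= 0:
        raise ValidationError(f"t_total must be positive, got {t_total}")
    times = np.linspace(0.0, t_total, n_samples)
    probs = site_probabilities(es, coeffs, times, params)
    return np.trapezoid(probs, times, axis=1) / t_total


class MonomerSums(NamedTuple):
    """Closed-form per-monomer mean-probability sums for a homopolymer."""

    first: float
    middle: float   # per middle monomer
    last: float
    per_monomer: np.ndarray


def predicted_monomer_sums(
    n: int, initial_kind: str = "base-pair", central: bool = False
) -> MonomerSums:
    """Closed-form monomer-level mean probabilities for homopolymers.

    For a hole created at the first base pair the favored edge monomers get
    psi = 3/(2(N+1)) and every middle monomer chi = 1/(N+1); created at a
    sugar of the first monomer, the first monomer keeps
    omega = (2N+5)/(4(N+1)), middles get chi = 1/(2(N+1)) and the last
    phi = 3/(4(N+1)).  With ``central=True`` (odd N, hole at the central base
    pair) the central monomer gets 2/(N+1) and all others 1/(N+1).  These
    sums depend only on N, never on t_S.
    """
    if n < 2:
        raise ValidationError(f"homopolymer monomer sums need N >= 2, got {n}")
    per = np.empty(n)
    if initial_kind == "base-pair":
        if central:
            if n % 2 == 0:
                raise ValidationError("central-monomer placement requires odd N")
            per[:] = 1.0 / (n + 1)
            per[n // 2] = 2.0 / (n + 1)
        else:
            per[:] = 1.0 / (n + 1)
            per[0] = per[-1] = 3.0 / (2 * (n + 1))
    elif initial_kind == "sugar":
        if central:
            raise ValidationError("central-monomer variant is defined for base-pair placement")
        per[:] = 1.0 / (2 * (n + 1))
        per[0] = (2 * n + 5) / (4.0 * (n + 1))
        per[-1] = 3.0 / (4.0 * (n + 1))
    else:
        raise ValidationError(
            f"initial_kind must be 'base-pair' or 'sugar', got {initial_kind!r}"
        )
    return MonomerSums(float(per[0]), float(per[1]) if n > 2 else float("nan"),
                       float(per[-1]), per)


def monomer_probability_sums(per_site: np.ndarray, site_map: SiteIndexMap) -> np.ndarray:
    """Sum per-site (mean) probabilities over the three sites of each monomer."""
    return np.asarray(per_site).reshape(site_map.n_monomers, 3).sum(axis=1)


def first_crossing_time(
    times: np.ndarray, trace: np.ndarray, mean_value: float
) -> float | None:
    """First time a probability trace reaches its mean, linearly interpolated.

    The trace is scanned for the first sign change of (trace - mean) in either
    direction; an exact hit at t=0 returns 0.  Returns None when the trace
    never reaches the mean on the given grid.
    """
    d = np.asarray(trace, dtype=float) - mean_value
    if abs(d[0]) == 0.0:
        return float(times[0])
    sign0 = np.sign(d[0])
    hit = np.nonzero(sign0 * d <= 0.0)[0]
    if hit.size == 0:
        return None
    i = int(hit[0])
    if d[i] == 0.0:
        return float(times[i])
    t0, t1, d0, d1 = times[i - 1], times[i], d[i - 1], d[i]
    return float(t0 + (t1 - t0) * d0 / (d0 - d1))


def _search_crossing(
    es: EigenSystem,
    coeffs: np.ndarray,
    beta: int,
    mean_value: float,
    params: ParameterSet,
    max_periods: float = 1e5,
) -> float | None:
    """Window-doubling search for the first crossing of site ``beta``'s trace.

    Windows start at 10 periods of the fastest pairwise frequency and double
    until a crossing is bracketed or ``max_periods`` fast periods are
    exhausted.
    """
    _, f_max = _frequency_extrema(es, params)
    w = _weights(es, coeffs)[beta - 1, :]
    omegas = es.eigenvalues / params.hbar

    def trace(ts: np.ndarray) -> np.ndarray:
        amp = np.exp(-1j * np.outer(omegas, ts)).T @ w
        return amp.real**2 + amp.imag**2

    if f_max == 0.0:
        p0 = float(trace(np.array([0.0]))[0])
        return 0.0 if abs(p0 - mean_value) < 1e-12 else None
    dt = 1.0 / (40.0 * f_max)
    t_start, prev_t, prev_p = 0.0, 0.0, float(trace(np.array([0.0]))[0])
    if abs(prev_p - mean_value) == 0.0:
        return 0.0
    n_window = 400  # 10 fast periods at 40 steps each
    total = 0.0
    while total < max_periods / f_max:
        ts = t_start + dt * np.arange(1, n_window + 1)
        ps = trace(ts)
        full_t = np.concatenate(([prev_t], ts))
        full_p = np.concatenate(([prev_p], ps))
        t_cross = first_crossing_time(full_t, full_p, mean_value)
        if t_cross is not None:
            return t_cross
        prev_t, prev_p = float(ts[-1]), float(ps[-1])
        t_start = prev_t
        total = prev_t
        n_window *= 2
    return None


@dataclass(frozen=True)
class TransferRates:
    """Mean transfer rates k_{alpha beta} from the initial site to all others.

    ``rates`` and ``crossing_times`` are indexed by site (length 3N); entries
    for the initial site itself are NaN, and sites the hole can never reach
    carry rate 0 with ``unreachable`` set.
    """

    alpha: int
    rates: np.ndarray            # 1/s
    crossing_times: np.ndarray   # s
    unreachable: np.ndarray      # bool

    @property
    def total(self) -> float:
        """Sum of k_{alpha beta} over all beta != alpha, 1/s."""
        mask = ~np.isnan(self.rates)
        return float(self.rates[mask].sum())


def transfer_rates(
    es: EigenSystem,
    coeffs: np.ndarray,
    alpha: int,
    params: ParameterSet,
    means: np.ndarray | None = None,
    max_periods: float = 1e5,
) -> TransferRates:
    """k_{alpha beta} = <|C_beta|^2> / t_{alpha beta} for every site beta.

    ``t_{alpha beta}`` is the first time the instantaneous probability at
    beta equals its time average.  A site with exactly zero mean probability
    (e.g. any sugar when t_S = 0) is flagged unreachable and reported with
    zero rate instead of failing the run.
    """
    if means is None:
        means = mean_probabilities_analytic(es, coeffs)
    n = es.n_sites
    rates = np.zeros(n)
    tcross = np.full(n, np.nan)
    unreach = np.zeros(n, dtype=bool)
    for beta in range(1, n + 1):
        if beta == alpha:
            rates[beta - 1] = np.nan
            continue
        m = float(means[beta - 1])
        if m < UNREACHABLE_TOL:
            unreach[beta - 1] = True
            continue
        t = _search_crossing(es, coeffs, beta, m, params, max_periods=max_periods)
        if t is None:
            raise ArithmeticError(
                f"no crossing of the mean found for site beta={beta} within "
                f"{max_periods:g} fast periods"
            )
        tcross[beta - 1] = t
        rates[beta - 1] = m / t if t > 0 else np.inf
    return TransferRates(alpha=alpha, rates=rates, crossing_times=tcross,
                         unreachable=unreach)


def dipole_moment(
    probabilities: np.ndarray,
    site_map: SiteIndexMap,
    params: ParameterSet,
    carrier: str = "hole",
) -> tuple[np.ndarray, np.ndarray]:
    """Dipole-moment traces (Px(t), Py(t)) in units of e*Å.

    The x axis runs along the helix (monomer index nu), the y axis across it
    (strand index sigma); the origin sits at the molecular center,
    nu_c = (N+1)/2 and sigma_c = 2.  Holes count as positive charge
    (``carrier="hole"``), electrons as negative.
    """
    if carrier not in ("hole", "electron"):
        raise ValidationError(f"carrier must be 'hole' or 'electron', got {carrier!r}")
    sign = 1.0 if carrier == "hole" else -1.0
    probs = np.atleast_2d(np.asarray(probabilities))
    nu = site_map.monomer_indices().astype(float)
    sigma = site_map.strand_indices().astype(float)
    xc = (site_map.n_monomers + 1) / 2.0
    px = sign * params.dx * ((nu - xc) @ probs)
    py = sign * params.dy * ((sigma - 2.0) @ probs)
    return px, py


def to_atomic_units(dipole_e_angstrom: np.ndarray) -> np.ndarray:
    """Convert a dipole trace from e*Å to atomic units (e*a0)."""
    return np.asarray(dipole_e_angstrom) * BOHR_PER_ANGSTROM


@dataclass(frozen=True)
class DynamicsResult:
    """Bundle of everything the time-dependent problem produces."""

    eigensystem: EigenSystem
    initial: InitialCondition
    expansion_coeffs: np.ndarray
    time_grid: np.ndarray
    probabilities: np.ndarray        # (3N, n_times)
    mean_probabilities: np.ndarray   # (3N,)
    rates: TransferRates
    dipole_x: np.ndarray
    dipole_y: np.ndarray


def simulate(
    h: FishboneHamiltonian,
    alpha: int,
    times: np.ndarray | None = None,
    carrier: str = "hole",
    max_periods: float = 1e5,
) -> DynamicsResult:
    """Full coherent-dynamics run for a hole created at site ``alpha``."""
    es = eigensystem(h)
    init = InitialCondition(alpha)
    coeffs = expansion_coefficients(es, init)
    if times is None:
        times = default_time_grid(es, h.params)
    probs = site_probabilities(es, coeffs, times, h.params)
    means = mean_probabilities_analytic(es, coeffs)
    rates = transfer_rates(es, coeffs, alpha, h.params, means=means,
                           max_periods=max_periods)
    px, py = dipole_moment(probs, h.site_map, h.params, carrier=carrier)
    return DynamicsResult(
        eigensystem=es,
        initial=init,
        expansion_coeffs=coeffs,
        time_grid=np.asarray(times, dtype=float),
        probabilities=probs,
        mean_probabilities=means,
        rates=rates,
        dipole_x=px,
        dipole_y=py,
    )
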