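"""Time-independent problem: eigenspectra, degeneracies, DOS, subbands.

For a homopolymer the 3N eigenvalues organize into three subbands once the
sugar coupling t_S is switched on: N eigenvalues pinned exactly at the sugar
on-site energy E_S (antisymmetric combinations of the two sugars of each
monomer, which decouple from the base-pair chain), plus two non-degenerate
subbands of N eigenvalues each, repelled below and above E_S.  At t_S = 0 the
model collapses to the base-pair wire plus 2N isolated sugars at E_S.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import FishboneHamiltonian
from .parameters import ParameterSet, ValidationError

__all__ = [
    "EigenSystem",
    "DOSHistogram",
    "SubbandGroup",
    "SubbandPartition",
    "eigensystem",
    "eigenvalues_only",
    "degeneracy_classes",
    "dos_histogram",
    "subband_partition",
]

#: Absolute tolerance separating the exact E_S degeneracy from physical
#: near-degeneracies at all scales used here.
DEGENERACY_TOL = 1e-9


@dataclass(frozen=True)
class EigenSystem:
    """Ascending eigenvalues, orthonormal eigenvectors, degeneracy classes.

    ``eigenvectors[:, k]`` is the k-th eigenvector; its beta-th component is
    the amplitude of that stationary state on site beta.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    degeneracy_classes: tuple[tuple[int, ...], ...]

    @property
    def n_sites(self) -> int:
        return self.eigenvalues.size

    @property
    def n_distinct(self) -> int:
        """Number m of distinct eigenvalues (degeneracy classes)."""
        return len(self.degeneracy_classes)


def degeneracy_classes(
    eigenvalues: np.ndarray, tol: float = DEGENERACY_TOL
) -> tuple[tuple[int, ...], ...]:
    """Partition ascending eigenvalue indices into transitive equality classes.

    Consecutive eigenvalues closer than ``tol`` (absolute, eV) belong to one
    class; a class of size > 1 is a degenerate level with zero internal
    oscillation frequency.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.size == 0:
        return ()
    classes: list[list[int]] = [[0]]
    for k in range(1, ev.size):
        if ev[k] - ev[classes[-1][-1]] < tol:
            classes[-1].append(k)
        else:
            classes.append([k])
    return tuple(tuple(c) for c in classes)


def eigensystem(
    h: FishboneHamiltonian, tol: float = DEGENERACY_TOL
) -> EigenSystem:
    """Diagonalize the FWM Hamiltonian (dense symmetric solver).

    Eigenvalues ascend; eigenvectors are orthonormal columns.  The residual
    ||H v - E v|| is checked and a numerical failure raises rather than
    returning silently wrong spectra.
    """
    vals, vecs = np.linalg.eigh(h.matrix)
    scale = max(1.0, float(np.abs(vals).max()))
    resid = np.abs(h.matrix @ vecs - vecs * vals).max()
    if not np.isfinite(resid) or resid > 1e-8 * scale:
        raise ArithmeticError(f"eigendecomposition residual too large: {resid:g}")
    return EigenSystem(
        eigenvalues=vals,
        eigenvectors=vecs,
        degeneracy_classes=degeneracy_classes(vals, tol),
    )


def eigenvalues_only(h: FishboneHamiltonian) -> np.ndarray:
    """Ascending eigenvalues without eigenvectors (cheaper for DOS at large N)."""
    return np.linalg.eigvalsh(h.matrix)


@dataclass(frozen=True)
class DOSHistogram:
    """Raw (unnormalized) count of eigenenergies per energy bin."""

    bin_edges: np.ndarray
    counts: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def dos_histogram(eigenvalues: np.ndarray, bin_width: float = 1e-3) -> DOSHistogram:
    """Histogram of eigenenergies with one empty margin bin on each side.

    Raw counts; their sum is always 3N regardless of ``bin_width``.
    """
    if bin_width <= 0:
        raise ValidationError(f"bin_width must be positive, got {bin_width}")
    ev = np.asarray(eigenvalues, dtype=float)
    lo = ev.min() - bin_width
    hi = ev.max() + bin_width
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    counts, edges = np.histogram(ev, bins=edges)
    return DOSHistogram(bin_edges=edges, counts=counts)


@dataclass(frozen=True)
class SubbandGroup:
    """One group of eigenvalues with its count and spread."""

    indices: tuple[int, ...]
    count: int
    e_min: float
    e_max: float

    @property
    def width(self) -> float:
        return self.e_max - self.e_min


@dataclass(frozen=True)
class SubbandPartition:
    """Eigenvalues split into the E_S-degenerate class and the bands below
    and above it.

    The figure-dependent "left/right" labels are avoided; bands are named by
    their position relative to E_S, with ``narrower``/``wider`` helpers.
    """

    degenerate: SubbandGroup
    below: SubbandGroup
    above: SubbandGroup

    @property
    def narrower(self) -> SubbandGroup:
        return min((self.below, self.above), key=lambda g: g.width)

    @property
    def wider(self) -> SubbandGroup:
        return max((self.below, self.above), key=lambda g: g.width)


def _group(ev: np.ndarray, idx: np.ndarray) -> SubbandGroup:
    if idx.size == 0:
        return SubbandGroup(indices=(), count=0, e_min=np.nan, e_max=np.nan)
    return SubbandGroup(
        indices=tuple(int(i) for i in idx),
        count=int(idx.size),
        e_min=float(ev[idx].min()),
        e_max=float(ev[idx].max()),
    )


def subband_partition(
    es: EigenSystem | np.ndarray, params: ParameterSet, tol: float = DEGENERACY_TOL
) -> SubbandPartition:
    """Partition a homopolymer spectrum around the E_S-degenerate class.

    Accepts a full :class:`EigenSystem` or a bare ascending eigenvalue array.
    The degenerate class is the set of eigenvalues within ``tol`` of the
    sugar on-site energy; the rest split into the subband below and the
    subband above it.  Without any eigenvalue at E_S the split is undefined
    (overlapping bands, typically a non-homopolymer) and an explicit error
    advises inspecting the DOS.
    """
    ev = np.asarray(es) if isinstance(es, np.ndarray) else es.eigenvalues
    at_es = np.abs(ev - params.e_sugar) < tol
    if not at_es.any():
        raise ValidationError(
            "no degenerate class at the sugar on-site energy; the subband "
            "partition is undefined — inspect the DOS histogram instead"
        )
    idx = np.arange(ev.size)
    return SubbandPartition(
        degenerate=_group(ev, idx[at_es]),
        below=_group(ev, idx[~at_es & (ev < params.e_sugar)]),
        above=_group(ev, idx[~at_es & (ev > params.e_sugar)]),
    )
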