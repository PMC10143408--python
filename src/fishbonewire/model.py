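"""Site indexing and assembly of the 3N x 3N Fishbone-Wire Hamiltonian.

Sites are addressed by a strand index sigma in {1, 2, 3} (left sugar, base
pair, right sugar), a monomer index nu in 1..N, and a flat site index
beta = 3*(nu - 1) + sigma in 1..3N.  The public surface uses these 1-based
indices throughout; arrays are 0-based internally.

The Hamiltonian couples each base pair to its own two sugars (t_S) and to the
neighbouring base pairs (the dimer couplings); sugars of different monomers
are never connected — the "fishbone" shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .parameters import ParameterSet, SequenceSpec, ValidationError, dimer_coupling

__all__ = ["SiteIndexMap", "FishboneHamiltonian", "site_index", "build_hamiltonian"]


def site_index(nu: int, sigma: int, n_monomers: int | None = None) -> int:
    """1-based flat site index beta = 3*(nu-1) + sigma.

    ``sigma`` is 1 (left sugar), 2 (base pair) or 3 (right sugar).
    """
    if sigma not in (1, 2, 3):
        raise ValidationError(f"strand index sigma must be 1, 2 or 3, got {sigma}")
    if nu < 1 or (n_monomers is not None and nu > n_monomers):
        raise ValidationError(f"monomer index nu={nu} out of range 1..{n_monomers}")
    return 3 * (nu - 1) + sigma


@dataclass(frozen=True)
class SiteIndexMap:
    """Bijection between (nu, sigma) and the flat site index beta."""

    n_monomers: int

    @property
    def n_sites(self) -> int:
        return 3 * self.n_monomers

    def beta(self, nu: int, sigma: int) -> int:
        return site_index(nu, sigma, self.n_monomers)

    def nu_sigma(self, beta: int) -> tuple[int, int]:
        if not 1 <= beta <= self.n_sites:
            raise ValidationError(f"site index beta={beta} out of range 1..{self.n_sites}")
        return (beta - 1) // 3 + 1, (beta - 1) % 3 + 1

    def monomer_indices(self) -> np.ndarray:
        """nu for each site in beta order (1-based, length 3N)."""
        return np.repeat(np.arange(1, self.n_monomers + 1), 3)

    def strand_indices(self) -> np.ndarray:
        """sigma for each site in beta order (1-based, length 3N)."""
        return np.tile(np.array([1, 2, 3]), self.n_monomers)


@dataclass(frozen=True)
class FishboneHamiltonian:
    """Dense real-symmetric FWM Hamiltonian with its provenance."""

    matrix: np.ndarray
    site_map: SiteIndexMap
    sequence: SequenceSpec
    params: ParameterSet

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[0]

    def to_csv(self, path: str | Path) -> None:
        """Dump the matrix as plain CSV for inspection."""
        np.savetxt(path, self.matrix, delimiter=",", fmt="%.12g")


def build_hamiltonian(seq: SequenceSpec, params: ParameterSet) -> FishboneHamiltonian:
    """Assemble the 3N x 3N FWM Hamiltonian for ``seq``.

    Diagonal: E_S at sugar sites, the base-pair on-site energy at sigma=2
    sites.  Off-diagonal: t_S between each base pair and its two sugars, and
    the 5'->3' dimer coupling between consecutive base pairs.
    """
    n = seq.n_monomers
    smap = SiteIndexMap(n)
    h = np.zeros((3 * n, 3 * n))
    ts = params.t_sugar
    for nu, base in enumerate(seq.bases, start=1):
        bp = smap.beta(nu, 2) - 1
        h[bp, bp] = params.onsite_for_base(base)
        for sigma in (1, 3):
            s = smap.beta(nu, sigma) - 1
            h[s, s] = params.e_sugar
            h[bp, s] = h[s, bp] = ts
        if nu < n:
            nxt = smap.beta(nu + 1, 2) - 1
            t = dimer_coupling(base, seq.bases[nu], params)
            h[bp, nxt] = h[nxt, bp] = t
    return FishboneHamiltonian(matrix=h, site_map=smap, sequence=seq, params=params)
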