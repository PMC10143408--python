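"""Tight-binding parameterization of the Fishbone-Wire Model (FWM) of B-DNA.

The FWM treats each monomer of a double strand as three sites: a Watson-Crick
base pair (G-C or A-T) flanked by its two deoxyribose (sugar) backbone sites.
All energies here are *hole* (HOMO) energies in eV — ionization-energy sign
convention, i.e. already sign-flipped relative to the electronic levels — and
no further sign manipulation is applied anywhere in the package.

The default numbers are the standard HOMO parameterization for hole transfer:
sugar on-site energy ``E_S = 9.0`` eV, base-pair on-site energies
``E_{G-C} = 8.0`` eV and ``E_{A-T} = 8.3`` eV, and the ten canonical
intra-strand dimer couplings (entered in meV, stored in eV).  The base-pair to
sugar coupling ``t_S`` is not well established experimentally and is treated
as a free parameter throughout.

Dimers are named by their bases read 5'->3' on one strand; the step ``XY`` and
the step ``complement(Y) complement(X)`` (read 5'->3' on the complementary
strand) denote the same physical dimer, so e.g. ``TG`` and ``CA`` share one
coupling value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "VALID_BASES",
    "COMPLEMENT",
    "CANONICAL_DIMERS",
    "TABLE1_MEV",
    "ParameterSet",
    "SequenceSpec",
    "canonicalize_dimer",
    "dimer_coupling",
    "homopolymer_spec",
    "load_parameters",
    "default_parameters",
]

VALID_BASES = frozenset("ATGC")

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Intra-strand couplings between consecutive base pairs (hole picture), meV.
#: Keys are the canonical 5'->3' dimer names.
TABLE1_MEV: dict[str, float] = {
    "AA": 20.0,   # AA ≡ TT
    "GG": 100.0,  # GG ≡ CC
    "AT": -35.0,
    "TA": -50.0,
    "GC": -10.0,
    "CG": 50.0,
    "AG": 30.0,   # AG ≡ CT
    "TC": 110.0,  # TC ≡ GA
    "AC": -10.0,  # AC ≡ GT
    "TG": 10.0,   # TG ≡ CA
}

CANONICAL_DIMERS = tuple(TABLE1_MEV)

PLANCK_H_EVS = 4.135667696e-15      # eV*s
HBAR_EVS = 6.582119569e-16          # eV*s
BOHR_PER_ANGSTROM = 1.0 / 0.529177210903


class ValidationError(ValueError):
    """Raised for invalid sequences, bases or parameter values."""


def _check_base(b: str) -> str:
    if not isinstance(b, str) or len(b) != 1 or b.upper() not in VALID_BASES:
        raise ValidationError(f"invalid base {b!r}: expected one of A, T, G, C")
    return b.upper()


def canonicalize_dimer(step: str) -> str:
    """Return the canonical name of a 5'->3' base-pair step.

    ``XY`` and ``complement(Y)+complement(X)`` name the same dimer; the
    canonical representative is the one listed in the coupling table
    (e.g. ``"CA" -> "TG"``, ``"CT" -> "AG"``).
    """
    if not isinstance(step, str) or len(step) != 2:
        raise ValidationError(f"dimer step must be two letters, got {step!r}")
    x, y = (_check_base(c) for c in step)
    key = x + y
    if key in TABLE1_MEV:
        return key
    alt = COMPLEMENT[y] + COMPLEMENT[x]
    if alt in TABLE1_MEV:
        return alt
    raise ValidationError(f"no canonical dimer for step {step!r}")  # pragma: no cover


@dataclass(frozen=True)
class ParameterSet:
    """All FWM energies, couplings, geometry and physical constants.

    Attributes
    ----------
    e_sugar : float
        Deoxyribose on-site energy E_S, eV.
    t_sugar : float
        Base-pair <-> deoxyribose coupling t_S, eV.  One scalar applied to
        both the left and right sugar of every base pair.
    onsite_bp : mapping
        Base-pair on-site energies keyed by "GC" and "AT", eV.
    t_dimer : mapping
        Couplings between consecutive base pairs keyed by canonical 5'->3'
        dimer name, eV.
    dx, dy : float
        Monomer spacing along the helix axis and strand spacing across it, Å.
    """

    e_sugar: float = 9.0
    t_sugar: float = 0.0
    onsite_bp: Mapping[str, float] = field(
        default_factory=lambda: {"GC": 8.0, "AT": 8.3}
    )
    t_dimer: Mapping[str, float] = field(
        default_factory=lambda: {k: v / 1000.0 for k, v in TABLE1_MEV.items()}
    )
    dx: float = 3.4
    dy: float = 10.0
    planck_h: float = PLANCK_H_EVS
    hbar: float = HBAR_EVS

    def __post_init__(self) -> None:
        missing = set(CANONICAL_DIMERS) - set(self.t_dimer)
        if missing:
            raise ValidationError(f"t_dimer missing canonical keys: {sorted(missing)}")
        if set(self.onsite_bp) != {"GC", "AT"}:
            raise ValidationError(
                f"onsite_bp must have exactly keys GC and AT, got {sorted(self.onsite_bp)}"
            )
        if not (self.dx > 0 and self.dy > 0):
            raise ValidationError("dx and dy must be positive")

    def onsite_for_base(self, base: str) -> float:
        """On-site energy, in eV, of the base pair containing ``base``."""
        b = _check_base(base)
        return self.onsite_bp["GC" if b in "GC" else "AT"]

    def with_t_sugar(self, t_sugar: float) -> "ParameterSet":
        return replace(self, t_sugar=float(t_sugar))


def dimer_coupling(x: str, y: str, params: ParameterSet) -> float:
    """Coupling in eV for the base-pair step ``x -> y`` read 5'->3'."""
    return params.t_dimer[canonicalize_dimer(_check_base(x) + _check_base(y))]


@dataclass(frozen=True)
class SequenceSpec:
    """A validated base sequence, read 5'->3' on one strand.

    Each letter stands for a whole Watson-Crick base pair (one monomer);
    ``n_monomers`` is the number of monomers N.
    """

    bases: str

    def __post_init__(self) -> None:
        if not isinstance(self.bases, str) or len(self.bases) < 1:
            raise ValidationError("sequence must contain at least one base")
        up = self.bases.upper()
        for c in up:
            _check_base(c)
        object.__setattr__(self, "bases", up)

    @property
    def n_monomers(self) -> int:
        return len(self.bases)

    @property
    def is_homopolymer(self) -> bool:
        return len(set(self.bases)) == 1


def homopolymer_spec(base: str, n: int) -> SequenceSpec:
    """Sequence of ``n`` identical monomers (purine on purine), e.g. G...G."""
    if n < 1:
        raise ValidationError(f"number of monomers must be >= 1, got {n}")
    return SequenceSpec(_check_base(base) * int(n))


def default_parameters(t_sugar: float = 0.0) -> ParameterSet:
    """The standard hole-transfer parameter set with the given ``t_S``."""
    return ParameterSet(t_sugar=float(t_sugar))


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a :class:`ParameterSet` from a YAML key-value config file.

    Recognized keys (all optional; defaults are the standard values):
    ``es`` (sugar on-site, eV), ``ts`` (sugar coupling, eV), ``e_gc``,
    ``e_at`` (base-pair on-sites, eV), ``dx``, ``dy`` (Å) and ``table1``,
    a mapping of dimer names to couplings *in meV* overriding the defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config file {path} must contain a key-value mapping")
    known = {"es", "ts", "e_gc", "e_at", "dx", "dy", "table1"}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    table_mev = dict(TABLE1_MEV)
    for key, val in (raw.get("table1") or {}).items():
        table_mev[canonicalize_dimer(str(key))] = float(val)
    return ParameterSet(
        e_sugar=float(raw.get("es", 9.0)),
        t_sugar=float(raw.get("ts", 0.0)),
        onsite_bp={"GC": float(raw.get("e_gc", 8.0)), "AT": float(raw.get("e_at", 8.3))},
        t_dimer={k: v / 1000.0 for k, v in table_mev.items()},
        dx=float(raw.get("dx", 3.4)),
        dy=float(raw.get("dy", 10.0)),
    )
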