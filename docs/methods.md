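# Methods

## Model and assumptions

The Fishbone-Wire Model treats a B-DNA segment as N monomers of three
tight-binding sites each: one Watson–Crick base pair and its left/right
deoxyriboses. Only two kinds of interaction exist: base pair ↔ own sugars
(`t_S`, one scalar for both sides of every monomer) and base pair ↔
neighbouring base pair (the sequence-dependent dimer coupling). Sugars are
mutually disconnected, and there is no backbone disorder: every sugar shares
one on-site energy `E_S` and every monomer the same `t_S`. Dynamics are fully
coherent — no dephasing, polaron or phonon coupling — so results apply to the
short-segment regime where coherent transfer dominates.

All energies are hole (HOMO) energies with the ionization-energy sign
convention; the parameter tables are entered already sign-flipped relative to
electronic levels and no further sign handling occurs anywhere.

Dimer couplings are defined for 5′→3′ steps; the step XY and the step
complement(Y)complement(X) on the opposite strand are the same physical dimer
and are canonicalized to one table key (10 keys cover all 16 letter pairs).
For arbitrary (non-homopolymer) sequences the builder applies the dimer table
stepwise along the strand; this is the natural extension of the dimer
parameterization, exact for homopolymers and dimers and a standard
approximation in between.

## Parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| `e_sugar` (E_S) | deoxyribose on-site energy | 9.0 | eV |
| `t_sugar` (t_S) | base-pair↔sugar coupling | user-chosen (0 – 2 typical) | eV |
| `onsite_bp` | base-pair on-site energies | G–C: 8.0, A–T: 8.3 | eV |
| `t_dimer` | 10 canonical dimer couplings | 20…110 meV table | eV internally |
| `dx`, `dy` | monomer / strand spacing | 3.4, 10.0 | Å |

Energies are stored in eV throughout; the coupling table is entered in meV
and converted exactly once at load, eliminating silent 10³ errors. `t_S` is
the physically least-constrained number (literature spans ≈0.24–1.5 eV), so
every observable is exposed as a function of it.

## Time-independent problem

Dense symmetric diagonalization (`numpy.linalg.eigh`; eigenvalues-only
variant for large-N DOS runs). 3N ≤ 6000 in every use case, where one solve
takes tens of seconds — sparse methods would buy nothing and complicate the
degenerate subspaces. A residual check raises on numerical failure rather
than returning a bad spectrum.

Degeneracy classes group ascending eigenvalues transitively within an
absolute tolerance of 1e−9 eV. The pinned-at-`E_S` degeneracy (antisymmetric
sugar combinations, which decouple from the base-pair chain for *any*
sequence) is exact in exact arithmetic and reproduced by `eigh` to ≪1e−9 eV,
while physically distinct levels are separated by ≥1e−5 eV at all sizes used
here, so the tolerance has a wide safe window.

The subband partition is defined relative to the `E_S` class — degenerate
class, band below, band above — rather than by gap detection, because at
small `t_S` the sugar-derived band sits arbitrarily close to `E_S`.
Figure-orientation-dependent "left/right" labels are avoided;
`narrower`/`wider` accessors identify the sugar-derived and base-pair-derived
bands unambiguously (the former widens, the latter narrows, as `t_S` grows).

DOS histograms use raw counts (sum = 3N) with a default 1 meV bin and one
empty margin bin per side.

## Time-dependent problem

Evolution is evaluated in closed form from the eigendecomposition; the time
grid only decides where the analytic solution is *sampled*. The default grid
resolves the fastest pairwise frequency with 40 points per period and spans
200 periods of the slowest nonzero one (capped at 2×10⁵ samples).

Mean-over-time probabilities have an exact closed form: only zero-frequency
(intra-degeneracy-class) terms survive the average, so
⟨|C_β|²⟩ = Σ_g (Σ_{k∈g} C_k v_{βk})². A numerical trapezoidal average over a
finite window is provided as a cross-check and agrees to ≤1e−3 at the default
window for all systems exercised in the tests.

First-crossing times are found on the analytic trace by bracketing plus
linear interpolation, on windows that start at 10 fast periods and double
geometrically (up to 10⁵ fast periods). Sites with exactly zero mean
probability — e.g. any sugar when `t_S = 0` — are flagged unreachable and
reported with zero rate instead of aborting the run.

Dipole moments are reported in e·Å with the hole sign (+) by default and a
converter to atomic units (1 Å = 1/0.529177210903 a₀). The molecular center
is ν_c = (N+1)/2, σ_c = 2.

## Frequency content

The Weighted Mean Frequency of a site follows the pairwise-line definition
literally: all k > k′ pairs enter with weight |C_k v_{βk} C_k′ v_{βk′}|,
including degenerate pairs at f = 0 (they dilute the mean through the
denominator). An `exclude_degenerate` flag drops them from both sums for
users who prefer the nonzero-line average; for base-pair injection the two
conventions coincide because the hole never populates the degenerate sugar
states. Zero-total-weight sites take WMF = 0 by convention (their mean
probability is also 0 in every case that occurs). User-facing tables report
THz; the library works in Hz.

The FFT cross-check computes a one-sided amplitude spectrum from a uniformly
sampled trace; with an integer number of periods in the window it reproduces
the analytic line amplitudes to ≈1e−6.

## Rate fits

Three laws: k = k₀ exp(−βr) with r = dx·(N−1) (the traveled distance over
N−1 steps), k = k₀′(N−1)^−η, and k = k₀′N^−η′. The default fitting method is
nonlinear least squares on the rates themselves (linear space), which weights
the fast short-chain rates most heavily — this is the convention under which
the published exponent values for this model and for the experimental
literature it connects to were obtained, and it is what `method="linear"`
reproduces (including the quoted standard errors, from the fit covariance).
Log-space ordinary least squares (`method="log"`), which weights all lengths
equally, is provided as an alternative; on the near-power-law rate series the
two give markedly different exponential exponents (β ≈ 0.11 vs ≈ 0.18 Å⁻¹ at
t_S = 0.1 eV), which is worth remembering whenever exponents from different
sources are compared. Both methods recover noiseless synthetic laws exactly.

## Problem sizes and verification

Tests verify the implementation against independent oracles: the exact
sine-mode reduction of the homopolymer FWM (N antisymmetric sugar levels at
`E_S` plus N independent 2×2 blocks coupling the symmetric sugar combination
to each open-chain mode with strength √2·t_S), the two-level Rabi closed form
for the decoupled GG dimer, closed-form monomer sums, and FFT vs analytic
spectra. Spectral statements are exercised at N up to 2000 (three 6000×6000
eigensolves, ≈1 min together); dynamics and rate fits use N ≤ 10, matching
the coherent short-segment regime the model is meant for — the persistence
length of DNA (≈150 monomers) bounds the physical relevance of larger N
anyway.

## Known limitations

- No backbone disorder (site-dependent `E_S` or `t_S`), no purine- vs
  pyrimidine-specific sugar coupling, no inter-sugar conduction channels.
- Coherent evolution only; rates are coherent mean transfer rates, not
  incoherent hopping rates, and should not be compared to high-temperature
  kinetics without care.
- No electrodes: transmission, I–V characteristics and thermoelectric
  quantities are out of scope.
- The dimer coupling table is a fixed parameterization; structural
  variability of the couplings is not sampled.
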