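# Methods

## The dihedral graph and the folding degree

The model reduces a protein backbone to its N–Cα–C atom path.  The third
iterated line graph of that path is again a path whose vertices are the
consecutive 4-atom backbone torsions, in order ψ₁, ω₁, φ₂, ψ₂, ω₂, φ₃, …
for an N-residue stretch (3(N−1) vertices).  The adjacency matrix A is
symmetric tridiagonal: unit off-diagonals (consecutive torsions share three
atoms) and cos(torsion) on the diagonal.  Per-vertex subgraph centralities
CSᵢ = Σⱼ vⱼᵢ² e^{λⱼ} are computed from the eigendecomposition of A
(`scipy.linalg.eigh_tridiagonal`); they equal the diagonal of the matrix
exponential e^A, which serves as an independent oracle in the tests (never
as the implementation).  The residue folding degree RCSₖ sums the
centralities of the φₖ and ψₖ vertices (1-based vertices 3(k−1) and
3(k−1)+1); it is defined for interior residues of a contiguous stretch
only.  The global folding degree ⟨CS⟩ is the plain mean over all 3(N−1)
vertex centralities and is reported by the full-matrix method only — a
local method does not produce a consistent full vertex set.

Positivity (CSᵢ > 0, hence RCSₖ > 0) holds because the diagonal of the
exponential of a real symmetric matrix is positive; the suite asserts it.

## Local-window approximation: why a 6×6 block

Because A is tridiagonal with spectral radius ≤ 2 + max|cos| ≤ 3, the
influence of a diagonal entry on [e^A]ᵢᵢ decays rapidly with graph
distance, so RCSₖ is almost determined by the torsions near residue k and
can be computed windowed, at cost linear in N.  Two windows are exposed:

* **`block` (default)** — the 6×6 sub-block spanning
  (ψ_{k−1}, ω_{k−1}, φ_k, ψ_k, ω_k, φ_{k+1}), i.e. one extra dihedral on
  each side of the (φ_k, ψ_k) pair.  Measured worst-case deviation from the
  full-matrix RCS: **< 0.2%** over ensembles of random dihedral
  configurations (φ, ψ uniform, ω = 180 ± 10°) as well as over realistic
  helix/strand mixtures.  This is the smallest window that keeps the
  per-residue error comfortably below 1%, and is what profiles, CV series
  and the theoretical surface use by default.
* **`block4`** — the minimal 4×4 sub-block (ω_{k−1}, φ_k, ψ_k, ω_k).
  Cheaper, but its truncation error against the full matrix is ~1.7%
  typically and up to ~3.5% worst-case, essentially independently of the
  angle distribution.  It is retained because the per-category survey
  scale the package ships (see below) is consistent with this variant:
  Gaussian draws at the surveyed (φ, ψ) means/s.d.s reproduce the surveyed
  H-category mean RCS to 0.004 under `block4` (7.269 vs 7.273) and to ~0.1
  under the 6×6 window.  For switching-function work this scale offset is
  immaterial (references are taken from the same method as the frames),
  but users comparing absolute RCS numbers against the shipped category
  table may prefer `block4`.

Every interior residue of a contiguous stretch has all six window torsions
defined, so the 6×6 window needs no padding in profiles.  For standalone
evaluation (`rcs_block` with only the four local angles, e.g. the
theoretical RCS(φ, ψ) surface) the conformation is assumed to continue
ideally (ψ_{k−1} = ψ_k, φ_{k+1} = φ_k), which is exact for uniform repeats
such as ideal secondary-structure motifs.

The theoretical surface is evaluated on a half-open grid [−180, 180)² (the
periodic boundary is not duplicated) with ω fixed at 180° (planar trans
peptide) on both sides; it is symmetric under sign flips of φ and/or ψ
since only cosines enter, and peaks at φ = ψ = 0.

## Dihedrals, chain breaks and PDB handling

ψₖ is computed from (Nₖ, CAₖ, Cₖ, Nₖ₊₁), ωₖ from (CAₖ, Cₖ, Nₖ₊₁, CAₖ₊₁),
φₖ from (Cₖ₋₁, Nₖ, CAₖ, Cₖ), IUPAC sign, degrees in (−180, 180].
Consecutive residues with a C–N distance above 2.5 Å (vs the 1.33 Å
peptide bond) are treated as separate stretches and no torsion crosses the
break.  Altloc conflicts resolve to the highest occupancy (ties: altloc
'A'); residues order by (resseq, icode); HETATM records are skipped; any
ATOM-record residue with a complete N/CA/C backbone participates.  Parsing
uses Bio.PDB; only PDB format is required (multi-model files double as
trajectories).

## Switching function and reference modes

RCSₖ,rel = (1 − xᵐ)/(1 − xⁿ) with x = (RCSₖ − RCS_ref)/RCS_tol.  Exponents
are restricted to positive even m < n so the function is symmetric in x,
bounded on the reals, and has range (0, 1] with a removable singularity at
|x| = 1 where the limit m/n is returned; with the default (2, 4) the
expression simplifies exactly to 1/(1 + x²), which is what the code
evaluates.  The segment value SCS_κ,rel is the arithmetic mean over the
segment; frames in which any segment residue lacks a defined RCS are
flagged and reported as missing rather than averaged partially.

Reference modes: *helicality* (RCS_ref = 7.273, RCS_tol = 0.421, the
surveyed H-category mean and s.d.); *segment_mean* (shared mean of the
reference structure's RCS over the segment); *per_residue* (each residue's
own reference RCS); *category* (the surveyed mean of the residue's SS
category).  For the structure-derived modes the default tolerance is 1.0 —
a looser tolerance broadens the switch and, empirically, yields clearer
PMFs — while the category mode can optionally use the category s.d.
instead.  Values are kept at full precision internally; 2-decimal rounding
is a display concern.

The shipped category table (`foldcv/data/ss_category_rcs.tsv`) carries the
surveyed per-category RCS and (φ, ψ) means/s.d.s for the nine DSSP 4
categories (H, G, I, E, B, T, S, P, C).  Only the DSSP 4 table is
included.  The underlying multi-thousand-structure survey is *not*
reproduced by this package — the statistics machinery (`ss_stats`) is
fully implemented and tested on synthetic fixtures, but running it over a
structure corpus is up to the user.

## Secondary-structure statistics

`ss_stats` parses classic DSSP output (also produced by DSSP 4; blank
labels map to C, the DSSP 4 'P' category is kept distinct), STRIDE ASG
records (lowercase 'b' mapped to B) and plain 3-column TSV.  Assignment
algorithms themselves are out of scope.  Category statistics use the
sample (n−1) s.d. and exclude residues without a defined RCS (termini,
breaks); motif-length histograms are label-only, include such residues,
and break runs at chain boundaries.  Confusion matrices report counts over
the common residue set plus per-category percent disagreement relative to
the declared reference labeling.

## PMFs and minimum-energy paths

F = −kT ln(p/p_max) over a 1D/2D histogram of the CV series; the
best-sampled bin is exactly 0 and empty bins are masked (infinite F), never
imputed.  kT is computed as R·T/(1000·4.184) kcal/mol → 0.596 at 300 K.
Default binning is 50 bins per axis over the observed range.  The
minimum-energy path between two occupied bins minimizes the maximum F
along an 8-connected, mask-avoiding path (minimax criterion — the standard
barrier estimate on a discretized surface, implemented as widest-path
Dijkstra); ties resolve to the shortest, then lexicographically smallest
path, found in a second pass restricted to bins at or below the optimal
level.  The reported barrier is max-F-on-path minus F(start).  This is a
deliberately simple grid substitute for dedicated PMF path tools; it does
not implement their node/flooding analyses.

## Synthetic data

The fixture generators define the test conditions:

* `build_backbone` grows N/CA/C coordinates from per-residue (φ, ψ, ω) by
  sequential NeRF placement with fixed standard stereochemistry
  (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; N–CA–C 111.2°, CA–C–N 116.2°,
  C–N–CA 121.7°).  Build–recompute round-trips recover torsions to 1e−6°.
* `random_dihedrals` draws φ, ψ uniform on (−180, 180] and ω = 180 ± 10°
  jitter — the ensemble used for the block-vs-full fidelity bound (100
  sets of 50 residues by default).
* `two_state_cv_trajectory` is a two-state Markov chain (default switch
  probability 0.05 per frame each way) with Gaussian within-state dihedral
  noise (default s.d. 10° on φ/ψ, 3° on ω) around helix-like and
  extended-state means taken from the surveyed H and E category angles.

What these emulate — and what they do not: the two-state generator
reproduces the *switching structure* of a folding trajectory (bimodal CV
distributions, well-separated PMF basins) but has no kinetics beyond a
memoryless chain, no correlated residue motions, no solvent, and perfectly
ideal stereochemistry.  Passing tests therefore demonstrate the
correctness of the descriptors and machinery, not force-field realism.

## Numerical choices and degenerate inputs

Angles are handled in degrees externally and converted to radians only
inside cosine evaluation; wrapping is to (−180, 180].  Eigendecomposition
of the tridiagonal matrices is the primary route everywhere; the dense
matrix exponential appears only as a test oracle.  Chains shorter than 3
residues yield all-undefined profiles; stretches shorter than 3 contribute
no RCS.  PMF construction refuses empty or NaN-containing series and
zero-spread series without an explicit range.  All generators are
deterministic under a fixed seed.

## Problem sizes

Default test and reproduction runs use 100 × 50-residue random
configurations for the fidelity bound, trajectories of 400–600 frames of
10–12 residues for CV/PMF checks, and 4×4 grids for exhaustive path
enumeration; these sizes give stable statistics while keeping the whole
suite fast on a single CPU.

## Known limitations

* The per-category survey table is shipped as data, not recomputed; only
  the DSSP 4 variant is included.
* RCS has no analytic coordinate gradient here, so the CV cannot drive
  biased sampling — it is an analysis CV.
* The minimax path is a grid heuristic; profiles along it are qualitative
  comparators, not converged reaction coordinates.
* Absolute RCS values differ by ~0.1 (helical range) between the `block`
  and `block4` methods; comparisons should stay within one method.
* The Trp-cage check requires the user to supply PDB entry 1l2y (not
  redistributed).
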