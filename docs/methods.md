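# Methods

This note records the models, conventions and numerical choices behind
each analysis, what the synthetic generators emulate, and the limits of
what passing tests demonstrate about real experimental data.

## Structure I/O and selections

Multi-model PDB files are parsed and written with gemmi; validation and
ordering are ours. Residue numbering is taken verbatim from the file
(never renumbered), a missing chain identifier becomes chain `A`, and
alternate locations keep the highest-occupancy conformer (ties broken by
altloc letter) — NMR depositions rarely carry altlocs, but the rule must
exist. Every model of an ensemble must share one (chain, residue, atom)
roster; a mismatch is an error that names the offending atoms rather than
a silent intersection. Extracted coordinate matrices use a canonical
order — ascending chain, residue number, then N, CA, C, O before
side-chain names alphabetically — so downstream numbers never depend on
file atom order. The symbolic atom class `backbone` is exactly
{N, CA, C, O}; `heavy` is every non-hydrogen. Coordinates round-trip
through PDB at the format's 3-decimal (0.001 Å) precision.

## Superposition, region RMSD, ensemble precision

Superposition uses the Kabsch SVD solution with the standard sign flip of
the smallest singular direction to exclude reflections; near-collinear
point sets are rejected (ratio of the two largest gyration eigenvalues
below 1e-12) rather than silently returning an ill-conditioned rotation.
The implementation is verified against an independently implemented
quaternion characteristic-polynomial oracle, which computes the optimal
residual without constructing a rotation at all.

Cross-structure RMSD is computed over an explicit one-to-one residue
correspondence. The representative conformer of each ensemble defaults to
the plain per-atom mean of its models, because a mean is reproducible
without an arbitrary model choice; model *k* can be selected instead, and
for divergent NMR ensembles the choice can move cross-RMSD values by a
few tenths of an Å. No outlier rejection or distance-cutoff trimming is
applied: the statistic is the plain RMSD over the stated region.

Ensemble precision follows the convention of NMR structure-statistics
tables: all models are iteratively superimposed onto the current mean,
the mean is recomputed, and the loop stops when the mean moves less than
1e-6 Å (cap 100 iterations; in practice 2-4 suffice). The reported value
is the mean ± sample (n−1) standard deviation of per-model RMSDs to the
converged mean. The iteration is order-independent to well below 1e-7 Å.

## Sequence identity

Global alignment is the Gotoh affine-gap dynamic program. It is written
in-package rather than delegated because the contract pins deterministic
tie-breaking (aligned pair, then gap consuming the first sequence, then
the second), which library aligners do not expose; scores are
cross-checked against Biopython's PairwiseAligner in the tests. Default
scoring is plain match/mismatch 1/0 with gap open −10 and extend −0.5 — a
deliberately rigid scheme chosen for reproducibility, not sensitivity;
for published region comparisons the structural correspondence should be
supplied explicitly rather than recomputed by alignment. Percent identity
counts strictly identical aligned pairs over non-gap columns in the
region (similar residues do not count), rounded half-up to one decimal.

## NOE restraints

Distance bins follow the four-range convention: strong 1.8–2.7 Å
(1.8–2.9 Å when an HN proton is involved), medium 1.8–3.3 Å (1.8–3.5 Å
HN), weak 1.8–5.0 Å, very weak 1.8–6.0 Å; the lower bound is always
1.8 Å. Pseudo-atom upper-bound corrections default to +1.0 Å (methyl),
+0.7 Å (non-stereospecific methylene) and +2.0 Å (aromatic ring) — values
in common NMR practice, configurable because conventions differ between
groups. Sequence-separation classes partition all residue pairs:
|i−j| = 0 intraresidue, 1 sequential, 2–4 medium-range, ≥5 long-range, so
per-class counts always sum to the total. Hydrogen bonds contribute two
distance restraints each (H–acceptor, donor-heavy–acceptor; default
targets 1.8–2.3 Å and 2.7–3.3 Å); side-chain dihedral restraints default
to ±30° about the rotamer center, while backbone φ/ψ widths must come
from chemical-shift analysis and are never predicted here. Only the
native TSV dialect is read bit-exactly.

## Chemical-shift perturbation

The combined amide shift change is Δδ = √(ΔδH² + (ΔδN/5)²); the 1/5
nitrogen scaling is fixed, not configurable, to prevent silent divergence
between datasets. Peaks are tracked from the assigned reference spectrum
across consecutive titration points by global minimum-cost one-to-one
assignment (scipy's Hungarian solver) on Euclidean distance in the scaled
plane — greedy nearest-neighbor mis-tracks slow crowded peaks, which is
why the global optimum is required and verified against brute-force
permutation search. A link longer than 0.25 ppm (scaled) marks the peak
as lost (exchange broadening); lost peaks are reported as missing, never
as zero. Perturbed-surface calling uses the final titration point with a
strict Δδ > 0.100 ppm rule and also grades residues into magnitude bins
(edges 0.100/0.200/0.300 ppm) for structure coloring.

## Heteronuclear NOE

NOE = I_sat/I_ref, with uncertainty from first-order quadrature
propagation of the per-spectrum noise standard deviations:
σ_NOE = |NOE|·√((σ_sat/I_sat)² + (σ_ref/I_ref)²). If only one noise level
is supplied it is used for both spectra. The propagation formula is a
choice — only the noise source is conventionally stated — and the
quantity is scale-invariant. Mobility flagging uses strict NOE < 0.5;
missing records (prolines, overlapped peaks) are never flagged.

## ITC one-site model

The simulator implements the Wiseman one-site model with per-injection
dilution tracked under the constant-volume perfusion convention:
[M]ᵢ = M₀(1−v/2)/(1+v/2) and [X]ᵢ = X₀·v/(1+v/2) for cumulative injected
fraction v, bound fraction from the binding quadratic, cumulative heat
Q = n·Θ·[M]·ΔH·V₀, and the displaced-volume midpoint correction added to
each finite difference. Two consequences worth knowing:

- Heat "conservation" (cumulative heat → n·M₀·V₀·ΔH) holds only in the
  limit of fine injections and early saturation. Free macromolecule
  displaced from the cell before it binds is real lost capacity: at the
  default design (equivalence near 10% cumulative dilution) the deficit
  is ~5%, and per-injection discretization of the midpoint correction
  adds a loss proportional to the injection fraction. The conservation
  test therefore uses a 1000:1 syringe:cell ratio with 500 × 1 µl
  injections, where the deficit stays under 0.5% for c = 5–500.
- At the default design the c value for the tightest interaction is ~2400,
  above the classical 1–1000 identifiability window; fitted Kd scatter is
  correspondingly skewed. The results object flags c outside 1–10⁴.

Fitting parameterizes (n, log₁₀Ka, ΔH, q₀); log-Ka keeps the search
well-scaled across eight decades. Initialization is deterministic: a
coarse grid over log₁₀Ka (3–12, step 0.25) with n = 1, exploiting that
the model is linear in (ΔH, q₀) at fixed (n, Ka), followed by
Levenberg-Marquardt refinement (lmfit) of all four parameters. Standard
errors come from the local quadratic approximation at the optimum; the Kd
error uses the delta method from the log₁₀Ka error. The first injection
is included by default with a `drop_first` escape hatch. Derived
thermodynamics use R = 1.9872×10⁻³ kcal/(mol·K) and default T = 293.15 K
(20 °C). Noiseless round trips recover parameters to better than 0.1%
across c = 5–500.

## Synthetic data: what it does and does not emulate

All generators are deterministic under a fixed seed, with one private
random stream per call.

- **Ensembles** are an idealized poly-alanine backbone (standard bond
  geometry via internal-coordinate chain extension; a strand–helix–strand
  pattern) plus iid Gaussian coordinate jitter. Real NMR ensembles have
  spatially correlated, restraint-driven heterogeneity concentrated in
  loops and termini; iid jitter tests the estimators' arithmetic, not the
  realism of NMR precision values. Under iid jitter the expected
  precision is √3·σ·√(1−1/m) for m models, which the tests use as an
  independent check.
- **Titrations** assume fast exchange: each site residue moves by
  f_bound·Δδ_max along a fixed random direction, with f_bound from the
  exact binding quadratic at 100 µM protein and ratios 0/0.25/0.50/1.00.
  Slow-exchange behavior is emulated only as peak disappearance.
  Defaults: five planted site residues at Δδ_max 0.3 ppm, background
  jitter 0.01 ppm per scaled dimension.
- **ITC thermograms** add iid Gaussian noise (default sd 2% of the
  largest heat) to the exact simulator output, at the default design
  (300 µM syringe, 2 ml of 30 µM cell, 25 × 20 µl, 20 °C). Real
  calorimetry has correlated baseline drift and injection-volume error,
  so recovery statistics here bound only the noise-driven component of
  Kd uncertainty.
- **Restraint lists** plant exact separation-class counts; **hetNOE
  profiles** plant mobile segments with levels clipped away from the 0.5
  decision line (rigid ≥ 0.55, mobile ≤ 0.45, defaults 0.80/0.30 with sd
  0.04) so planted truth is recoverable by construction — these test
  bookkeeping, not classifier robustness near the boundary.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
50 fit replicates per interaction for Kd recovery, 1,000 random point
sets for the superposition oracle, 100-residue titrations, 108-residue
hetNOE profiles, and 20-model ensembles of 15–30 residues. These sizes
give Monte-Carlo standard errors comfortably below the stated tolerances
while keeping the full suite in seconds.

## Known limitations

- No mmCIF input; single-letter chain semantics only; ligands and waters
  are not treated specially.
- Correspondences must be supplied; there is no structure-based alignment
  search, TM-score, or automatic core detection.
- The restraint reader's tolerant mode handles simple columnar layouts
  only; violation analysis against coordinates is out of scope.
- CSP-based Kd estimation is not implemented (Kd comes from ITC).
- The ITC module fits integrated heats; raw power traces and
  competitive/multi-site models are out of scope.
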