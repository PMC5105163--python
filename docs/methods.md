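# Methods

## Scope and model

`msmex` estimates the metastable thermodynamics and kinetics of a
biomolecular system from trajectory ensembles recorded under one or more
conditions (e.g. wild type and point mutants), and complements the
simulation-side picture with NMR-detected hydrogen/deuterium exchange in
the EX2 limit. The package assumes:

- dynamics that are Markovian on the analysis lag time, so a discrete-state
  transition matrix at lag τ is a faithful propagator (checked by implied
  timescales and the Chapman–Kolmogorov test);
- microscopic reversibility — all transition matrices are estimated under a
  detailed-balance constraint;
- that conditions to be compared share one conformational space, which is
  enforced operationally: TICA and the k-means microstates are fitted on
  the pooled data, and every condition is discretized with the same
  centers.

## Featurization and TICA

Features are all pairwise Cα–Cα distances over a residue selection
(condensed-matrix column order). The selection is geometric — residues
whose Cα lies within a cutoff (default 15 Å) of a center residue's Cα on a
reference frame — with explicit include/exclude overrides so a published
residue list can be reproduced exactly. The Cα-to-Cα rule is a declared
convention; the override mechanism makes the analysis independent of it.

TICA solves `C̄_τ v = λ (C₀ + εI) v` with mean-free covariances accumulated
per trajectory (sliding window; lagged pairs never cross trajectory
boundaries) and the symmetrized estimator `C̄_τ = (C_τ + C_τᵀ)/2`, which
guarantees real eigenvalues. The ridge ε defaults to `1e-6·tr(C₀)/d`
because pairwise distance sets are rank-deficient (a rigid fragment's
distances are redundant). Components are sorted by |λ|; signs are fixed by
making the largest-magnitude loading positive. Three components are kept
by default; the TICA lag defaults to the smallest MSM lag candidate and is
configurable — slow eigenvalues are insensitive to it well below the
slowest relaxation time.

## Markov model estimation

Counting is sliding-window at lag τ, per condition. The model is estimated
on the largest strongly connected component of the count graph (ties
broken by total counts, then smallest index). The reversible
maximum-likelihood transition matrix uses the standard fixed-point
iteration on symmetric edge weights,

    x_ij ← (C_ij + C_ji) / (c_i/x_i + c_j/x_j),

iterated until the stationary distribution moves < 1e-12 (max norm); then
`T_ij = x_ij/x_i`, `π_i = x_i/Σx`. The test suite verifies detailed
balance to 1e-10 and agreement to 1e-6 in T with an independent
quasi-Newton constrained-likelihood maximizer on random count matrices.

Spectral quantities use the symmetrized similarity transform
`D^{1/2} T D^{-1/2}` (D = diag π), so eigenvalues are real by
construction; implied timescales are `−τ/ln λ_i`. The default analysis lag
is chosen where consecutive implied timescales change by < 10%.

PCCA++ memberships come from the dominant right eigenvectors by simplex
vertex identification (successive farthest-point orthogonalization),
`χ = ψ A` with `A` the inverse of the vertex rows, clipped to [0, 1] and
row-renormalized. Adjacent-eigenvalue degeneracy (< 1e-10) across the cut
is rejected with a suggestion to change the number of states. Crisp
assignments are argmax memberships; coarse populations are crisp sums of π.

## Thermodynamics, rates, uncertainty

Free energies are `ΔG_m = −RT ln(Π_m/Π_ref)` with R = 0.00831462
kJ K⁻¹ mol⁻¹ and T = 310 K by default; the most populated state is the
reference. Cross-condition comparisons match metastable states by Jaccard
overlap of their crisp microstate sets on the shared discretization
(overlap < 0.2 → unmatched; exact ties are an error) and report the
population fold-change and `ΔΔG = RT ln(fold)`.

Coarse rates are defined as 1/MFPT with the mean first-passage time from
the standard linear system on T, π-weighted over the source set. This is a
reporting convention, not a rate-theory claim; for timescale-separated
two-set partitions it obeys flux balance `Π_m k_mn = Π_n k_nm`, which the
tests check.

All uncertainties are trajectory-level bootstrap: trajectories resampled
with replacement, k-means centers and microstate→metastable map held
fixed, counts and the reversible T re-estimated per replicate. 1σ
intervals are the 15.87/84.13 percentiles (asymmetric lower/upper bounds);
replicates that lose a metastable state are dropped and counted.

## Interaction analysis

An interaction between two heavy-atom groups exists in a frame if any
donor–acceptor pairing satisfies the hydrogen-bond thresholds
(donor–acceptor ≤ 3.5 Å, hydrogen–acceptor ≤ 2.5 Å, D–H···A ≥ 120°, all
inclusive) or the heavy-atom minimum distance is ≤ 4.0 Å. These defaults
are conventional values and fully configurable. State-conditional
frequencies use a two-level bootstrap: per replicate, trajectories are
resampled, the MSM is re-estimated (fixed discretization), 100 frames are
drawn from the state with probability proportional to the updated
stationary weight of each frame's microstate (inverse-count normalized),
and the presence fraction is recorded; 50 replicates give mean ± SD.
Differences between states are flagged when
`|mean_A − mean_B| > z·sqrt(SD_A² + SD_B²)` (z = 2 default).

## Per-state observables

Flip probability is the state-conditional fraction of frames whose
four-atom dihedral falls in a configurable "flipped-out" interval — the
interval is a user decision because "flipped" is a visual, not numeric,
category. Helicity uses the O(i)···N(i+4) ≤ 3.5 Å register criterion
rather than dihedral windows, which is robust for the pseudo-backbones of
the synthetic generator (an ideal α-helix built at φ=−57°, ψ=−47° has
O–N(i+4) ≈ 3.1 Å; an extended strand ≈ 11 Å). Solvent contacts count
solvent oxygens within 3.5 Å; topologies without solvent fall back to a
flagged proxy (exposure score `1/(1+n_close)` from non-self heavy-atom
crowding). Observable uncertainties use the same trajectory bootstrap as
the MSM quantities.

## H/D exchange (EX2)

Signal decays S/N(t) are classified before fitting: never above 3× the
noise level → "fast" (exchanged within the ~35 min dead time; half-life
reported "<15 min"); total decay < 5% over the horizon → "stable"
(">4000 min"); otherwise `A·exp(−k_obs t)` is fitted by least squares with
A, k > 0 and no baseline offset — the fully exchanged signal falls into
the noise, which is exactly what the "fast" classification encodes.
Series with gross non-monotone outliers (> 6σ from the fit) are excluded,
as overlapping peaks are in real spectra. Intrinsic rates are supplied as
an external table and averaged arithmetically over positions {i−1, i, i+1}
(the i±1 convention). Then `K_ex = k_obs/k_int`, `P = K_ex⁻¹`, and
`ΔG_op/cl = −RT ln K_ex`, positive when the closed (protected) state is
favored; P < 1 is reported with an "unprotected" flag. CSP combines shifts
as `sqrt(Δδ_H² + (0.14·Δδ_N)²)`.

On the default acquisition grid (35-min spacing, 60-h horizon) the
Fisher information limits rate precision to ≈1–5% relative std at S/N 50
across the fittable window 1e-4–1e-2 /min; the recovery tests therefore
assert unbiasedness and RMS error within 5% across the full two decades
and strict per-realization 5% in the central decade.

## Restraints

The restraint energies are `E_com = k_com|r_com − r_ref|²` and
`E_in = k_in(I_xy² + I_xz² + I_yz²)` with `I_ab = −Σ w x_a x_b` in
COM-centered coordinates — no ½ prefactors, and unit weights by default:
the geometric (unweighted) tensor is the convention under which the
published force-constant units (kcal mol⁻¹ Å⁻² and kcal mol⁻¹ Å⁻⁴) are
dimensionally consistent. A mass-weighted mode exists but is off by
default. Gradients are analytic; the COM-shift chain-rule terms of the
inertia gradient vanish identically because centered coordinates have
zero weighted mean. The periodic-image monitor reports the minimum
distance to the 26 neighbor images and flags distances below twice the
electrostatic cutoff (2 × 9 Å). The demonstration integrator is
first-order overdamped Langevin on a rigid body (COM + orientation only)
— sufficient to show that the restraints pin the off-diagonal inertia and
suppress rotational diffusion, with no thermodynamic claims.

## Synthetic data generator

The generator is the ground-truth source for every recovery test. Latent
dynamics are a discrete-time Markov chain at the frame interval: a
nearest-neighbor Metropolis chain has any requested stationary
distribution by construction, and uniform rescaling of its off-diagonal
part sets the slowest relaxation time exactly without breaking detailed
balance — so populations (including a ~1.6% rare state) and the exchange
time are plantable and analytic. Structures are emitted as per-state
archetypes plus AR(1) Gaussian noise (default σ = 0.10 Å, correlation
time 2 frames; the autocorrelation keeps TICA's fast modes nontrivial —
pure white noise would make the time-lagged problem degenerate). The
default three-state pseudo-complex (155 atoms: two receptor chains, one
peptide) encodes the structural signatures of interest — a helix region
built from φ/ψ by an internal-coordinate chain builder that is folded or
unfolded per state, a four-atom flip dihedral, and a peptide that shifts
away from the receptor in the rare state. σ = 0.10 Å gives > 99% per-frame
class fidelity against the 3.5 Å helicity criterion (0.41 Å margin)
while the states differ by tens of Å in feature space.

What the generator does **not** emulate: force-field energetics, solvent,
real MHCII geometry, aging/convergence pathologies of long MD, or
non-Markovian memory beyond the AR(1) emission noise. Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimators, not the realism of any particular simulation.

## Problem sizes and numerical choices

The recovery studies run at 5×10⁵ frames (50 trajectories × 10⁴ frames),
k = 100 microstates, TICA lag 5, MSM lag 25 frames, 50 bootstrap
replicates — sizes at which the rare state contributes ~8×10³ frames and
~5×10³ exchange events, enough for percent-level population recovery, and
which complete in minutes on one CPU. k-means uses k-means++ with the run
seed, tol 1e-6, ≤ 500 Lloyd iterations. The reversible MLE iterates to
1e-12 in π (≤ 1e6 sweeps). Eigen-decompositions are in symmetrized form.
Every stochastic routine takes an explicit seed and is bit-reproducible.

## Known limitations

- PCCA++ uses the inner-simplex construction with clipping; for poorly
  separated spectra a full membership optimization could differ.
- The 1/MFPT "rate" convention is not a reaction-rate theory estimate.
- CK-test pass/fail depends on the 2σ bootstrap band; with few
  trajectories the band is wide and the test is permissive.
- The H/D-exchange fitter assumes EX2 throughout; EX1 or mixed regimes
  are out of scope, as is intrinsic-rate prediction from sequence.
- DCD/XTC reading requires the topology to be supplied separately (PDB);
  no remote structure fetching.
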