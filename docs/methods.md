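# Methods

This note documents the models, conventions and numerical choices behind
`lcfingerprint`, and what the synthetic-data validation does and does not
demonstrate about real data.

## The system and its representation

The object of study is a free immunoglobulin light-chain homodimer: two
identical chains, each with a variable domain (VL, residues 1–109 by
default), a linker/hinge (110–120) and a constant domain (CL, 121–214).
Residue ranges are configurable per chain (`DomainArchitecture`); defaults
follow the common author numbering in which the hinge spans residues
110–120.  Ensembles are stored densely: one shared atom table (chain,
residue, atom name, element, mass) plus an `(n_frames, n_atoms, 3)`
coordinate array in nm, and one statistical weight per frame (non-negative,
summing to 1 within 1e-9).  PDB files are read and written in Å through
biotite and converted at the boundary; the internal length unit is nm
because the distance thresholds and R_g values of interest are naturally
quoted in nm.

Masses default to standard atomic masses from the element field (inferred
from atom names by the PDB parser); an unrecognized element is an error
rather than a silent guess, because every center of mass downstream is
mass-weighted.

## Collective variables

Per frame the package computes

* **θ, the elbow angle** — the angle at the hinge vertex
  H = COM(linker residues of both chains) between the vectors
  H → COM(VL dimer) and H → COM(CL dimer).  Range [0, π]; a straight
  molecule reads θ ≈ π.  The vertex-at-hinge construction is a choice:
  the published analyses illustrate but do not define their atom groups, so
  thresholds could shift by a few hundredths of a radian under other
  constructions.  Arm vectors shorter than 1e-6 nm raise a degeneracy error.
* **d_VC** — |COM(VL_A ∪ VL_B) − COM(CL_A ∪ CL_B)| in nm.
* **d_CC, d_VV** — distances between the two CL (respectively VL) domain
  centers of mass, the coordinates of the state-conditioned interface maps.

All COMs are mass-weighted over all atoms of the selection (PLUMED-style);
a `ca_only` switch restricts to Cα for sensitivity checks.  All CVs are
rigid-transform invariant and symmetric under chain relabeling; both
properties are asserted in the test suite (100 random rigid transforms,
tolerance 1e-9).

## Reweighting and errors

Well-tempered metadynamics deposits a final bias V_i per stored frame; the
unbiased ensemble is recovered with the last-bias estimator
w_i ∝ exp(+V_i / k_B T), computed max-shifted for overflow safety, with
k_B = 0.0083144621 kJ·mol⁻¹·K⁻¹ and T = 310 K by default.  The sign
convention is exposed (`sign=+1` default) since deposited tables differ.
Weight degeneracy is reported as the Kish effective sample size 1/Σw².

Statistical errors of any weighted average use contiguous block averaging
(default 5 blocks, frame order preserved to respect autocorrelation):
block means are computed with block-local weight renormalization, combined
with block-weight weighting, and the error is the weighted standard error
over blocks.  With uniform weights the estimate reduces exactly to the
plain weighted mean (asserted).

## State partition and the fingerprint call

The four-state partition uses only the printed thresholds: θ > 2.5 rad is
"straight"; d_VC < 3.4 nm is compact (G), 3.4–4.1 nm intermediate (L_S),
> 4.1 nm extended (H); everything with θ ≤ 2.5 rad is bent (L_B)
regardless of distance.  Boundary closure is a measure-zero convention:
θ = 2.5 belongs to L_B, d = 3.4 and d = 4.1 belong to L_S, matching the
strict inequalities that define G and H.

Populations are percent weighted sums with block errors.  Two replicate
runs are combined per state as the mean of percents with error
max(half |difference|, propagated block error): when independent replicates
disagree beyond their internal errors, the spread is the honest error.

`fingerprint_call` compares the H-state band against two configurable
thresholds: AL-like when the upper error bound H + σ reaches 5 %, MM-like
when the whole band sits below 1 %, otherwise indeterminate.  Using the
upper bound is deliberate: a chain whose H population is statistically
compatible with the amyloidogenic band (e.g. 4.8 ± 0.5 %) should be
flagged, while the MM call requires the band to exclude 1 %.  Note the
asymmetry consequence: a single very-long i.i.d. replicate of a chain with
a true H population just below 5 % has a tiny Monte-Carlo error and is
reported indeterminate — the AL call of such borderline chains comes from
the two-replicate error, which reflects sampling quality, not only n.

## Free-energy surfaces

F(bin) = −k_B T ln(P/P_max) on uniform 2-D grids (default 60×60 over the
data range padded 5 %; binning is a presentation choice, not part of the
statistic).  Empty bins carry +inf and a mask, never a finite fill value;
the occupied minimum is exactly 0.  F depends only on weight ratios
(uniform rescaling invariance is property-tested), and refining bins 2× on
a smooth density moves occupied-bin F by ≤ 0.5 kJ/mol (asserted on a broad
Gaussian).  Isolines are metadata at multiples of 2 k_B T.  At 310 K,
2 k_B T = 5.15497 kJ/mol; the conventional printed value is 5.16 (the
value is quoted to three decimals, 5.155, and then rounded half-up), and
`isoline_spacing_printed` reproduces that convention while
`isoline_spacing_kJmol` returns the exact number.

State-conditioned surfaces over (d_CC, d_VV) renormalize the weights within
the state subset; an unpopulated state is an explicit error.

## RMSF and Ramachandran occupancy

RMSF is computed on Cα atoms of one domain of one chain: every frame is
least-squares superposed (Kabsch, via scipy Rotation) onto the weighted
mean structure using a fit core (default: all residues of the domain;
flexible CDR loops can be excluded via config since canonical renumbering
is out of scope), iterating mean → fit → mean twice.  On well-conditioned
test ensembles further iterations change the profile by < 1e-4 nm
(asserted).  RMSF_r = sqrt(Σ_i w_i |x_{i,r} − ⟨x_r⟩|²).  Chain profiles are
averaged arithmetically over the two equivalent chains, then over
replicates, with provenance recorded.

The left-handed α-helix occupancy of a residue is the weighted fraction of
frames with backbone dihedrals in 0° < φ ≤ 120°, −60° ≤ ψ ≤ 90°.  The
region bounds are a documented convention — the αL basin has no universal
numeric definition — and any exhaustive rectangular partition of the
Ramachandran torus sums to occupancy 1 (asserted).  Dihedrals follow the
IUPAC sign convention (cross-checked against biotite).

## SAXS

Back-calculation is a coarse Debye sum,
I(q) = Σ_jk f_j f_k sin(q d_jk)/(q d_jk), with one scattering center per
residue at the residue COM and effective weight f equal to the residue
electron count (an `atomic` representation with atomic numbers is also
available).  This reproduces the global-shape observables — R_g, low-q
intensity, ensemble-average trends — but deliberately omits the hydration
shell and excluded-volume terms of crysol-class predictors, so *absolute*
χ² values against experiment are systematically different; comparisons of
χ² between ensembles remain meaningful.  Ensemble curves are weight
averages of per-frame curves.

Scale c (and optional flat background b) minimizing
Σ((I_exp − c·I_calc − b)/σ)² are closed-form weighted least squares; χ² is
reduced by (N − n_params) since the convention is otherwise ambiguous.
The calculated curve is linearly interpolated onto the experimental grid
and never extrapolated.

The Guinier fit is an iterative weighted linear regression of ln I on q²
(weights (I/σ)² from error propagation, uniform when σ is absent).  The
window starts at the lowest ⌈n/10⌉ + 5 points and is shrunk (never below 5
points) until q_max·R_g ≤ 1.3 at the fitted R_g.  The 1.3 limit is treated
as a validity ceiling, not a target: extending the window up to the
ceiling provably biases R_g upward on globular shapes (for a homogeneous
sphere, ln I = −q²R_g²/3 − 0.00286 (qR)⁴ + …, and a fit filling the window
to q·R_g = 1.3 overestimates R_g by ≈ 1.8 %, versus ≈ 0.4 % for the
conservative window).  The fitted standard error of R_g propagates from
the slope covariance.

## Synthetic ensembles

The generator is the statistical stand-in for deposited trajectories; its
defaults define the validation conditions.  Per frame a state is sampled
i.i.d. from the target populations (default 62.0 / 33.0 / 0.2 / 4.8 %, a
borderline amyloidogenic profile); (θ, d_VC, d_CC, d_VV) are drawn from
per-state truncated Gaussians honoring the partition bounds (means
L_B (2.1 rad, 3.1 nm), L_S (2.8, 3.7), G (2.8, 3.1), H (2.8, 4.4), σ of
0.10–0.15; the H state's d_CC mean is shifted +0.4 nm outward, emulating
the looser constant-domain interface of the extended conformation).
Geometry is realized exactly before jitter: the hinge at the origin, dimer
COMs in the xy-plane at arm length d_VC/(2 sin(θ/2)) separated by θ, each
dimer split along z by d_CC or d_VV — so ground-truth labels and CVs are
exact by construction (verified to 1e-9 nm at zero jitter).  Domains are
rigid 50-bead uniform balls of radius 1.0 nm (11 beads per linker, radius
0.3 nm), one residue per bead; per-bead Gaussian jitter (default 0.05 nm)
adds realism without moving COMs appreciably.  Weights are uniform or
Boltzmann weights of a Gaussian bias (σ = 2 kJ/mol default).  A single RNG
stream seeded once makes output byte-reproducible.

What this validates: estimator correctness (classification, populations,
errors, FES, RMSF, Guinier/χ² machinery) under known truth.  What it does
not: force-field realism, autocorrelated sampling, sequence-specific
effects, side-chain packing, or hydration-sensitive SAXS features — results
on real ensembles inherit those caveats from the simulations, not from this
package.

Validation problem sizes were chosen to resolve the statistics of interest:
population recovery uses 20 000 frames per replicate (3σ multinomial bands
of ±0.45 % at 62 % and ±0.15 % at 4.8 %), two replicates per reference
chain mirroring the two-independent-simulation protocol of the study
design; per-replicate targets average to the published per-chain columns
with half-ranges equal to the published errors.

## Degenerate inputs and tie-breaks

Empty selections, unpopulated states, fewer frames than blocks, non-finite
CVs, non-positive temperatures, all-zero σ, rising low-q curves ("no
Guinier regime") and chain-terminal φ/ψ are explicit errors with the
offending frame/row named where applicable.  Elbow arms shorter than
1e-6 nm are degenerate.  Weight tables bind to PDB models by order (the
deposited COLVAR-style convention), not by id.  q defaults to Å⁻¹ with an
explicit `nm^-1` override.

## Known limitations

* The elbow-angle atom groups are a convention; absolute θ values near the
  2.5 rad threshold can shift slightly under other published constructions.
* Absolute SAXS χ² is not comparable to hydration-aware predictors.
* Coordinate R_g is mass-weighted while SAXS measures an electron-density
  weighted R_g; at the coarse-grained level used here the difference is
  within the Guinier tolerance (≤ 2 %, asserted on dumbbell fixtures).
* Binary trajectory formats (XTC/DCD) and mmCIF are not parsed; multi-model
  PDB plus TSV tables are the interchange formats.
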