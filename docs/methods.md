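# Methods

This note documents the models and estimators implemented in
`allostate`, the defaults and why they were chosen, the numerical
edge-case handling, and what the synthetic validation does and does not
establish about real molecular-dynamics data.

## Coordinate conventions and units

Coordinates are Ångström, energies kcal/mol, temperature Kelvin, with
k_B = 0.0019872041 kcal/(mol·K) and the Coulomb constant
332.0637 kcal·Å/(mol·e²). Residues are 0-based internally; file formats
carrying their own numbering (PDB `resSeq`) keep the original numbers
for reports and round-trips, and residue ranges given on the command
line are 1-based inclusive, the convention users see in PDB files.
Chain breaks are flattened: a residue is a (chain, resid) pair mapped to
a single 0-based index in file order.

## Superposition, RMSD, RMSF

Rigid-body fits use the Kabsch SVD construction with the determinant
sign correction, so the returned rotation is always proper even for
near-planar or mirror-related inputs. Fits are unweighted over the
selected atoms (Cα by default); there is no mass weighting or per-domain
block fitting.

`rmsd_series` reports the per-frame RMSD versus a chosen reference
frame after superposition (`fit=False` is available for frames that are
already aligned, and is the reading under which the textbook one-atom
closed forms hold exactly — the optimal translation alone always
absorbs 1/N of a single-atom displacement, so fitted single-atom RMSDs
are smaller than the naive value).

`rmsf_per_residue` superposes all frames onto a reference and reports
`RMSF_i = sqrt(⟨|r_i − r_ref,i|²⟩)`. The default reference is the
time-mean structure (computed by aligning to frame 0, averaging, and
re-aligning to the mean — one iteration, which is where the fixed point
is reached for all practical purposes); `reference_mode="initial"`
measures about the first-frame positions instead, since "fluctuation
about the original position" is a reading some studies use. Both are
exposed because the choice changes values whenever the mean and initial
structures differ; the default is the dominant convention.

## DCCM

The cross-correlation is the scalar (3D dot-product) form
`C_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)` over one selected atom
per residue, with Δr measured from the time mean after superposition
onto the mean (same iterated-once scheme as the RMSF). Per-axis
correlation variants are deliberately out of scope. Residues with zero
fluctuation make C undefined; their rows are NaN and reported, never
silently zeroed. The display mask removes entries with |C| strictly
below the threshold (default 0.3): the boundary value itself is kept,
because the masking rule is phrased as ignoring values *less than* the
threshold. `analytic_dccm_from_covariance` computes the same quantity
exactly from 3×3 blocks of a model covariance
(`C_ij = tr Σ_ij / sqrt(tr Σ_ii · tr Σ_jj)`) and is the oracle used
throughout the tests.

Superposition interacts with the DCCM: fitting removes the apparent
rigid-body component of sampled fluctuations, so sampled and
model-covariance DCCMs agree only while fluctuation amplitudes are
small compared to the structure size. The validation systems are
chosen inside that regime (see "Synthetic generators" below).

## Residue network and communities

Edges join residue pairs whose minimum inter-atom distance is within
4.5 Å in at least 75% of frames (both boundaries inclusive:
"within ... for at least"). With one-bead-per-residue models this is a
Cα-distance criterion, flagged with a warning since heavy-atom minimum
distance is the stricter definition. Sequence neighbours (|i−j| ≤ 1)
are excluded by default — covalent contacts otherwise dominate every
path — and the exclusion is configurable down to 0.

Edge length is d = −ln|C| (natural log; any other base rescales all
distances uniformly and cannot change shortest paths, betweenness, or
communities). Edges with C = 0 have infinite length and are dropped
with a report.

`floyd_warshall_paths` is a direct Floyd–Warshall implementation that
also counts co-optimal shortest paths (each path counted once, at its
highest-numbered intermediate vertex); ties in length are detected with
a 1e-12 relative tolerance. Path counting assumes strictly positive
edge lengths, which −ln|C| guarantees for |C| < 1.

Edge betweenness credits each connected node pair one unit, split
equally over its co-optimal shortest paths (the standard fractional
convention, delegated to networkx's Brandes implementation). An
alternative integer mode — a full unit per co-optimal path, so the
credit from a pair is the *number* of optimal paths through the edge —
is available behind a flag, since "the number of paired optimal paths"
admits both readings; the fractional mode is the default and the one
all defaults and tests use.

Girvan–Newman removes the current maximum-betweenness edge, recomputing
betweenness after every removal, until no edges remain; ties are broken
by the lexicographically smallest (i, j) pair so runs are deterministic.
The reported partition is the connected-components partition of maximum
Newman–Girvan modularity over the whole removal trace, including the
initial partition (so a graph that should not be split, e.g. a clique,
reports a single community). Modularity is scored on the original graph
with |C| as the affinity weight — the distance weight is a cost and
would invert the meaning of "strong" edges. Communities smaller than
three residues are removed from the report and returned separately, and
inter-community connectivity is the sum of original-graph edge
betweenness over edges crossing each community pair.

## PCA and free-energy landscapes

PCA diagonalises (via SVD of the centered coordinate matrix) the 3n×3n
covariance of the superposed Cartesian coordinates of the selected
atoms. Eigenvalues are Å² and equal the variance of the corresponding
projection; eigenvectors are orthonormal rows. Porcupine export scales
eigenvector components into per-atom displacement vectors anchored at
the mean structure. The landscape is a 2D histogram of (PC1, PC2)
projections converted through `ΔG = −k_B T ln(P/P_max)`; normalising by
the most-populated bin puts the global minimum at exactly zero and
empty bins are NaN rather than infinite.

## Markov state models

Microstates come from k-means (k-means++ seeding, fixed seed, default
k = 100 and 100 iterations — the preset used for kinase-ensemble MSMs;
the validation chains are discrete and skip clustering). Transition
counts use the sliding window at the chosen lag and never cross
trajectory boundaries. The lag is specified in frames; a nanosecond
mapping applies only when the frame stride time is known (a 60 ns lag
is the documented preset from the application domain, not a default).

Estimation is reversible by default: counts are symmetrized,
(C + Cᵀ)/2, then row-normalized, which satisfies detailed balance
exactly with π proportional to the symmetrized row sums. This is a
deterministic approximation to the iterative reversible
maximum-likelihood estimator; at the 10⁵-step sample sizes used here
the difference is far below the reported error bars, and determinism is
worth more to a test suite than the last decimal of likelihood. States
without transitions are trimmed to the largest connected set (weighted
by counts) with a report.

Implied timescales are `t_i(τ) = −τ/ln λ_i(τ)` with eigenvalues
computed through the symmetric similarity transform
`D^(1/2) T D^(−1/2)` (real spectrum guaranteed for reversible T);
non-positive eigenvalues yield NaN, marked rather than dropped. The
Chapman–Kolmogorov test compares `T(τ)^f` against a model re-estimated
at `f·τ`, both projected onto PCCA+ macrostate sets with the base
model's stationary weights.

PCCA+ takes the leading m right eigenvectors, finds the m rows spanning
the largest simplex (successive orthogonalization vertex search), and
inverts the vertex matrix to get fuzzy memberships, clipped to [0, 1]
and row-normalized. This is the inner-simplex construction without the
subsequent constrained optimization refinement; for metastable systems
with a clear spectral gap — the regime in which macrostate analysis is
meaningful at all — the refinement changes memberships negligibly,
and the planted-block tests confirm exact crisp recovery. Macrostate
populations are reported both crisply (Σπ over argmax members) and
membership-weighted.

Frame pools for representative selection take only trajectories with
strictly more than 50% of frames in the macrostate ("more than 50%" is
read as a strict inequality; a 50/50 trajectory is excluded). The
representative conformation maximises the summed similarity
`Σ_j exp(−d_ij/d_scale)` where d is the pairwise Kabsch RMSD matrix of
the pool and d_scale its standard deviation. The summed aggregation is
chosen because a per-pair score must be reduced somehow to rank frames;
summing rewards centrality and is robust to single outliers (a max-min
alternative was considered and rejected as less robust). A pool of
identical frames (d_scale = 0) degenerately returns the first frame
with a log notice.

## Energy coupling

Pair interaction energies can be supplied directly (e.g. from an
MM-GBSA per-pair decomposition, as tab-separated
`res_i res_j e_eel e_vdw g_pol g_sas`) or estimated from an ensemble
with a deliberately simple nonbonded model: Coulomb with a uniform
dielectric (default 1.0) and Lennard-Jones with Lorentz–Berthelot
combination, frame-averaged, for pairs separated by at least three
residues in sequence (|i−j| ≥ 3). Polar-solvation and surface terms are
accepted as precomputed columns (default 0) — implicit-solvent
machinery is out of scope — and the internal bonded energy between
*distinct* residues is zero by definition. A distance-dependent
dielectric was considered and rejected: it adds a parameter without
changing what the classifier consumes (relative shifts).

Classification works in ΔE space: ΔE_p = E_holo,p − E_apo,p, with μ and
σ the mean and population SD (ddof = 0) of all ΔE. Group a is
|ΔE−μ| ≤ σ (closed), b is σ < |ΔE−μ| ≤ 3σ (closed above), c is strictly
beyond 3σ — "at least three standard deviations beyond the mean" read
as the strict exterior of the 3σ band. Classification is invariant
under positive affine maps of ΔE (property-tested), so the choice of
energy zero or overall scaling cannot change groups. The bands are
drawn in ΔE space, not in the apo/holo scatter plane; the scatter
export provides both per-pair (E_apo, E_holo, group) rows and the μ±σ,
μ±3σ boundaries for rendering. The coupling fraction is
N_c/(N_b+N_c); with N_b+N_c = 0 it is defined as 0 and flagged
degenerate (no shift signal to measure), and the coupled flag is a
strict inequality at the threshold (default 0.25), so a fraction of
exactly 0.25 is *not* coupled. σ over fewer than 10 pairs triggers a
warning, not a failure. "Coupling score" and "coupling fraction" are
treated as synonyms; the code says fraction.

## Synthetic generators and what the validation shows

**Elastic-network ensembles.** Springs (i, j, k) build the
anisotropic-network Hessian `H = Σ k·(û ûᵀ)` on the unit bond vectors;
the fluctuation covariance is `k_B T · H⁺`, with the null space removed
by eigenvalue thresholding at 1e-8 relative to the largest eigenvalue.
Frames are sampled i.i.d. from that Gaussian rather than by Langevin
time-stepping: the equal-time covariance — all that DCCM, RMSF,
networks and PCA consume — is then exact by construction, and time
correlation for MSM testing comes from the discrete chain generator
instead. A disconnected spring graph is rejected up front (more rigid
null modes than the six of a connected 3D body); geometrically
degenerate but connected layouts simply have additional soft modes
removed by the threshold. Validation chains use consecutive springs
only (pure stretch networks, ~1 Å amplitudes at 300 K), keeping
fluctuations small against the structure so the superposed sampled
DCCM tracks the analytic one to <0.01 at 10⁵ frames; heavily braced
chains were rejected as validation fixtures because their soft bending
modes reach amplitudes where the rigid-body fit itself reshapes the
covariance, which is a property of the DCCM definition, not an
estimator error.

The two-domain system plants community ground truth: two compact
10-bead clusters (pseudo-random geometry under a fixed construction
seed, ~3 Å bead spacing), all intra-domain pairs within 6.5 Å sprung at
k = 10 kcal/mol/Å², one weak k = 0.5 bridge between two beads pulled to
~4 Å at the interface, at 300 K. These values put intra-domain contacts
comfortably inside the 4.5 Å/75% occupancy criterion and make
inter-domain correlation weak, so the planted partition is the
modularity optimum; 20 000 frames give stable occupancies.

**Markov chains.** The planted-metastable chain has 3 blocks of 2
microstates with total in-block probability 0.98 per step (uniformly
split) and 0.02 leak, giving a slow timescale t₂ ≈ 33 steps — long
enough to separate cleanly from the fast intra-block relaxation,
short enough that 10⁵ steps contain thousands of inter-block events
for tight estimation. The Chapman–Kolmogorov counterexample is a
3-state hidden chain lumped to 2 observed states whose
near-deterministic hidden cycle makes the lumped dwell-time
distribution sharply non-geometric; its CK deviation (~0.15 at factor
2) is an order of magnitude above the pass level of true chains
(~0.001), so the test discriminates rather than straddles.

**Energy tables.** Apo energies are N(μ_bg, σ_bg²); holo adds fresh
N(0, σ_bg²) noise per pair plus `shift·σ_bg` for planted outliers
(defaults: 200 pairs, 10 outliers at 10σ). The returned ground-truth
labels are recomputed from the *realized* ΔE sample by the same band
rule the classifier uses, so label recovery is checked exactly —
including the background pairs that land in group b by chance — rather
than against an approximate intention.

**What this does not show.** The generators produce Gaussian,
harmonic, i.i.d.-in-time (ensembles) or perfectly Markovian (chains)
data. Passing tests demonstrate that the estimators compute their
definitions correctly and recover planted structure under realistic
noise; they do not demonstrate robustness to anharmonicity, slow
non-Markovian memory, force-field error, or sampling heterogeneity of
real trajectories. Problem sizes (≤ 20 beads, 10⁵ frames or steps) are
chosen so the full suite runs in well under a minute per stage on one
CPU while keeping statistical errors several-fold below every
tolerance tested.

## Reproducibility

Every stochastic step takes an explicit integer seed
(`numpy.random.default_rng`); the pipeline manifest records package and
library versions, the seed, all stage parameters, and SHA-256 checksums
of inputs and outputs, and deliberately contains no timestamps so that
two runs under the same seed are byte-identical — which is itself a
tested property.
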