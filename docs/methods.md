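# Methods

This note records the models, conventions, and numerical choices behind
`hjdimer`, and what the synthetic tests do and do not establish about
real MD data.

## Units and input assumptions

All lengths are nm internally; PDB coordinates (Å) are converted once at
the read boundary and never again. Times are ps. Residue numbering is
taken verbatim from the input file (1-based), because contact-map labels
must match the deposited numbering scheme (central bases 11–16 of each
26-residue strand). Input coordinates are assumed whole-molecule and
unwrapped: the package performs no periodic-boundary handling, and
distances computed from wrapped trajectories will be wrong. Unwrap before
analysis.

Two trajectory formats are supported: multi-model PDB (one MODEL per
frame; frame spacing must be supplied, since PDB models carry no time),
and a plain-text frames format (`"natoms dt_ps"` header, then one
`x y z` line per atom per frame, written at `%.17g` so write/read is
bit-identical). Binary MD formats are deliberately out of the core; the
reader contract is small enough that adapters can wrap it.

## Transition-dipole geometry

Each dye is reduced per frame to two end points r and s: centroids of
configurable atom-name selections. The default selection is the two
indolenine-ring nitrogen atoms (one per heterocycle), since a cyanine's
S0→S1 transition dipole runs along the polymethine long axis between the
heterocycles; any selection can be substituted in the dye config. The
dipole direction is (r−s)/|r−s|, the center is the midpoint (r+s)/2 (not
mass-weighted — the relevant center is that of the transition dipole
vector, not of the nuclei), and the dye length is l = |r−s|. The dipole
magnitude μ is treated as constant per dye (defaults: TD-DFT values
15.35 D for Cy5, 15.57 D for Cy5.5); bending/stretching-induced
fluctuations of μ are not modeled.

The orientation factor κ = μ̂_m·μ̂_n − 3(R̂·μ̂_m)(R̂·μ̂_n) is stored
*signed*; |κ| is taken at presentation time. κ is invariant under rigid
motion, symmetric in argument order, flips sign when exactly one dipole's
end labeling is swapped, and satisfies |κ| ≤ 2 (extremes: collinear
parallel dipoles κ = −2; parallel-stacked κ = +1; orthogonal κ = 0).

## Extended-dipole coupling

The coupling is the screened Coulomb interaction of the two charge pairs
±q_i = ±μ_i/l_i placed at the dye ends:

    J = J0 · [1/|r_m−r_n| + 1/|s_m−s_n| − 1/|r_m−s_n| − 1/|s_m−r_n|]
    J0 = μ_m μ_n / (4π ε0 n² l_m l_n)

Note the units: J0 is energy × length (reported in meV·nm); the bracket
has units of 1/length. Quoted "J0 in meV" values in the literature
usually fold a reference distance in; here the factorization is kept
dimensionally explicit. Internally the computation is SI
(Debye → C·m via 1 D = 10⁻²¹/c; scipy's ε0), converted to meV once.

Screening: only the n² division of Eq.-style J0 is applied, with
n = 1.33 (water at optical frequencies) by default and configurable; no
local-field correction factors.

Sign convention: +q at r, −q at s. A parallel-stacked pair has J > 0; a
collinear head-to-tail pair has J < 0. Summaries and heatmaps report |J|.

A point-dipole form J = κ μ_m μ_n / (4π ε0 n² R³) is provided purely as
the limiting-case cross-check: tests verify <0.1% agreement at
R = 100·l and monotone convergence along R/l ∈ {10, 30, 100}, and that
at contact-scale separations the extended form is smaller in magnitude
than the point form for stacked geometry (charge smearing saturates the
interaction). The per-frame extended-dipole J uses each frame's actual
dye lengths, so l fluctuates with the coordinates while μ stays fixed.

## Frame selection

`select_frames(traj, burn_in, stride)` keeps frames with t ≥ burn_in at
a stride that must be an integer multiple of the frame spacing
(tolerance 10⁻⁹ relative). The production bookkeeping this reproduces:
1 μs written every 10 ps (100001 frames), 100 ns burn-in, 100 ps
orientation stride → 9001 observations per trial; 500 ps contact stride
→ 1801 frames per trial.

## Contact maps

Groups: six central bases (window 11–16 inclusive, configurable) of each
of the four strands, plus one group per dye — 26 groups for the standard
system. A dye residue inside the window is never double-counted as a
base. Base groups are represented by their center of mass over all
residue atoms with standard atomic masses (a heavy-atom-only option
exists); dye groups by three points — whole-residue center of mass plus
both end centroids — to account for the dye's anisotropy. Contact means
minimum representative-point distance ≤ cutoff (1.2 nm default). The
boundary is closed ("within" read inclusively); exact-boundary cases are
measure-zero for real data and pinned in tests. Probabilities are contact
frames over retained frames, pooled across trials with frame-count
weighting; the diagonal is forced to 1. Outputs are checked for symmetry,
unit diagonal, and [0, 1] bounds on construction.

## Ensemble statistics

Heatmaps are normalized 2-D histograms (numpy.histogram2d) of pooled
observations; normalization is by in-range count, and pooling multiple
trials before binning is order-independent. Default bins: R ∈ [0, 5] nm
at 0.05 nm, |κ| ∈ [0, 2] at 0.05, |J| ∈ [0, 200] meV at 2.5 meV — widths
chosen to resolve the peak scales of interest (R ≈ 0.4–0.6 nm,
|J| ≈ 60–150 meV) at desk-scale sample sizes.

Classification: H-like iff |κ| ≤ 1 (boundary closed on the stacked
side — arbitrary but fixed, and recorded in output metadata), J-like
otherwise; "dimer" iff R ≤ 1.5 nm, else "separated". Both thresholds are
configurable.

Trial summaries report, per quantity (R, |κ|, |J|): the pooled mean over
all trials' observations, the pooled population SD (ddof = 0), and — 
because "±SD over trials" is ambiguous between pooled-frame and
across-trial spread — also the sample SD (ddof = 1) of the per-trial
means, plus the per-trial means themselves.

## Junction angles

Published junction-angle constructions vary and the one this package
nominally mirrors is not fully specified in accessible form, so the
implementation pins an explicit convention and validates it only on
constructed geometries with known angles:

* An arm axis is the first principal direction (SVD) of the ordered
  base-pair centroids of the arm's two strand spans, paired index-wise
  as listed (the caller lists the antiparallel partner span in reverse).
  The axis is directed first-centroid → last-centroid and re-oriented
  away from a junction center when given.
* A stacked duplex is described by concatenating its arms' centroids;
  the IDA is the angle between the two composite duplex axes, in
  [0, 180]°.
* The twist is the dihedral between the duplex planes about the
  inter-duplex offset vector, computed from the normals axis_i × d̂ and
  folded into [0, 90]° so coplanar duplexes give 0 regardless of axis
  orientation. It is undefined (error) when the duplex anchors coincide
  or an axis is parallel to the offset.

Both angles are rigid-motion invariant and continuous under small
perturbations away from the degenerate configurations.

## Synthetic data: what it emulates and what it does not

`generate_dimer_trajectory` builds two rigid rods of fixed length. Per
frame the center separation is drawn from a normal distribution and each
rod is independently perturbed by two small-angle rotations
(~N(0, sd), default sd = 10°) about axes orthogonal to its director —
simple, and analytically tractable for recovery tests. Mode defaults
place the ensembles at the separations characteristic of the
corresponding dimer arrangements: stacked 0.50 ± 0.04 nm, end-to-end
1.4 nm, separated-stacked 2.5 nm, monomer-like 4.2 nm, plus per-frame
mixtures. Draws are floored (0.05 nm; for end-to-end modes
(l_m+l_n)/2 + 0.05 nm) to keep geometries physical.

`generate_mock_junction` builds four 26-residue pseudo-atom strands
(one atom per base) as two straight duplexes crossing at a configurable
angle (default 60°), with three-atom dye residues (ends + center atom)
at anchor positions encoding the isomer/attachment geometry: transverse
dyes sit 0.5 nm apart in the Iso I-like arrangement and 4.0 nm apart —
opposite sides of the junction — in the Iso II-like one. The isomer is
encoded *only* in the dye anchors; real isomers differ in strand
connectivity, but the contact/orientation pipeline only sees the
geometric consequences, which is what the mock fixes. Frames are static
by default (so construction values are recovered exactly, to file
round-trip precision) with optional seeded Gaussian jitter.

Accordingly, passing tests establish that the analysis chain is correct
and self-consistent — formulas, unit conversions, selection logic,
bookkeeping, determinism — not that any particular physical system
behaves this way. The generators have no DNA mechanics, solvent, ions,
tether torsions, correlated dye–DNA motion, or κ–R coupling beyond the
constructions above; quantitative claims about real dye–DNA systems
still require real trajectories.

## Problem sizes

Statistical tests and the acceptance script use 3 trials × 3000 frames
for ensemble recoveries (pooled SE of the mean R ≈ 4×10⁻⁴ nm under the
default noise), 100 frames for contact-map oracle equivalence, and
20–50 frames for mock-junction and determinism checks — sizes at which
every expected property is resolvable with wide margins.

## Determinism

All stochastic generation flows through `numpy.random.default_rng`
seeded from the generator parameters / run config / CLI; file writers use
fixed float formats and
sorted JSON keys. Repeated runs with identical config + seed produce
byte-identical outputs, and every output embeds the SHA-256 of its run
configuration and the thresholds in force.
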