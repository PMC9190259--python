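# Methods

This note documents the models and procedures implemented in
`abensemble`, their assumptions, the tunable parameters, and the design
choices made where the methodology was genuinely open. Nothing here
states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Input model and preconditions

An ensemble is one topology plus T coordinate frames in Å, read from a
multi-model PDB. Every model must contain the same atoms in the same
order; a mismatch is an error naming the offending model. Residue ids
are taken verbatim from the file (1-based, possibly non-contiguous);
residues with insertion codes are folded into the preceding residue id
with a warning (synthetic data carries none). Chain roles
(heavy/light/antigen) come from the configuration; chains not named
there are classified as water or ion by residue name. Masses are
standard atomic weights. Frames are assumed pre-wrapped and whole: no
periodic-boundary imaging is applied anywhere, and all distances are
direct Euclidean distances. Hydrogen-bond analysis requires explicit
hydrogens and refuses structures without any. "Backbone" means
{N, CA, C, O} throughout.

## Interface interactions

All thresholds live in `InteractionCriteria` and are logged in every
output; the defaults are:

| parameter | default | meaning |
|---|---|---|
| interface_heavy_cutoff | 4.5 Å | residue-level interface definition (heavy atoms only) |
| hbond_da_cutoff | 3.5 Å | heavy donor–acceptor distance |
| hbond_angle_range | 120–180° | donor–H–acceptor angle |
| salt_cutoff | 4.5 Å | side-chain N/O pair of opposite charges |
| cation_pi_cutoff | 6.0 Å | ring centroid to cation |
| cation_pi_angle_windows | 0–60° ∪ 120–180° | centroid→cation vs ring normal |
| pi_stack_cutoff | 6.0 Å | ring centroid to ring centroid |
| hydrophobic_cutoff | 4.5 Å | hydrophobic atom pair |
| donor_h_max_dist | 1.25 Å | hydrogen-to-donor covalent association |

Every threshold is inclusive; an exact-boundary pair is detected (a
small 1e-9 guard absorbs floating-point rounding at constructed
boundaries). Pair searches run through a k-d tree and are
property-tested identical to an all-pairs scan.

Decisions taken where the methodology leaves room:

* **Donor association.** A hydrogen belongs to the nearest N/O/S within
  1.25 Å in the same residue, so no CONECT records are needed. Donors
  are N/O/S with ≥ 1 associated hydrogen; acceptors are N/O (S is not an
  acceptor).
* **Charged groups.** Arg (NE, NH1, NH2), Lys (NZ) and protonated His
  (HIP: ND1, NE2) are positive; Asp (OD1/OD2) and Glu (OE1/OE2)
  negative — i.e. standard states near pH 7.4.
* **Cation–π.** Cations are Lys NZ and Arg CZ; rings are Phe/Tyr
  6-rings, both Trp rings separately, and the His 5-ring. Neutral-His
  cations are excluded by default (`include_his_cations` enables an
  imidazolium approximation). Ring normals come from an SVD plane fit.
* **π-stacking is distance-only**: no angle filter is applied, so
  perpendicular rings within 6 Å count. This mirrors the criteria table
  this module implements, which lists no angle for stacking.
* **Hydrophobic typing** follows the rule "C/S atoms whose bonded
  neighbours include no N or O", precomputed per residue template for
  the 20 standard amino acids; contacts are collapsed to one record per
  residue pair per frame.
* **Bridging waters are first-order only**: a water bridges when it is
  hydrogen-bonded (either direction) to both molecules in the same
  frame; water→water→antigen chains do not make the first water
  bridging. One `hbond_bridge` record is emitted per antibody-side
  hydrogen bond through a bridging water. Bridging waters are excluded
  from the bulk-solvent class, so the three hydrogen-bond classes
  (direct / bridge / solvent) partition without double counting.
* **Two counting modes.** `fixed_interface` restricts all detectors to
  a caller-supplied reference residue selection (typically derived from
  a crystal structure) — used for like-for-like comparisons across
  scenarios. `fluctuating_interface` scans the full cross-molecule atom
  set every frame, capturing all interactions as the system fluctuates;
  the bulk-solvent selection is the per-frame interface residue set,
  hydrogens included. Ion contacts always use the whole Fv.

The non-solvent percentage is computed from per-kind mean counts:
100·(total − solvent)/total, with total the sum over all intermolecular
kinds including solvent hydrogen bonds; the non-solvent non-hydrophobic
variant additionally subtracts hydrophobic residue contacts.

## Dihedral states

φ(i) = C(i−1)–N(i)–CA(i)–C(i) and ψ(i) = N(i)–CA(i)–C(i)–N(i+1), IUPAC
sign convention (cross-checked against MDAnalysis), range (−180°, 180°].
A loop's first φ and last ψ use flanking framework residues when
present, else they are dropped. Torsions of collinear atom quadruples
are an error.

States are built per CDR: each dihedral is histogrammed on a circular
grid (`bin_width`, default 10°; it must divide 360°); bins holding at
least `peak_bin_fraction` (default 1.5 %) of frames are super-threshold,
and maximal circularly contiguous runs of super-threshold bins form
peaks (runs crossing the ±180° seam merge). Each frame gets a
per-dihedral peak label, off-peak frames are "noise"; a state is a
realized joint label vector without noise. States below
`rare_state_fraction` (default 1 %), plus all noise frames, pool into
the rare fraction, so kept populations + rare fraction = 1 exactly.
State means are per-dihedral circular means over member frames.

Choices made here: 10° bins resolve rotamer-scale modes while keeping
1.5 %-bins meaningful at T ≈ 10⁴; off-peak frames count as rare because
the state definition assigns populations only to realized peak
combinations; joint states are observed combinations, not the Cartesian
product. Because tails beyond a peak's super-threshold bins count as
noise, recovered populations are faithful when the within-state spread
is small against the bin width (the regime the generator's defaults
target); very broad states shed a few percent into the rare fraction.

Circular similarity of two states is the arithmetic mean over dihedrals
of 1 − Δ/180° (Δ = circular absolute difference of mean torsions in
[0°, 180°]): 1 for identical states, 0 when every dihedral is opposed.
Aggregation by arithmetic mean is this module's decision (the per-angle
normalization is fixed; a stricter minimum-over-dihedrals aggregation is
available as an option). Apo/holo matching is greedy one-to-one in descending
similarity, accepting pairs ≥ 0.8; ties break deterministically by state
index. Sampling is classified per CDR by kept-state counts (more_apo /
equal / more_holo); equality is strict by default with a configurable
tolerance. ω torsions and side-chain χ angles are out of scope.

## Cartesian sampling

Frames are rigid-body least-squares fitted (proper rotations only;
degenerate/collinear alignment selections are rejected) onto a
reference frame over the V_H/V_L-interface backbone. The PCA basis is
fitted on the concatenated (apo then holo) frames of the CDR backbone
selection, with coordinates weighted by √mass per atom before the
covariance; per-ensemble cluster counts are then computed on each
ensemble's own 3-PC projection, so both forms share one basis.

The average-linkage clustering threshold (default 11) is applied to
Euclidean distances in this mass-weighted PC space, i.e. its units are
√Da·Å — stated prominently because a plain-Å reading would differ by a
factor of ≈ √m. Cluster labels are relabelled densely by first
appearance for determinism; the implementation is scipy's
linkage/fcluster, tested identical to an explicit O(T³) agglomeration.

DRES (dimensionality-reduction ensemble similarity) fits a Gaussian KDE
per projected ensemble (Silverman's factor on each sample's covariance)
and estimates the Jensen–Shannon divergence (natural log) by Monte-Carlo
sampling from the 50/50 mixture (default 10⁴ samples, seeded), clipping
to [0, ln 2]. Identical frame sets score exactly 0 (the log-ratio is
identically zero); well-separated ensembles approach ln 2 ≈ 0.693.
Estimator settings (bandwidth rule, sample count, seed) are recorded in
every output. Two finite samples of the *same* distribution score
slightly above 0 from KDE sampling error (≈ 0.03–0.05 at 200–500 frames
in 3-D), decaying with ensemble size. Time-lagged/kinetic analyses and
free-energy surfaces are out of scope.

## Affinity statistics

ln(K_d in nM) is the affinity proxy; ln(k_off) is used where supplied,
with missing values excluded pairwise. Per-antibody metrics are means
over exactly the six CDRs (H1–H3, L1–L3); an antibody without a K_d
stays in the metric table but is excluded from every correlation.
Correlations report R² (squared Pearson), slope, intercept and n, with
no p-values; a leave-one-out scan recomputes R² with each point removed
and reports the most influential point — the implemented generalization
of ad-hoc single-outlier omission. Metrics constant across a panel are
skipped. R² is affine-invariant and symmetric (property-tested).

## Synthetic data

The generators define the study conditions for all tests; their defaults
are fixed and seeded.

* **Toy complexes** realize requested interaction counts by
  construction, one motif per interaction on a 24 Å grid: donor/acceptor
  pairs at 2.9 Å / 165°, charged pairs at 3.5 Å, a cation 5 Å along a
  ring normal, parallel rings 5 Å apart, hydrophobic atoms at 4.0 Å, a
  bridging water hydrogen-bonded to both molecules (2.9 Å / 170° and
  2.8 Å / 160°), a bulk water > 4.5 Å from the antigen but bonded to an
  interface Fv residue, and a Na⁺ 4.0 Å from a carboxylate. Toy residues
  carry full backbones plus the minimal side-chain motif per class,
  under standard residue/atom names so the production typing tables
  apply unchanged; waters are ideal 3-site molecules. Every build is
  audited by running the complete detector suite on frame 0 and
  comparing with the planted counts — a mismatch is a generation error,
  so "no accidental interactions" is enforced, not hoped for. Six
  5-residue poly-Gly CDR loops (chains H/L, residues 101–125, per-frame
  Gaussian jitter of 0.06 Å) and a rigid V_H/V_L framework block
  (residues 201–203) make the dihedral/PCA/pipeline stages runnable on
  generated panels.
* **Dihedral ensembles** draw frame states i.i.d. from planted
  populations and add wrapped-Gaussian noise to per-state means; specs
  whose state separation is ≤ 3× the spread are rejected.
* **Cartesian ensembles** displace the CDR backbone along three fixed
  orthonormal modes (a deterministic property of the selection) by
  per-center amplitudes plus Gaussian noise; all other atoms stay fixed
  so superposition is exact.
* **Panels** plant ln(K_d) = slope·f + intercept + ε against the
  non-solvent percentage f. Counts are integers, so f is realizable on a
  grid of 100/total_interactions percentage points; the default total of
  25 bounds the construction error by ±2 %. Defaults: 9 antibodies,
  f ∈ [55 %, 95 %], slope −0.15 per percentage point, intercept 12,
  noise sd 0.5 — chosen so ln(K_d) spans roughly −2.5 to 4 (≈ 0.1 nM to
  50 nM), the range typical of experimentally characterized antibody
  panels. An optional planted outlier shifts one antibody's ln(K_d) for
  leave-one-out testing. The apo member of each pair is an independently
  sampled Fv-only ensemble over the same topology.

What the synthetic data does *not* emulate: real side-chain chemistry
and rotamer coupling, solvent density (only targeted waters exist),
correlated loop dynamics, force-field energetics, and conformational
exchange kinetics. Passing tests therefore demonstrate the correctness
of the detection, state-construction, clustering and correlation
machinery under exactly known ground truth — not the biophysical
fidelity of any simulation.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design: state
recovery uses T = 10⁴ frames and K ≤ 4 states; clustering recovery uses
100 seeded replicates of 120-frame ensembles; detector/oracle
equivalence uses 100 random fixtures; DRES checks use 200–500 frames
with 10⁴–2·10⁴ Monte-Carlo samples; end-to-end panels use 6–9 antibodies
with ≤ 3 frames. These sizes make the whole suite run in about a minute
on one CPU while leaving every statistical tolerance comfortably
satisfied.

## Known limitations

* No periodic-boundary handling: ensembles must be imaged/whole before
  analysis.
* Chain-level roles: a chain mixing water and ion residues is rejected
  rather than split.
* Insertion codes are folded into the preceding residue id.
* The linkage threshold is in mass-weighted PC units; results are not
  comparable to plain-Å clustering without rescaling.
* DRES between independent same-distribution samples is biased above 0
  by KDE sampling error; comparisons should use similar ensemble sizes.
* The correlation grid is exploratory and reports no multiple-testing
  correction.
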