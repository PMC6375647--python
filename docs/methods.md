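# Methods

## The representation

A ligand-binding pocket is represented as a fixed-size 3D image. Starting
from a protein–ligand complex, a spherical grid of radius 15 Å with 1 Å
spacing is centered on the geometric center of the ligand, then refined in
three steps: (1) *excluded volume* — points within 2 Å (inclusive) of any
protein heavy atom are removed; (2) *envelope clipping* — points outside the
protein body are removed, where the body is by default the convex hull of
protein heavy-atom centers (an alternative "envelope" mode keeps points
within `R_env` = 4 Å of any atom; the hull falls back to the envelope when
the protein is degenerate for a 3D hull); (3) *largest component* — points
disconnected from the main grid under face (6-)adjacency are dropped
(26-adjacency is available). Each step only removes points, and removals are
logged per step.

Every surviving grid point receives a 14-component interaction-energy
vector: one channel per SYBYL probe type (C.2, C.3, C.ar, N.2, N.4, N.am,
N.ar, N.pl3, O.2, O.3, O.co2, P.3, S.3, F), each the sum of a distance-binned
pair potential u(probe, protein type, r) over all protein heavy atoms within
the cutoff (distances are grid-point to atom-center; no radii). The
potential is a pluggable table in the style of DFIRE-type knowledge-based
potentials; the package ships the table *format* plus a synthetic table for
testing, not empirical parameters. The default cutoff of 14.5 Å follows the
convention of that family of potentials. Protein atoms are typed by an
editable (residue, atom name) → SYBYL lookup covering the 20 standard amino
acids, with an element-level fallback (C→C.3, N→N.am, O→O.2, S→S.3, P→P.3,
halogens→F) so typing is total; fallback use is counted and warned about.

The pocket is pose-standardized before voxelization: the grid is translated
so the ligand center sits at the origin and rotated so the longest, middle
and shortest principal axes of the binding-residue heavy atoms (residues
with a heavy atom within 5 Å of the ligand) align with x, y, z. Eigenvector
sign is fixed by requiring the third central moment of the binding atoms
along x and y to be non-negative, with z completing a right-handed frame;
the residual ambiguity (when a skewness is ~0) is at most an axis flip, and
pose-invariance checks compare tensors over all eight flip combinations.
The oriented points are binned into a 32×32×32 voxel tensor (voxel index =
floor(coordinate + 16)); points sharing a voxel have their channel vectors
averaged, and the point↔voxel mapping is retained for explanation
back-mapping. A 2-channel "occupancy" variant (one-hot occupied/empty)
carries shape information only and serves as the baseline that isolates
the contribution of the energy channels.

Two caveats on invariance. The sampling lattice is axis-aligned in the
input frame, so the final tensor is *exactly* invariant to translations and
to lattice-preserving rotations (the cubic point group) of the input
complex — this is what the invariance test asserts — while a general
rotation resamples the energy field and is removed only up to
discretization. Second, boundary conventions ("within 2 Å" removes d ≤ 2.0
exactly; a point exactly on a hull face is inside; a distance exactly at
the potential cutoff falls in the last bin) matter on measure-zero sets
only but are pinned down for reproducibility.

## The classifier

The network is a VoxNet-lineage 3D CNN: two valid stride-1 convolutions
(64 filters each, kernels 5 then 3) with leaky-ReLU (slope 0.1), so a 32³
input leaves the second convolution as 64 feature maps of side 26; then
dropout (0.2), 2× max pooling, dropout (0.4), a dense layer of width 128
with leaky-ReLU, and a softmax output. The dropout rates, dense width and
slope are package defaults, exposed in `NetworkConfig` and recorded with
every trained model. Training uses categorical cross-entropy and Adam with
learning rate 1e-5, decay 0, β₁ 0.9, β₂ 0.999, batch size 32 (any of
16/32/64/128 behaves comparably), 50 epochs — these are the library
defaults for full-scale data. Optional per-channel z-scoring (statistics
from the training set, stored with the model) is available and used in the
synthetic study, where raw channel magnitudes differ by an order of
magnitude across channels. All layers, backpropagation and Adam are
implemented in NumPy with a shift-and-matmul convolution (one GEMM per
kernel offset), which keeps memory flat and routes arithmetic through BLAS;
gradients are verified against central finite differences in the test
suite. Training is fully deterministic given a seed.

Evaluation is one-vs-rest per class using the class's softmax probability
as score: accuracy, precision, specificity, sensitivity, fall-out, Matthews
correlation, and ROC/AUC by threshold sweeping with trapezoidal
integration (equal to the Mann–Whitney pair statistic with ties counted ½).
Ratios with zero denominators are reported as missing, never coerced to 0.
Two cross-validation protocols are provided: stratified k-fold (default
k = 5, shuffled with a fixed seed; the stratification is a package choice)
and leave-one-group-out, which holds out one annotated group (e.g. one
enzyme family) per round.

## Class-activation maps

The CAM answers "which part of the pocket drove this classification". The
plain CAM is defined for a GAP + linear head (offered as a model variant);
the default head is max-pool + dense, for which the package uses the
gradient-weighted generalization: feature maps of the last convolution are
combined with weights equal to the spatially averaged gradients of a class
target, rectified at zero. The target is the *contrast* logit_c − mean of
the other logits rather than the raw logit: softmax probabilities are
invariant to a shared additive component of the logits, so a network is
free to encode one class's evidence entirely as negative evidence in the
other logits, leaving that class's raw logit flat and its CAM empty; the
contrast target removes exactly that unidentifiable component. Because both convolutions are valid, feature-map
voxel m is centered on input voxel m + 3; the CAM is trilinearly resampled
onto the voxel grid with this margin taken into account (and across the
pooling factor when the model consumes pooled inputs). The top 1% of voxels
by CAM value (quantile over all 32³ voxels — the population that makes "top
1%" ≈ 330 voxels) select the pocket grid points they contain; each selected
point donates its CAM value to the residue of its nearest protein heavy
atom within 5 Å (ties broken by lowest residue number, then chain), and the
per-residue sums are the CAM-scores. CAM mass is conserved: residue scores
plus unassigned-point mass equals selected-point mass exactly. An all-zero
CAM (a class with no positive evidence) yields an empty selection with a
warning rather than an error.

## The synthetic benchmark

Real pocket benchmarks require thousands of curated complexes; the
generator builds pseudo-complexes that exercise every pipeline stage and
carry a learnable, *regionally planted* class signal. Each complex is an
ellipsoidal shell (axis scales 1.25 : 1.0 : 0.8, cavity radius uniform in
6.5–8.5 Å) of residue-like side-chain atom clusters around a 10–30-atom
pseudo-ligand, randomly rotated as a whole; 44 lining residues plus 28
outer-shell residues (the outer shell at +5.5 Å makes hull clipping and
component filtering both act). A 60°-half-angle cap of the lining is drawn
from a class-signature species — ASN (amide/carbonyl), PHE (aromatic), MET
(thioether) at weight 0.85, LEU otherwise — while everything else is LEU.
Classes therefore differ in atom-type composition but not in shape, so
energy channels must outperform the occupancy baseline, and the signature
cap provides ground truth for CAM localization. The signature species were
chosen with comparable per-residue atom counts (4/7/4) so no class's
planted signal is systematically weaker. The synthetic pair potential draws
a distinct nonzero energy for every (probe, protein type) pair over bins
0–4, 4–8, 8–14.5 Å with magnitudes decaying 2.0 : 1.0 : 0.2 across bins,
mimicking how knowledge-based potentials vanish toward their cutoff; the
decay keeps the type signal concentrated near the atoms that carry it,
which is what makes region-level explanation well-posed. Everything is
deterministic under (seed, class, index).

What the generator does *not* emulate: real backbone geometry and bonding,
realistic ligand chemistry, the size and redundancy structure of curated
PDB datasets, or label noise. Passing the synthetic study therefore
demonstrates that the pipeline is internally correct and that the
representation/classifier/explanation chain can recover a known signal —
not that the headline numbers transfer to real proteins.

## The scaled-down study instance

The packaged study (`voxpocket.benchmark`, also run by
`scripts/acceptance.py`) uses 60 pockets (20 per class) and a reduced
member of the same architecture family sized for a single CPU core: 8
filters per convolution, dense width 32, and 16³ inputs obtained by 2×
average pooling of the 32³ tensors (the compositional signal lives in
channel means and survives pooling; full-resolution tensors are still what
the pipeline produces and what CAM selection is computed on). Training uses
Adam at learning rate 1e-3 for 25 epochs with per-channel standardization —
appropriate for this sample size, where the full-scale defaults would
converge impractically slowly. Cross-validation is stratified 5-fold; CAM
localization is evaluated with the model trained on all 60 pockets,
upsampling the CAM from the pooled model grid to the 32³ voxel grid. A
localization hit means the top CAM-scored residue lies in the planted
region — it is a signature residue or has a heavy atom within 5 Å (the
method's own residue-mapping distance) of one; background residues are
deliberately interleaved with the patch at 15%, so exact residue identity
is not resolvable even by a perfect explanation, while region membership
is.

## Known limitations

- The NumPy network is single-core and unsuited to datasets beyond a few
  hundred pockets; the architecture and training contracts are the point.
- Plain CAM requires the GAP-head variant; the default head uses the
  gradient-weighted form, and the two can differ on the same pocket.
- The convex-hull reading of envelope clipping is one of two defensible
  interpretations (hull of atom centers vs. union of atom envelopes); both
  are implemented, neither privileged by theory.
- Metal ions and non-selected hetero groups are excluded entirely from the
  protein for refinement and potentials.
- Binding residues for axis computation use a 5 Å heavy-atom cutoff; this
  mirrors the CAM residue-mapping distance but is an assumption.
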