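# Methods

## The prediction problem

Heme (iron-protoporphyrin, HET code `HEM`) is bound by its host proteins
through a compact patch of residues — typically Cys, His, Met and Phe —
that line a partially buried pocket.  `hemebind` predicts, per residue of
a protein chain, whether that residue belongs to such a patch.  Two
classifier paths are trained and then combined:

* **Structure path (STR).**  Each residue is described by 33 numbers:
  its 20 logistic-scaled profile scores, its relative solvent
  accessibility (RASA), six statistics of atom depth (DPX) and six of
  atom protrusion (CX).  The SVM input for a residue is the concatenated
  33-number blocks of a *spatial window*: the residue plus its M−1
  nearest neighbors by Cα–Cα distance (default M = 15), ordered target
  first, then by increasing distance with sequence-index tie-breaks.
* **Sequence path (SEQ).**  The SVM input is a *sliding window* of N
  consecutive scaled profile rows centered on the target (default
  N = 17); a 21-bit one-hot amino-acid encoding is available as the
  profile-free alternative.

Both paths use an RBF-kernel SVM with hard decision threshold 0.
Predicted positives of the structure path then pass a **spatial
false-positive filter**: a positive is demoted to negative when fewer
than T of its W nearest Cα neighbors (defaults W = 18, T = 5, target
excluded) are raw positives.  The filter makes exactly one pass and
always counts neighbors in the *raw* track; iterating it would erode the
edges of genuine clusters, so iteration is deliberately unsupported.
The final **ensemble** is a hard AND vote: a residue is called binding
only when the filtered structure call and the sequence call agree.  No
filter is applied to the sequence path.

## Descriptor definitions and numerical choices

* **SASA** is computed with the Shrake–Rupley method: each heavy atom is
  inflated by the probe radius (1.4 Å) and sampled with 960 deterministic
  golden-spiral points; a point survives if it lies outside every other
  inflated atom.  Van der Waals radii: C 1.70, N 1.55, O 1.52, S 1.80 Å
  (1.70 Å for anything else).  Hydrogens are ignored throughout.  At 960
  points the per-residue quadrature jitter is below ~5% (sub-Å² in
  absolute terms) for partially occluded residues and far smaller
  elsewhere; from 1920 points on, doubling the density moves every
  residue by less than 2%.  The logistic squashing applied downstream
  makes this noise immaterial to the features.
* **RASA** = residue SASA / maximum SASA of its residue type (the Rost &
  Sander reference maxima), clamped to [0, 1] because terminal residues
  can numerically exceed their reference maximum.  UNK residues have no
  reference value and are excluded from datasets.
* **DPX** of an atom is 0 if the atom is solvent accessible, else the
  Euclidean distance to the nearest accessible atom of the chain.  With
  numerical SASA, "accessible" means SASA > 1e−6 Å².  A chain with no
  accessible atom is a degenerate input and raises an error.
* **CX** of an atom counts heavy atoms within a 10 Å sphere (itself
  included); the internal volume is that count times a 20.1 Å³ mean atom
  volume, and CX = (sphere volume − internal volume) / internal volume,
  floored at 0 for neighborhoods denser than the sphere.  CX is
  external-over-internal volume, i.e. high for protruding atoms and low
  in concavities.
* **Per-residue summaries** of DPX and CX are six statistics each:
  mean and population SD over all atoms, mean and SD over side-chain
  atoms (atoms not named N/CA/C/O), minimum and maximum.  Glycine has no
  side-chain atoms; its side-chain statistics fall back to the all-atom
  values.  All twelve statistics are mapped through the standard
  logistic function 1/(1+e^(−x)) so every feature lives in (0, 1).
* **Profiles** are consumed in the PSI-BLAST ASCII dialect (the
  20-column substitution-score block; the percentage block is ignored).
  Row i of the profile corresponds to residue i of the chain; a length
  mismatch is a hard error — no alignment heuristics.  Scores are
  logistic-scaled elementwise.  The *conservation score* of a position
  is the raw diagonal element: the score of the query's own residue
  type.
* **Windows at chain edges.**  Sliding-window positions beyond the
  termini contribute zero blocks; spatial windows of chains shorter than
  M are zero-padded at the tail.  Zero is the neutral choice because all
  retained features are positive after scaling.

## Labels

A residue is labeled heme-binding when any of its heavy atoms lies
within 4.5 Å of any heavy atom of any heme in the complex (union over
multiple hemes).  The distance criterion is the standard proxy in the
binding-site literature for contact definitions that would otherwise
require a specific surface-complementarity program; the cutoff is
configurable.  Chains without hemes get all-zero labels with a warning.

## Training protocol

Negative residues outnumber positives roughly 6:1, so every training
set is balanced: all binding residues plus an equal-size random draw of
non-binding residues (without replacement, seeded).  Hyper-parameters
are chosen by exhaustive grid search over the canonical LIBSVM ranges
C ∈ {2⁻⁵ … 2¹⁵}, γ ∈ {2⁻¹⁵ … 2³} (steps of ×4), scored by Matthews
correlation under an internal stratified 5-fold CV; ties prefer smaller
C, then smaller γ, and the winner is refit on all training data.

Outer evaluation is 5-fold cross-validation split **by chain**, never by
residue, so residues of one protein can never appear on both sides of a
fold boundary; a guard rejects duplicated chain objects.  Reported
metrics are per-fold values (residues pooled within the fold) and their
unweighted mean.  Fold-averaged and pooled metrics differ in general;
reports label which is which.  All stochastic steps — fold assignment,
negative sampling, grid-CV shuffles — take explicit seeds.

## Evaluation measures

From the 2×2 confusion table: recall TP/(TP+FN), precision TP/(TP+FP),
accuracy (TP+TN)/total, F1 = 2PR/(P+R) (all reported as percentages),
and MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)).  Whenever a
denominator factor is zero the affected measure is defined as 0; real
runs never hit these cases, degenerate toy inputs can.

## The synthetic benchmark

Real heme-protein benchmarks cannot be rebuilt offline (they need a PDB
snapshot, a contact-analysis server and profile searches against a large
sequence database), so the package ships a generator that fabricates
miniature complexes carrying the statistical structure the method
exploits.  Defaults (and the conditions of the shipped benchmark):
30 chains × 60 residues, one heme per chain, an 8-residue binding patch,
conservation boost 8, four-helix-bundle scaffold, generation seed 1.

* **Scaffold.**  Ideal α-helix geometry (2.3 Å radius, 1.5 Å rise,
  100°/residue, 3.8 Å Cα spacing), threaded through four antiparallel
  helices on an 8 Å square for the bundle style.  Each residue gets
  backbone N/CA/C/O plus one pseudo side-chain atom 2.4 Å along the
  outward normal.
* **Heme.**  A planar 43-atom porphyrin-like grid (central Fe plus rings
  of 6, 12 and 24 atoms at 2, 3 and 4 Å).  Only its geometry matters;
  the pipeline never uses ligand chemistry.
* **Pocket construction.**  A rigid plane tangent to a convex helical
  surface can contact at most about five residue blobs under the 4.5 Å
  cutoff, so exact 8-residue patches are planted by carving a pocket:
  the patch residues around a mid-height surface anchor take compact
  0.8 Å side-chain stubs, the ring descends along the surface normal to
  the pose with the most rigid contacts, and the few patch members still
  out of range have their side chain extended toward the ring to a
  randomized distance well inside the cutoff.  Every non-patch residue
  stays at least 0.04 Å beyond the cutoff, so the planted labels are
  exact by construction and survive the 10⁻³ Å coordinate rounding of
  the PDB format.  Mid-height anchoring reflects that binding sites
  avoid frayed termini, and gives planted patches the lower protrusion
  and lower accessibility of real heme interfaces.
* **Identities.**  Patch residues draw from {Cys, His, Met, Phe} with
  probability 0.85, the background uniformly from all twenty types.
* **Profiles.**  Background rows are integer noise in [−4, 4].  At patch
  positions the row is reshaped the way iterated profile searches shape
  conserved columns: the diagonal is raised by the boost (capped at 12)
  and each other substitution score is depressed by a random amount up
  to half the boost (floored at −6).  The randomness keeps single
  positions ambiguous, so the sliding-window context genuinely helps —
  without the depression the logistic scaling saturates (a background +4
  scales to 0.982 against 0.9999 for a boosted +12) and the planted
  conservation is nearly invisible to the classifier.  Boost 0 leaves
  rows untouched, giving a clean null.

**What the fixtures do not emulate:** real side-chain rotamers and
packing, β-sheet or loop geometry, sequence motifs such as CXXCH beyond
residue-identity enrichment, heme chemistry, and the label noise of a
real contact-analysis pipeline.  Passing tests therefore demonstrate
that the implementation recovers signals of the kind the method assumes,
at toy scale — not field performance on deposited structures.

## Problem sizes

The shipped benchmark (30 × 60 residues) makes a full five-variant
cross-validated run, including two grid-searched SVM paths per fold,
complete in a couple of minutes on one CPU; the acceptance script's two
runs (ensemble plus shuffled control) finish in under ten.  These sizes
were chosen so the whole validation cycle is routinely re-runnable.

## Known limitations

* The contact-labeling cutoff is a proxy for surface-complementarity
  contact analysis; labels near the 4.5 Å boundary can differ from that
  analysis on real structures.
* DSSP-derived SASA (common in the prior literature) differs slightly
  from Shrake–Rupley values; since downstream features are learned,
  only consistency between training and prediction matters.
* Profiles must be supplied (or synthesized); the package never runs a
  profile search itself.
* Single-model PDB input only; no mmCIF in this version.
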