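# Methods

This note documents the models, conventions and numerical choices behind
`ugdyn`, and what the synthetic fixtures do and do not establish about
real data.

## Structures and selections

Structures are parsed with gemmi (PDB and mmCIF).  Only the first model
is read; alternate locations are resolved to the blank/'A' conformer so
every downstream selection is deterministic; hydrogens are dropped at
parse time (crystal structures rarely carry them, MD frames may — all
geometry here is heavy-atom or Cα based).  Residues with insertion codes
are rejected with an explicit error rather than silently renumbered:
every selection in the package is keyed on author residue numbers, and
an insertion code would make that key ambiguous.  Multi-copy asymmetric
units are handled by passing an explicit chain everywhere; the default
is the first protein chain.

Trajectories are either multi-model PDB (gemmi) or DCD/XTC read through
MDAnalysis against a PDB/mmCIF topology; frame order is file order and
every frame must match the topology atom count exactly.  Round-trip
fidelity is format-bound: PDB text carries 10⁻³ Å, DCD is float32
(~10⁻⁴ Å at protein scales), XTC quantises to 10⁻³ nm.

### Glycosylation sites

An N-glycosylation site is an ASN whose ND2 is covalently bonded to the
C1 atom of a sugar.  Two detection routes are implemented, recorded in
the site's `evidence` field: an explicit covalent link record in the
file, or an ND2–C1 distance of at most 2.0 Å (a generous covalent-bond
cutoff; the actual C–N bond is ~1.44 Å).  Both are provided because
deposition practice varies — older entries often omit LINK records.  The
recognised sugar vocabulary (NAG, NDG, BMA, MAN, FUC, GAL, GLC, SIA and
common synonyms) is an argument, since PDB chemical-component naming has
drifted.  Synthetic fixtures may instead *declare* sites on any residue.

### Sequence coverage

`sequence_coverage` = (residues with ≥1 resolved atom) / (primary
sequence length).  The length cannot be inferred from coordinates alone,
so it must be supplied (`Structure.sequence_lengths`); the function
errors instructively otherwise.  The survey's cohort filter applies the
inclusion rule *coverage strictly greater than 0.90*, so a chain at
exactly 90% is excluded.

## Conformational coordinates

* **CC1 (clamping, Å)** — Euclidean distance between the TRXL1 and TRXL3
  domain centers.
* **CC2 (bending, °)** — angle at the TRXL2 center formed by the TRXL1,
  TRXL2, TRXL3 centers, in [0, 180].  TRXL2 is the vertex: the
  coordinate tracks TRXL2's bend toward the GT24 core, and the
  middle-listed domain of the triple is the natural hinge.
* **CC3 (twisting, °)** — signed torsion of four Cα atoms (two in TRXL2,
  two in TRXL3; default quad 518, 466, 863, 735), IUPAC right-handed
  convention, wrapped into (−180, 180].

Domain centers default to the *geometric center of Cα atoms*.  Published
values of these coordinates are described as center-of-mass based, but
the accompanying essential-dynamics analysis is Cα-only and the exact
convention is unstated; both `atom_mode` (calpha/heavy) and `weighting`
(geometric/mass) are therefore exposed, and comparisons against
published per-structure values use tolerances (1 Å on CC1, 2° on
CC2/CC3) wide enough to absorb the convention gap.  For the *Ct*UGGT
domains the two conventions differ by well under these tolerances.

Missing residues inside a domain range use whatever atoms are present,
with the count reported per domain — this matches how the coordinates
must behave on gapped crystal structures.  A fully absent domain or an
unresolved quad residue makes the corresponding coordinate `None` in the
bundled record (`ccs_for_structure`); the low-level operations raise
instead, naming the offending domain or residue.  One known consequence:
a deposited structure whose disordered span covers a quad residue
(e.g. a model missing 461–505, which contains 466) cannot yield CC3 from
the deposited coordinates alone — the operation refuses to guess.

## Essential dynamics

Superposition is the closed-form Kabsch/SVD solution for the optimal
proper rotation (determinant +1 enforced by sign correction), with
optional weights; <3 atoms or collinear sets are rejected.  Trajectory
alignment defaults to the iterative-mean reference (align to running
mean, re-average, repeat until the mean shifts <10⁻⁶ Å or 20
iterations), the standard for covariance analysis; a first-frame mode
exists for reproducibility tests.  The fit is computed on the selected
atoms (Cα by default) and applied to all atoms.

PCA diagonalises the unweighted Cα positional covariance about the
ensemble mean with the population divisor *n_frames* (this makes
Σλ equal the aligned ensemble's total positional variance, an identity
the tests assert at 10⁻⁶ relative).  Implementation is SVD of the
centered frame matrix, so no 3N×3N matrix is formed.  Numerically zero
eigenvalues (below 10⁻¹² of the leading one) are dropped — a degenerate
ensemble simply yields fewer components.  Eigenvector sign is fixed by
making the largest-magnitude coefficient positive, so output is
deterministic across platforms; projections are invariant up to that
consistent flip.  `compute_pca` warns if the selection centroid drifts
>1 Å across frames (unaligned input).

Crystal structures are projected onto MD-derived components by
restricting the mean and eigenvectors pairwise to the atoms present in
both — an approximation (the restricted eigenvectors are no longer
exactly orthonormal) that is documented and tested only for directional
agreement.  Trajectory fusion concatenates frames restricted to a common
atom-key selection ((chain, residue, atom name) triples) and keeps
per-frame source labels.

## The glycan-reach survey

Distance semantics: the distance from a residue to a site is the
*minimum heavy-atom inter-atomic distance* between the residue and the
glycosylated ASN — not the sugar atoms.  Minimum is the reduction
consistent with asking whether a residue is "within reach" of a glycan;
a mean-distance mode is provided for sensitivity checks, as is a Cα–Cα
mode for the residue–residue control.  Per-residue records carry d1
(closest site) and d2 (second closest, absent with <2 sites); a
glycosylated residue has d1 = 0 by construction.

The survey pools records across entries (each residue counts once, the
per-residue reading of a pooled statistic), histograms d1/d2/control at
1 Å default bin width (configurable; the published figure does not state
one), builds cumulative curves as sorted values vs. fraction ≤, computes
per-entry radius of gyration √(Σwᵢ|rᵢ−r̄|²/Σwᵢ) and its median marker,
and reports fraction-within for each threshold (70 and 80 Å by default —
the Parodi-limit bracket, which is an *input* here, not a derived
quantity).  Surveys run per chain by default.

## Synthetic generators

All generators are seeded (`numpy` `default_rng`; identical spec ⇒
bit-identical output) and emit machine-readable ground truth.

* `make_conformer` places seven pseudo-domain blobs of Cα/ALA atoms
  (so all production Cα selections work unmodified).  TRXL2 sits at the
  origin; TRXL1/TRXL3 are placed at r = CC1 / (2 sin(CC2/2)) from it so
  the clamp distance and bend angle are exact; the four quad atoms are
  placed around the TRXL2/TRXL3 centers to realise the twist torsion
  exactly; the remaining blob atoms are shifted so every domain centroid
  is exact.  The four static domains sit at fixed anchors.  Recovery of
  planted triples is therefore exact (≤10⁻⁶), which the oracle tests
  exploit; noise, when requested, is applied *after* exact placement.
* `make_cc_trajectory` re-places the same layout (one seed = one
  molecule) per frame along planted cc1/cc2/cc3 series plus i.i.d.
  isotropic Gaussian atom noise; the default 6000 frames matches the
  ensemble size used for essential dynamics of the 250 ns runs.
* `make_mode_trajectory` plants explicit orthonormalised 3N modes with
  given amplitude series — the exact PCA oracle.
* `make_glycoprotein` builds Cα traces (random walk or extended at
  3.8 Å spacing, or an α-helix with canonical 2.3 Å radius / 1.5 Å rise
  / 100° twist), with sites either declared or realised as ASN + ND2 +
  NAG(C1 at 1.45 Å) for detector testing; ground-truth d1/d2 are
  computed by an exhaustive double loop independent of the survey code.
  With a planted exceedance fraction f, residues are placed in two
  radial shells around a single site ([4, 0.95·T] and [1.05·T, 1.8·T]),
  each residue far with probability f; the 5% margins keep the planted
  Bernoulli labels exactly consistent with measured distances even when
  an ND2 atom shortens a residue–site distance by up to ~1.9 Å.
* `make_cohort` spawns per-entry seeds from one root seed and can plant
  filter failures (coverage ≤ 0.90, zero sites).

What the synthetic fixtures do **not** emulate: real secondary/tertiary
structure, side chains beyond the site ND2, glycan trees beyond the
first GlcNAc, crystallographic artefacts (alternate conformations,
lattice contacts), and physically realistic dynamics (no force field —
planted modes are geometric, not energetic).  Passing tests therefore
establish the *correctness of the measurements and statistics*, not any
biological claim about real cohorts; the published 99.61%-within-70 Å
figure depends on the authors' 1,244-entry cohort and is deliberately
not reproduced here.

## Problem sizes and defaults

Unit and property tests use 4–20 atoms per pseudo-domain, trajectories
of 40–5000 frames, and cohorts of up to 20 chains × 200 residues; the
acceptance script uses the canonical 6000-frame fused ensemble (4 × 1500
frames, 42 Cα atoms) and 20 × 200-residue survey cohorts.  These sizes
were chosen so every statistical check sits well above its noise floor
(e.g. ~4000 pooled residues give a binomial σ of ~0.3% on the planted
5% exceedance) while the whole suite remains interactive.

## Known limitations

* Coordinate comparisons against published per-structure values require
  the deposited wwPDB files, which are not bundled; the corresponding
  checks fail with an explanatory message until the files are placed
  under `data/pdb/`.
* The crystal-structure projection onto MD components is a pairwise
  restriction, not a re-fit; with large gaps it is only directionally
  meaningful.
* The per-entry ROG uses resolved atoms only; for low-coverage entries
  it underestimates the true molecular size (the cohort filter keeps
  this bias below 10%).
* `filter_cohort` trusts the supplied coverage and site lists; it does
  not re-derive them.
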