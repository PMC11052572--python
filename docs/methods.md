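# Methods

`fusescreen` implements the inference layer that sits downstream of a
multimer structure predictor. The predictor itself (a GPU job producing
coordinate files, per-model confidence metrics and PAE matrices) is out
of scope; those outputs are this package's inputs. The scientific
setting is the search for a gamete-fusion complex: an all-vs-all screen
of candidate egg and sperm surface proteins, followed by validation of
the candidate assembly against structural, topological and biochemical
constraints.

## Confidence model

Each prediction carries two global confidences in [0, 1]: ipTM (the
predicted interface TM-score, sensitive to inter-chain accuracy) and
pTM. The **ranking confidence** combines them as

    rc = 0.8·ipTM + 0.2·pTM

rc is always recomputed from ipTM/pTM; an rc stored in a metrics file is
only cross-checked (a disagreement above 1e-6 warns, and the recomputed
value wins). Within an ensemble of models for one chain pairing, the
"top" model is the max-rc model with ties broken by model name, and the
ensemble is summarized by (top rc, mean rc, top ipTM, n_models). The
mean over the full ensemble, not the top model alone, drives network
construction: a single lucky model is much weaker evidence than a
consistently recovered interface.

## Screen and interaction network

A screen over n proteins considers every unordered pair including
self-pairs — n(n+1)/2 combinations (120 for the 15-protein roster of 4
egg and 11 sperm proteins). A pair becomes an edge of the interaction
graph when its ensemble **mean rc ≥ 0.4**. The comparison is inclusive:
the threshold is a named constant and a CLI flag, and the boundary case
is pinned by a test. Relative to a chosen hub protein, edges of the
hub's connected component are classified *direct* (incident to the hub)
or *indirect* (annotated with the first-hop neighbor on a shortest path
to the hub, ties broken lexicographically). Homodimer self-loops are
their own class — a protein's self-interaction is reported alongside the
component but never counted as a direct or indirect hub interaction, so
the "hub cluster" size is the count of direct plus indirect heteromeric
edges.

## Per-chain pDockQ

Interface quality of one chain against the rest of its complex uses the
pDockQ sigmoid

    pDockQ = 0.724 / (1 + exp(−0.052·(x − 152.611))) + 0.018,
    x = ⟨pLDDT over interface residues⟩ · ln(n_contacts)

with contacts defined as residue pairs (one residue per side) whose Cβ
atoms — Cα for glycine — lie within 8.0 Å. The pLDDT average runs over
the union of interface residues on both sides (a query-chain-only
variant is exposed as an option). With zero contacts the logarithm is
undefined and the score is pinned to the additive floor 0.018, the
score's own "no interface" value; the ceiling 0.742 is the sigmoid
asymptote. All four constants are configurable (`PDockQParams`); the
natural log is part of the definition. Contact counting uses a k-d tree
and is tested against an all-pairs double loop.

## Superposition and outlier rejection

Model-vs-reference comparison pairs Cα atoms either by author residue
number (the default when both structures share numbering provenance,
e.g. a prediction of the same construct that was crystallized) or by
global sequence alignment keeping identical-residue columns. The rigid
fit is the closed-form least-squares (Kabsch/SVD) solution with the
determinant correction that forbids reflections; at least three
non-collinear pairs are required.

Outlier rejection is iterative sigma trimming: fit, compute per-pair
deviations, drop pairs deviating by more than `sigma_cutoff` (default
2.0) times the current RMSD, refit, for at most `max_cycles` (default
5) cycles or until nothing is rejected. For sigma ≥ 1 the RMSD is
non-increasing across cycles. Two numerical guards: an RMSD at or below
`min_rmsd` = 1e-6 Å counts as converged (otherwise an exact fit would
shed points on floating-point noise), and a rejection step that would
leave fewer than three pairs raises an error carrying the last valid
fit. Published after-rejection numbers from other software depend on
that software's rejection heuristic, so agreement there is expected
only qualitatively; the pre-rejection RMSD over matched residues is the
reproducible quantity.

## Buried interface area

Buried surface area between chain groups A and B is

    BSA = (SASA(A) + SASA(B) − SASA(A∪B)) / 2

with solvent-accessible surface from an in-package Shrake–Rupley
sampler: probe radius 1.4 Å, a deterministic golden-spiral lattice of
960 points per atom (configurable), Bondi-type van der Waals radii
(C 1.70, N 1.55, O 1.52, S 1.80 Å; hydrogens excluded). A residue
counts as an interface residue when complexation costs it more than
0.1 Å² of accessibility. The sampler is validated against the
closed-form spherical-cap overlap area of two single-atom chains and
against an independent Shrake–Rupley implementation. Published interface
areas computed with other radii sets, point densities or probe handling
can differ by ~10–15%; within this package the computation is
deterministic. A "combined" interface of one chain against two others
treats the pair as a single group.

## Membrane topology

A trans-synapse assembly must keep the membrane anchors of egg-side
subunits on the opposite side from the sperm-side anchors. Each chain
contributes anchor points by rule: `c_term` for C-terminally anchored
ectodomains (single-pass type-I proteins and, as a proxy, GPI-anchored
proteins whose attachment residue is the ectodomain C-terminus),
`n_term`, or `both_termini` for multi-pass chains such as tetraspanins
whose whole body is membrane-proximal. The verdict projects all anchors
onto the unit vector from the sperm-anchor centroid to the egg-anchor
centroid; the **margin** is min(egg projections) − max(sperm
projections), and the assembly is separable iff the margin is positive.
This centroid-axis test matches the qualitative argument it formalizes
and is cheap and rigid-invariant; it is sufficient but not necessary
for linear separability (a full LP separating-plane check would be
strictly stronger and is deliberately not the default). The margin in Å
is this package's own statistic — upstream work presents the same
consistency visually.

## N-glycosylation sequons

A sequon is N-X-S/T with X ≠ P; NXC and other non-canonical motifs are
excluded. Overlapping sequons are all reported, and a record's region
(e.g. ectodomain bounds) restricts the scan. Sequons are mapped onto a
structure through a per-protein (chain, offset) map; hits whose Asn is
missing or differs in identity stay unmapped with a warning rather than
failing the run. A mapped sequon is flagged as a potential
glycan–interface clash when its Asn (side-chain ND2 when present, else
Cα) lies within 10 Å — roughly the reach of the first glycan residues —
of any interface-residue heavy atom; the threshold is configurable.
Cross-species "shared" sites are decided by global alignment of the two
orthologs: sequons whose Asn positions occupy the same alignment column
are one site. Per-species and shared counts are reported separately,
since a combined total depends on the sharing convention.

## Synthetic data: what it emulates and what it does not

The generators produce every input class with planted ground truth:

* **Toy complexes** — chains as straight Cα/Cβ poly-alanine traces,
  200 Å apart, with individual residues relocated to create an exact
  planted number of isolated Cβ contacts (7.5 Å pairs, all unplanned
  pairs ≥ 8.4 Å). The realized contact matrix is verified by brute
  force before any file is written; unrealizable plans fail first.
  B-factors carry the planted pLDDT profile; metrics and PAE files are
  emitted in both supported JSON dialects.
* **Screens** — per-pair model ensembles whose rc values (ipTM = pTM =
  target, so the recomputed rc equals the draw) fall in a planted band:
  (0.45, 0.95) for true edges, (0.05, 0.35) for non-edges, with
  overlapping bands rejected as ill-posed. The flagship
  `default_screen_spec` plants the full 15-protein screen outcome: an
  IZUMO1-centered cluster of 7 heteromeric interactions (5 direct — JUNO,
  CD9, CD81, SPACA6, TMEM81 — and 2 indirect — IZUMO4 via JUNO, SOF1 via
  SPACA6), the isolated heterodimers IZUMO2–IZUMO3, TMEM95–FIMP,
  DCST1–DCST2, and the IZUMO4/DCST1 homodimers. The default ensemble
  size is 5 models per pair; the 25-model case is exercised separately.
* **Sequences** — backgrounds drawn from an alphabet without asparagine
  (so no accidental sequon can occur), with sequons planted exactly at
  the requested positions, including deliberate overlaps.

Every generator is deterministic under its seed (one rng per call, no
global state). What this corpus does **not** emulate: real score
distributions (bands are user-set, real screens have borderline pairs),
physically plausible backbone geometry, crystallographic artifacts
(alternate locations, gaps mid-chain beyond those planted), or the
predictor's correlated error structure. Passing the closed-loop tests
therefore demonstrates that the pipeline's bookkeeping and numerics are
exact, not that the 0.4 cutoff separates real interactions from noise —
that judgement comes from the upstream study design this package
operationalizes.

## Problem sizes and defaults

The test suite and acceptance script run on desk-scale instances chosen
to exercise every code path: 15-protein screens (120 pairs × 5 models),
toy complexes of 60-residue chains, superposition problems of ~100 Cα
pairs, SASA benchmarks at 2000 sphere points, and 50-seed closed-loop
sweeps on 6-protein screens. The full suite completes in seconds on one
CPU.

## Known limitations

* PDB is the only coordinate output format (mmCIF is read, not written).
* The author-number correspondence assumes both structures use the same
  numbering; for renumbered models use the sequence-alignment method.
* The topology margin uses the centroid axis, not the optimal separating
  plane; a separable assembly always has positive margin along *some*
  axis but may score a small negative margin here in adversarial
  geometries.
* The SASA sampler is O(atoms × neighbors × points) and aimed at
  single-complex interfaces, not proteome-scale batches.
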