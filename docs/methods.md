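# Methods

This note records the models, parameter choices and numerical conventions
behind `ltp-epimap`, and what the test suite does and does not demonstrate.

## Scope and intent

The package assesses the allergenic potential of candidate plant nsLTPs by
comparing them with known allergenic LTPs at three levels: overall sequence
(homology screen, phylogeny), residue conservation (MSA annotation), and
epitope content (consensus prediction, shared motifs, PD similarity).  All
inputs are local FASTA files; nothing is fetched at run time.  Webserver
ensembles of trained models (neural networks, SVMs) are deliberately out of
scope — the consensus-voting logic is implemented over a transparent
propensity-scale panel instead, and published consensus regions from such
ensembles are treated as *inputs* (packaged fixtures), not as quantities
this package claims to reproduce.

## Homology screen

* Pairwise alignments use Biopython's exact dynamic-programming
  `PairwiseAligner`: BLOSUM62, gap open 10, gap extend 0.5 (first gap
  position costs the open penalty).  Full-length mode is global (end gaps
  penalized); window mode aligns each query window locally against the full
  subject.
* Percent identity = identical aligned pairs × 100 / alignment length
  *including gap columns*, rounded half-up to two decimals.  This is the
  conservative convention of Codex-style screening; a "shorter sequence"
  denominator is available as an option.  Published identity tables for the
  same sequence pair differ between search engines at the level of a percent
  or so, so engine-reported decimals are treated as bounds, not exact
  targets.
* Window mode slides a length-80 window at step 1 (a query shorter than 80
  residues is a single degenerate window) and reports the best window per
  subject.  Flag thresholds: ≥ 35 % in any window (the Codex screening
  criterion) and > 70 % full-length (the conventional structural-similarity
  remark level).  Both are config knobs.

## Progressive MSA

A self-contained Clustal-style progressive aligner: pairwise global
identities give distances (1 − fractional identity), SciPy UPGMA (average
linkage) supplies the guide tree, and profiles are merged by three-state
(Gotoh) affine dynamic programming on sum-of-pairs BLOSUM62 column scores
(gap characters score 0; tie-break diagonal > gap-in-B > gap-in-A).  The
aligner is deterministic for a fixed input order and adequate for the small
families (≤ a few dozen sequences, ~100 residues) this package targets.  It
is *not* Clustal Omega: conserved-column counts on real families are
engine-dependent, which is why such counts are treated as soft targets
(± a couple of residues).  One test cross-checks against MAFFT that both
engines recover the eight invariant cysteine columns of a simulated family.

## Conservation annotation

* Symbols follow the Clustal convention: `*` for an identical gap-free
  column; `:` when all residues of the column fall inside one Gonnet-PAM250
  "strong" group (pairwise score > 0.5): STA, NEQK, NHQK, NDEQ, QHRK, MILV,
  MILF, HY, FYW; `.` for one "weak" group: CSA, ATV, SAG, STNK, STPA, SGND,
  SNDEQK, NDEQHK, NEQHRK, FVLIM, HFY; blank otherwise.  Any gap in the
  column disqualifies all three.
* The percent conservation score of a reference residue X is
  `count(rows carrying X in that column) × 100 / N`, with N the panel size
  (default: number of rows; the conventional allergenic-LTP panel uses
  N = 15).  Only exact residue identity counts — similarity groups and gaps
  do not.  Scores are kept at full precision and *floored* to integer
  percent for display, matching the convention in which 14/15 is quoted as
  93 % and 2/15 as 13 %.

## Neighbor joining

Canonical Saitou–Nei NJ on the uncorrected MSA distance matrix (no
multiple-hit correction, by design).  Ties in the Q criterion break at the
lowest (row, column) index, negative branch lengths clamp to zero, and the
last three nodes join on one unresolved internal node (standard unrooted
binary tree).  NJ is exact on additive matrices; the tests exploit this by
round-tripping random trees through their patristic distance matrices, and
cross-check topology against scikit-bio's independent implementation on
noisy matrices.

## Epitope panel and consensus

* Seven published scales ship as data: Parker hydrophilicity, Emini surface
  accessibility, Karplus–Schulz flexibility, Kolaskar–Tongaonkar
  antigenicity, Chou–Fasman turn propensity, and polarity/exposure scales
  derived from Ponnuswamy's average surrounding hydrophobicity and Janin's
  buried transfer free energy (both negated so larger = more exposed, as
  stated in the data file).  All scales are oriented so larger = more
  epitope-prone.
* Per-residue statistic: arithmetic mean over a symmetric window (default 7,
  truncated at termini), except Emini's published product form
  (per-position value / 0.37, multiplied over the window).  Profiles are
  z-normalized per sequence; the default call is z > 0, except
  Kolaskar–Tongaonkar which keeps its published absolute rule (windowed
  mean propensity > 1.0).  A constant (zero-variance) profile yields no
  calls — the z-score is undefined and calling everything would be
  anti-conservative.
* Consensus: a residue is kept when at least `min_votes` profiles call it;
  the default rescales the classical ≥ 5-of-8 ensemble rule to the panel
  size (⌈5n/8⌉ = 5 for the 7-scale panel).  Kept residues merge into
  maximal runs; runs shorter than 6 residues are dropped.  Optional
  per-predictor weights exist to de-emphasize weak predictors without
  changing the rule (default all 1.0, since no principled reweighting is
  defined).  Linear-vs-conformational labeling is carried through from
  fixtures verbatim, never inferred — conformational prediction needs
  structure-aware models the panel does not have.
* The packaged fixtures (consensus regions for chickpea, mung bean, cowpea,
  pigeon pea and soybean LTPs; three validated peach epitopes) were checked
  row by row for coordinate/string consistency.  One validated peach row is
  quoted in the literature with a 15-position range but a 16-residue
  string; the loader keeps the string as authoritative and records the
  discrepancy in the region's `note` field rather than guessing.  Rows
  without a recorded note must be self-consistent or loading fails.

## Shared-motif analysis

Motifs are exact-identity substrings only (the triads quoted for LTP
epitopes are exact residue strings; similarity-based matching is the PD
index's job).  `shared_substrings` returns all common substrings
≥ `min_len` (default 4, the shortest motif of interest) reduced to the
maximal set — no reported motif is a substring of another reported motif.
The triad partition assigns each motif to its most specific Venn cell
(three-way beats two-way) and maximal-deduplicates per cell, so a pairwise
cell may properly contain a longer motif whose 4-mer core is three-way.
Every reported motif is verifiable by direct substring search in all listed
member epitopes, which is asserted in tests and by construction.  Sizes are
tiny (epitopes ≤ ~36 residues), so the brute-force enumeration is exact and
instantaneous.

## PD index

* Descriptor space: the published five-factor amino-acid property solution
  of Atchley et al. (2005) — a factor-analytic condensation of ~500
  property scales into polarity, secondary-structure propensity, size,
  composition and charge axes — shipped as a versioned data file.
* `pd(a,b) = c · (1/n) Σᵢ ‖d(aᵢ) − d(bᵢ)‖` on equal-length peptides.  This
  is a metric (non-negativity, identity of indiscernibles, symmetry,
  triangle inequality) and is invariant under self-concatenation, both
  property-tested.
* The single global constant `c` pins the conventional PD scale behavior:
  identity 0, conservative substitution < 4, random unrelated pair > 10.
  `calibrate` sets the median PD of 10,000 uniformly random unrelated
  10-mer pairs to the anchor 13 (comfortably above the >10 convention while
  keeping the worst within-strong-group single substitution in a 10-mer at
  ≈ 2.6, under the < 4 threshold).  The result (c ≈ 3.2301, seed 42) is
  persisted in `data/pd_calibration.json` and never recomputed silently;
  rescaling the descriptor table rescales `c` inversely, leaving all PD
  values invariant.
* `db_scan` evaluates every query-length window of every database sequence
  (no gapped peptide matching — PD is positional) and reports windows under
  the threshold (default 4), sorted by PD, subject, offset.

## Synthetic families

* Defaults model a mature type-1 LTP: length 93, invariant cysteines at
  positions 3, 13, 27, 28, 48, 50, 73, 87 (the classical eight-cysteine
  scaffold).  Descendants of a uniform-random ancestor mutate site-wise;
  substitutions stay within a residue's Clustal strong group with
  probability 0.5, else go uniformly to any other residue.  Cysteine sites
  never mutate; planted motifs overwrite designated descendants after
  mutation (colliding with the scaffold is an error unless explicitly
  allowed).  Indels are off by default so Hamming identity is exact ground
  truth.
* The per-descendant mutation rate is derived from the requested
  descendant–descendant identity: two lineages diverge independently, so
  for target t, scaffold length L and k cysteines the rate solves
  `(k + (L−k)(1−r)²)/L = t`; chance convergence of two substitutions adds
  ≈ +0.01, keeping realized identity within the ±0.05 tolerance the tests
  assert.
* `generate_tree_family` evolves sequences down an arbitrary phylogeny with
  per-branch mutation probability `1 − exp(−rate·length)`, providing the
  oracle for NJ topology recovery (≥ 18/20 seeds on a balanced quartet with
  a long internal branch).
* What the simulator does *not* model: indel processes (optional only in
  principle, absent here), site-rate heterogeneity, hydrophobic-core or
  disulfide-pairing constraints beyond fixed cysteines, and real LTP
  residue composition.  Green tests on synthetic families therefore
  demonstrate algorithmic correctness under a clean substitution model, not
  performance on real divergent LTPs.

## Problem sizes and determinism

Test and acceptance runs use small, fixed problem sizes chosen to exercise
every code path with exact oracles: exhaustive alignment enumeration up to
8-mers, families of 4–10 sequences × 93 residues, 10,000-pair PD medians,
20-seed topology recovery.  All randomness flows through seeded NumPy
generators; the pipeline's outputs are byte-identical across reruns with
the same config, which a test asserts.

## Known limitations

* The progressive aligner and the screen's BLOSUM62 defaults are reasonable
  stand-ins for, not reproductions of, the specific engines behind public
  allergen-database searches; decimals differ, bounds hold.
* The propensity panel is not a trained epitope predictor; its regions on
  real proteins should be read as candidate surface/flexible stretches
  feeding the downstream motif and PD analyses.
* Accession-based checks (real chickpea/lentil/peach etc. sequences) need a
  one-time fetch script run with network access; the repository ships no
  third-party sequence data beyond the short published epitope strings.
* Percent conservation assumes the reference row is part of the alignment;
  mapping validated epitope coordinates from a precursor to a mature chain
  uses the C-terminal 91-residue convention and is the caller's
  responsibility to verify against a signal-peptide annotation.
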