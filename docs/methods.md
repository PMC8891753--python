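# Methods

## Problem setting

Light-harvesting complex (LHC) proteins of Chromista — fucoxanthin
chlorophyll *a/c*-binding proteins (FCPs) — fall into families with
distinct roles: Lhcf (PSII antenna, the majority family), Lhcr
(PSI-associated, with an Lhcz sister sub-clade of unknown function) and
Lhcx (photoprotection). Annotating a newly sequenced proteome means (i)
finding all FCP genes, (ii) placing each in a family, and (iii) locating
the pigment-binding residues on the Lhcf monomers by homology with a
crystallographically characterised reference. `fcptools` implements this
workflow as a reusable, fully deterministic pipeline with a synthetic
truth-generating counterpart for validation.

## Similarity engine and discovery

Candidates are found by exhaustive affine-gap Smith-Waterman (Gotoh
recurrences; a gap of length *k* costs open + *k*·extend) rather than a
seeded heuristic: at desk scale (hundreds of proteins) full dynamic
programming is affordable and removes a source of irreproducibility. The
DP fill is a numba-compiled kernel; traceback ties break to the
lowest-coordinate optimum, so alignments are unique.

Raw scores are converted to bit scores with the standard gapped BLOSUM62
Karlin-Altschul constants (λ = 0.267, K = 0.041; fixed module constants,
overridable per call) and to expectations E = m·n·2^(−bits) with m the
query length and n the total database residue count. This makes the
conventional survey cutoff E < 10⁻⁴⁰ meaningful for discovery; the cutoff
is configurable (`e_threshold`) since published surveys do not always
state the value used for the target proteome itself.

## Family classification

A candidate is assigned the family of its best bit-scoring hit against
labelled reference panels (the best-similarity-match rule). A call is
flagged *ambiguous* when fewer than two qualifying hits exist or when the
margin between the best and the best other family is below `margin_bits`
(default 10 bits ≈ a 1000-fold E-value ratio; the threshold is a design
choice — the motivating case is a candidate with one single weak
cross-family match). Ambiguous calls are resolved on the cladogram: the
smallest enclosing clade holding at least `min_labeled` (default 3)
labelled panel leaves votes by majority family; ties stay unclassified.
This mirrors how practitioners resolve single-weak-hit artifacts (e.g. an
Lhcf protein whose only BLAST match happens to be an Lhcr sequence) and
leaves genuinely uncertain sequences (the Lhcx5-type case) explicitly
unresolved rather than forcing a label.

## Alignment

`progressive_align` is a classical progressive aligner: pairwise
Smith-Waterman identities give guide distances (d = 1 − identity over the
local alignment), a neighbor-joining guide tree orders the merges, and
profiles are merged by global profile-profile alignment with average
sum-of-pairs column scoring (gap pairings score zero) under the same
affine penalties. There is no iterative refinement; the downstream
statistics (distance matrices, per-column residue lookups) are robust to
modest alignment differences, and column-exact reproduction of any
specific external aligner is not a goal. Every row is checked to ungap
back to its source sequence after each alignment.

Residue positions and alignment columns are both reported 1-based
(crystallography convention); 0-based indices exist only internally.

## Distances, trees, supports

Protein p-distances use pairwise deletion (only columns where both rows
are ungapped). The Jukes-Cantor correction uses the 20-state form
d = −(19/20)·ln(1 − (20/19)·p), consistent with amino-acid sequences;
p ≥ 19/20 is saturation and an error (inside bootstrap replicates, where
single resamples can saturate, p is clamped just below the pole).

Neighbor joining is the canonical Q-criterion algorithm. Determinism is
guaranteed by breaking Q-ties toward the pair whose sorted representative
leaf names are lexicographically smallest; negative branch lengths are
clamped to zero and the deficit logged. NJ is exact on additive matrices,
which the test suite exploits (200/200 random additive 5–8-taxon trees
recovered; cross-checked against an independent NJ implementation).

Bootstrap supports resample alignment columns with replacement; each of
`bootstrap_reps` (default 100) replicates is taken through distances and
NJ, and each internal edge of the main tree is annotated with the
percentage of replicates containing its bipartition. Replicate RNG
streams derive from one root seed by replicate counter, so runs are
reproducible and individually parallelisable. The NJ root is an arbitrary
trifurcation; for reading clades off a cladogram the tree is
midpoint-rooted (`midpoint_root`), the only rooting the package performs.

### Lhcf groups A–D

Lhcf clades are labelled by lineage composition, walking the (rooted)
tree top-down and labelling each maximal qualifying clade (size ≥
`min_size` = 3, support ≥ `min_support` = 50 where supports exist):
all-haptophyte → B, all-diatom → C, all-seaweed → D, haptophyte-majority
mixtures containing at least one diatom → A; everything else is
descended into, and uncovered leaves stay unassigned. The thresholds are
design defaults — published cladograms display supports only for main
nodes and state no cutoffs.

## Binding-site transfer

A reference annotation row (site id, pigment, ligand class — central
coordination vs H-bond — reference sequence and 1-based position, primary
residue, optional alternates) is validated against the reference sequence
at load time. Transfer maps the reference position to its alignment
column; a target is *present* at offset 0 when its residue in that column
is allowed. Otherwise target residues at amino-acid offsets ±1…±w are
scanned, nearest first (negative first on ties, the anchor residue first
when the target is gapped at the column). Offsets are measured in target
residues with gaps skipped, because documented shifts are stated in amino
acids; the default window w = 3 equals the largest shift reported for
this system (a fucoxanthin-site tyrosine displaced by 3 residues). `X`
never matches. Matches via an alternate residue are flagged so conserved
and non-conserved ligand columns can be reported separately.

Percentages are rounded half-up to integers, and the denominator is
always the full family membership (whether fragmentary proteins should be
excluded is unstated in the source material; including all members is the
simpler, documented choice). A pigment site with several ligand residues
counts as "found" when at least one of them has nonzero presence. Two
fucoxanthin sites whose reference contacts run through chlorophyll *c*
(Fx306/Fx307) are representable in annotations but excluded from default
reports, since cross-species comparison of those cells is not meaningful.

One packaged reference cell is known not to be self-consistent: the
published 25% value for the second fucoxanthin site's tyrosine in the
17-member reference panel corresponds to no integer numerator (no k/17
rounds to 25). The packaged table carries the printed value, the pipeline
always computes its own percentages from counts, and this cell is
excluded from comparisons.

## Synthetic data

The generator emulates the statistical structure the analysis relies on,
with exact knowledge of truth:

* **Trees**: one Yule (pure-birth) tree per family, rescaled to unit
  root-to-tip depth so the substitution rate *is* the root-to-tip
  Jukes-Cantor distance.
* **Evolution**: uniform 20-state exchange (equal rates), matching the
  Jukes-Cantor assumption downstream, so p-distance recovery is
  analytically checkable: P(site differs after distance d) =
  (19/20)(1 − e^(−20d/19)).
* **Defaults as study conditions**: root length 200 aa (a typical mature
  LHC protein), `subst_rate` 0.26 → within-family identity ≈ 60%,
  family roots 0.48 each from a grand root → between-family identity
  ≈ 25%; 3 families of 20 with 5 held out as queries. These are the
  conditions under which best-hit classification of FCP families
  operates, and they are not tuned per experiment.
* **Sites**: binding residues are implanted *after* evolution, so
  per-sequence retention is an exact Bernoulli draw and presence
  percentages have a clean binomial truth. A retained site may be
  displaced by up to `max_shift` residues with probability `shift_prob`.
* Same seed ⇒ byte-identical FASTA and truth outputs.

What the generator does **not** emulate: indels (alignment stages are
exercised with substitution-only families plus hand-made gapped
fixtures), compositional bias, rate heterogeneity across sites, and the
motif structure of real LHC transmembrane helices. Passing tests
therefore demonstrate correctness of the machinery under the stated
model, not performance guarantees on real proteomes.

### A note on measuring site recovery

With the shift-scan window w > 0, an absent site can be "found" by a
coincidentally matching residue nearby; under a uniform residue
background the false-positive floor is ≈ (1 − retention)·(1 − (19/20)^(2w))
— about 2.7 percentage points at w = 3. Recovery of an implantation model
without shifts is therefore measured with w = 0 (the estimator matched to
the truth model); shift detection is validated separately with
constructed shifted fixtures. On real data the window trades exactly this
specificity for sensitivity to genuinely shifted sites.

## Numerical and degenerate-input choices

* Smith-Waterman score 0 ⇒ empty spans, no alignment strings.
* Single sequence ⇒ 1-row MSA; empty input ⇒ error.
* NJ needs ≥ 3 taxa; bootstrap needs ≥ 4 rows and a non-zero distance
  matrix (all-identical alignments are rejected as signal-free).
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; nothing reads global RNG state.

## Problem sizes used in validation

The packaged validation suite runs entirely on synthetic data: 200
additive matrices (5–8 taxa) for NJ exactness, 50 seeds of random 8-mers
against a brute-force alignment oracle, 30 seeds of 28-member families
for presence recovery, 20 seeds of the default 3-family panel for
classification recovery, and one 150-sequence alignment with 100
bootstrap replicates as the study-scale end-to-end run. The acceptance
script reproduces the headline counts on a 112-protein synthetic proteome
(28/12/12 homologs + 60 decoys) and a 28-member annotated Lhcf family.

## Known limitations

* Best-hit classification inherits the reference panels' coverage; a
  family absent from the panels can only come out `unclassified`.
* The progressive aligner has no refinement pass and will be inferior to
  modern aligners on gappy, low-identity sets; it is adequate for the
  ≥ 25% identity regime the pipeline targets.
* E-value constants assume BLOSUM62 11/1; other matrices/penalties would
  need their own λ and K for calibrated cutoffs.
* Group A–D labelling is a greedy top-down composition rule; unusual
  topologies where a pure clade nests directly inside a qualifying mixed
  clade are resolved in favour of the enclosing (maximal) clade.
* Transferred sites are homology candidates only; confirming that a
  residue truly binds pigment requires structural evidence.
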