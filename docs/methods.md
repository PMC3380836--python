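# Methods

This note documents the models, conventions, parameter choices and known
limitations behind `ovolkit`, in the order a pipeline run encounters them.

## Coordinates

All coordinates are 1-based and fully closed: the span 118–140 covers
23 residues (140 − 118 + 1). This matches how protein motif coordinates
are printed in the literature; conversions to Python slices happen at the
I/O boundary only. Residue alphabets are the 20 standard amino acids plus
`X` (unknown); `*` is rejected because a stop codon inside a protein
string indicates an upstream translation/parsing fault.

## Pattern engine

The supported dialect is the Prosite subset used for C2H2 zinc fingers:
bare residues, bracket sets, and bounded wildcards `x`, `x(n)`, `x(n,m)`,
joined by `-`. Prosite's `{...}` exclusions and `<`/`>` anchors are
rejected explicitly rather than silently ignored.

Three conventions matter for reproducibility:

* **Exceptional residues.** Lowercase bracket members (e.g. the `sgat` of
  `[Fsgat]`) mark rarely observed residues. They are *allowed* during
  scanning exactly like uppercase members; the case distinction is
  preserved only for rendering and reporting, because it encodes observed
  frequency, not matching semantics.
* **Unknown residues.** An `X` in a sequence satisfies wildcards only. It
  can never certify membership of a bracket set or fixed letter, since an
  unknown residue cannot be shown to be one of the listed ones.
* **Variable repeats.** At each anchor, wildcard widths are expanded
  shortest-first. The default `leftmost-non-overlapping` mode emits the
  greedy left-to-right cover (tandem zinc fingers do not overlap);
  `all-overlapping` enumerates every satisfying (start, length).

`find_tetrad` looks for four consecutive non-overlapping matches whose
inter-motif gaps are at most `max_linker` residues (default 20; observed
linkers in the family are 5, 5 and 15 residues). `rightmost_tetrad`
solves the same problem over *overlapping* candidate matches by choosing
motif IV as the rightmost match and extending leftward with backtracking;
`build_architecture` uses it because a chance cysteine a residue or two
upstream of a real finger can derail the greedy cover, while the
C-terminal-most compact chain is unambiguous.

### Consensus derivation

`derive_pattern` works per alignment column over the motif instances:
residues at frequency ≥ `f_major` (default 0.2) become uppercase members,
rarer observed residues become lowercase exceptional members, and a column
whose top frequency falls below `f_wild` (default 0.5) becomes a wildcard.
Columns in which any instance is gapped join the wildcard consolidation,
so the derived pattern always re-matches every ungapped instance
(self-consistency); consolidated wildcard runs render as `x(n)` or
`x(n,m)` with bounds taken from the per-instance covered lengths — which
may include `x(0,m)` when an instance skips the run entirely, so the
parser accepts a zero minimum. Bracket members are ordered by descending
frequency with ties broken by first appearance down the column, which is
what reproduces brackets like `[Fsgat]` byte-for-byte. The two thresholds
are exposed because no canonical values exist; the defaults reproduce the
published bracket shapes on frequency mixes like F 0.8 / S,G,A,T 0.05.

### Logo matrices

Per column, frequencies are renormalized over non-gap residues and the
information content is `log2(20) − H` bits, optionally minus the
small-sample correction `e_n = 19/(2 ln2 · n)` (n = non-gap count),
clamped at zero. The correction defaults on, mirroring WebLogo 3.
All-gap columns carry zero frequencies and are flagged rather than
dropped, so an instance with a single-column insertion widens the matrix
by exactly one column. Rendering graphics is out of scope; the matrix is
the deliverable.

## Disorder and compositional bias

Disorder prediction itself is a trained classifier in external tools; the
package consumes their per-residue output (position, residue, score in
[0,1], optional state) and derives missing states from a 0.5 score
threshold. `call_disordered_regions` reports maximal disordered runs of
length ≥ `min_len` (default 5).

`find_bias_patches` slides a window (default 20 residues) per residue
type and merges windows in which that residue's frequency is ≥ `min_frac`
(default 0.35) into maximal patches, finally trimming each patch to the
first/last occurrence of the biased residue so boundaries sit on the
residue itself. Without the trim, a window straddling the edge of a
homopolymer run can drag neighboring positions into the patch and even
fuse two distinct patches across a spacer. Patches for different residues
may overlap and all are reported — nested His-rich/Asn-rich arrangements
are real features of ID regions, not errors. Published bias patches in
this family range from 21 to 322 residues; the defaults are exposed in
configuration because no canonical thresholds exist.

## Architecture

The core is the span from motif I start to motif IV end, linkers
included — the tetrad is treated as one conserved domain. N- and
C-extension lengths follow by arithmetic, and always satisfy
`n_ext + core + c_ext = total`. When a protein carries more than four
candidate fingers the C-terminal-most compact tetrad is chosen, because
the conserved tetrad of this family sits at the C-terminal end. Scanning
a family with its own consensus pattern (for OVOL-like families,
`C-x(2)-C-x(3)-[FWsgat]-x(8)-H-x(3,4)-H`) is recommended over the generic
C2H2 pattern: the generic pattern's wider tail (`x(3,5)`) admits
one-residue motif inflation from chance histidines, and its bracket set
omits the exceptional residues the family's motif IV actually uses.

## Divergence

p-distance is the proportion of differing sites among comparable sites,
with pairwise deletion: a site is comparable for a pair only when both
members carry a standard residue. `X` is excluded along with gaps — an
unknown residue can certify neither match nor mismatch. Bootstrap
variance resamples alignment columns (of the active subset) with
replacement, recomputes the pair's distance per replicate, and reports
the unbiased sample variance over defined replicates (default 1000,
seeded).

`partition_columns` converts per-sequence disorder calls into alignment
partitions: each row's disordered intervals are projected onto columns,
and a column is disordered when more than `rule_frac` (default 0.5) of
its non-gap residues are disorder-annotated in their own row. How the
original analyses turned per-protein disorder calls into alignment
partitions is not documented anywhere; column majority voting is the
implemented default, and a per-pair alternative (a site counts as
disordered for a pair only when both members are annotated) is available
via `pair_rule="pairwise"`.

`compare_partitions` computes distances on the full, structured-only and
disordered-only site sets, emits five-number box-plot summaries, and runs
Kruskal–Wallis across the three distance collections. A statistical
caveat is inherited deliberately: pairwise distances are not independent
observations (each sequence participates in many pairs), so the KW
p-value is a descriptive screen rather than a calibrated test. The
statistic itself is computed exactly as defined — midranks, the tie
correction `1 − Σ(t³−t)/(N³−N)`, χ² with k−1 df — with `H = 0` by
convention when all values are identical, and an optional seeded
permutation p-value for small samples. It cross-checks against an
independent implementation to machine precision in the test suite.

Neighbor joining (via scikit-bio, negative branch lengths clamped to
zero) provides a light clustering check on the p-distance matrix. It
reconstructs additive matrices exactly, which the test suite exploits:
random additive trees of up to 8 taxa are recovered with Robinson–Foulds
distance 0. It is not a substitute for model-based phylogenetics;
substitution-model selection and Bayesian inference are out of scope.

## Micro-synteny

A locus is a focal gene (possibly lost) plus ordered flanking markers
with family assignments. Verdicts score marker *presence* within a rank
window (default 8) on each side:

* `orthologous` — ≥ `min_ortho` (default 3, a conserved triad) identical
  marker genes shared;
* `paralogous-duplication` — fewer identical genes but ≥ `min_para`
  (default 2) marker *families* shared: two homologous flanking pairs
  (e.g. BANF1/BANF2 plus SNX32/SNX5) are the minimal footprint of a
  segmental duplication;
* `duplicate-retained-original-lost` — a focal-less locus that still
  shares ≥ `min_ortho` markers with a reference genome's focal-bearing
  locus, plus at least one paralogous family pair (distinct genes, same
  family, e.g. AKT2a/AKT2b) linking it to the focal-bearing duplicate.

Marker order and strand are recorded and reported but never scored;
colinearity statistics, genome-browser extraction, and absence claims
over whole genomes (only absence within a supplied table can be reported)
are out of scope.

## The synthetic family generator

`simulate_family` emulates the statistical structure the analysis
assumes, with homology tracked per site so a gap-true alignment and exact
truth annotations come out alongside the sequences.

* **Core**: four C2H2 templates (21/21/22/22 aa, linkers 5/5/15) whose
  Cys/His anchors are hard-invariant by default — failures downstream
  then indicate pipeline bugs, not simulation luck; a flag re-enables
  anchor mutation for robustness testing. The post-Cys set position
  mutates only within {F,W,S,G,A,T}, the states the family consensus
  allows. Other core sites substitute at `p_core` per unit branch length
  (default 0.02), drawing the replacement uniformly from the other 19
  residues — no empirical exchangeability matrix, since the downstream
  statistics are distance-based, not model-based.
* **Extensions**: drawn once at the root per configured side (`N` by
  default; per-lineage sides accepted), length uniform on
  `id_length_range` (default 100–1000 aa, the published range), then
  evolved at `p_id` (default 0.4) with indels: geometric lengths of mean
  3, insertion and deletion equiprobable, rate 0.02 per site per branch.
  With probability 0.5 a segment is compositionally biased, its dominant
  residue at frequency 0.5; substitutions and insertions redraw from the
  segment's own composition so the bias is stationary. Because the
  extensions descend from a root segment, they stay alignable while
  diverging toward saturation — real lineage-specific extensions are
  outright non-homologous, which is *more* divergent, so passing the
  structured-vs-disordered ordering here is the conservative direction.
* **Tree**: a user Newick guide tree, or a star tree with unit branches
  over `n_taxa` (default 6). Per-branch substitution probabilities scale
  as `1 − (1 − p)^length`.

What the generator does *not* emulate: among-site rate variation within a
partition, empirical amino-acid exchangeabilities, alignment error (the
emitted alignment is the true one), and genuinely non-homologous
extensions. Tests passing on simulated families therefore demonstrate
the pipeline's correctness under its own assumptions, not the biological
conclusions themselves.

Disorder tracks derived from truth (`emit_disorder_tracks`) score 0.9
inside true ID regions and 0.1 elsewhere, plus optional Gaussian noise,
clamped to [0,1] with states at the 0.5 threshold — noise-free tracks
round-trip exactly to the truth intervals.

## Reference stand-ins

No sequences are downloaded. `ovolkit.standins` constructs deterministic
*synthetic* proteins whose architecture matches published coordinates for
human OVOL1 (267 aa; motifs 118–140, 146–168, 174–197, 213–236) and
fruit-fly OVO-B (1351 aa; motifs 1197–1315; seven single-residue-bias
regions at the published spans). Cysteine never occurs outside the
intended anchors, so scans find exactly the intended fingers. The
published His-rich span "645–665 (39 aa)" is internally inconsistent (the
interval holds 21 residues) and is excluded everywhere. These stand-ins
validate coordinate arithmetic, scanning and architecture partitioning;
they are not the database sequences and carry `SYNTHETIC` in their ids.

## Problem sizes

Default verification sizes, chosen to characterize behavior tightly while
keeping any run interactive: 200 randomized cases for pattern-engine
equivalence, 100 random additive trees for NJ recovery, 100 simulation
replicates (6 taxa each) for the divergence contrast, and 10 families × 8
taxa for architecture recovery. The full test suite runs in well under a
minute on one CPU.
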