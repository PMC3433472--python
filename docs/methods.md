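# Methods

`selexkit` analyzes high-throughput sequencing data from a
cell-internalization SELEX experiment: per-round Illumina reads of an RNA
library whose 20-nt random region is flanked by fixed constant regions.
This note documents the models, conventions, defaults, and known
limitations of each stage.

## Preprocessing

Reads are demultiplexed by an exact match of a per-round 5′ barcode
(prefix of the read; the reverse complement of the read is tried when the
forward orientation fails, and the read is re-oriented on success).  The
variable region is the substring strictly between the first occurrence of
the 5′ constant (`GGGAGGACGATGCGG`, the tail of the Sel2 5′ primer) and
the next occurrence of the 3′ constant (`CAGACGACTCGCCCGA`, the reverse
complement of the Sel2 3′ primer).  Flank matching tolerates a
configurable number of Hamming mismatches (default 0 — no indels in
flanks, since flank indels cannot be distinguished from variable-region
boundary shifts).  Extracted regions are rejected with a reason code when
a flank is unmatched, when they contain an ambiguous base (N), or when
their length falls outside 18–22 nt; 18–22 nt is retained as the analysis
window because indel drift during selection produces real 19/21-nt
variants around the nominal 20.  Rejection is bookkeeping, not an error:
assigned + rejected always equals the input read count.

Per-round reads are collapsed to unique variable regions with duplicate
counts ("cluster sizes"); replicate sequencing runs of the same round
(round 0 is commonly sequenced twice) are merged by summing counts.  The
cross-round non-redundant database assigns ids in descending total-read
order and serializes in the published CSV column layout (id,
representative flag, variable region, length, per-round reads, total,
rounds, full RNA, dot-bracket, sequence family, structure family).  The
full-length RNA is 5′ constant + T→U-converted variable region + 3′
constant (15 + var + 16 nt).

## Round metrics

Complexity `C = U/T` and % Enrichment `E = 1 − C` per round, where `U`
and `T` are unique and total filtered reads.  The round of 50% enrichment
is located by a four-parameter logistic least-squares fit
`E(x) = bottom + (top − bottom)/(1 + exp(−k(x − x0)))` with
`0 ≤ bottom, top ≤ 1`, initialized at (bottom 0, top 1, x0 = median
round, k = 1); the midpoint is `x0` and is flagged when it falls outside
the observed round range.  Length distributions are read-weighted; SEM
uses the n−1 variance denominator with read counts as frequency weights.
The two-pool length comparison is a pooled-variance Student's t-test
computed from weighted moments (equivalent to expanding each read).

A sequence's **cluster size** is its maximum per-round duplicate count.
The total-reads alternative is recomputable from the stored per-round
counts; the maximum convention is used because it matches the behaviour
of round-0 singletons, which have small clusters regardless of how many
rounds they straddle.  The **true-selected** filter keeps sequences
present in ≥ 2 selection rounds with cluster size ≥ 3; round 0 (the
unselected library) is excluded from both criteria.  The filter returns
an exact two-part partition of its input.

## Secondary structure

Each unique sequence is assigned a single structure — its
minimum-free-energy (MFE) structure — plus four ensemble statistics:
ensemble free energy `G_ens = −RT ln Z`, MFE-structure probability
`P_mfe = exp(−G_mfe/RT)/Z`, and ensemble diversity
`D = Σ_{i<j} 2 p_ij (1 − p_ij)` (the expected base-pair distance between
two independent draws from the Boltzmann ensemble, where `p_ij` is the
probability that bases i and j pair).

The builtin engine is a deliberately simplified thermodynamic model:
additive pair energies (GC/CG −3.0, AU/UA −2.0, and GU/UG −1.0 kcal/mol
when wobble pairs are enabled), no dangles and no loop penalties, a
minimum hairpin loop of 3 nt, no pseudoknots, and — by default — no
lonely pairs.  RT is computed at the configured temperature (default
30 °C).  The no-lonely-pair constraint is exact, via a three-nonterminal
grammar (free segment / inward-stacked pair / non-stacked pair reachable
only under an outward stack); MFE runs the grammar in min-plus form with
a deterministic traceback (pairing preferred over leaving a base
unpaired; smallest partner index; stack continuation preferred), the
partition function runs it in sum-product form, and an outside pass
yields exact `p_ij`.  The design trade is transparency for realism:
every quantity is checkable against exhaustive structure enumeration at
small lengths (the test suite verifies agreement to 1e-9 relative), while
absolute energies are not comparable to nearest-neighbor engines.  For
realism an adapter drives an external partition-function folder
(ViennaRNA's `RNAfold -p` console layout is parsed), and all downstream
family analyses consume dot-brackets only, so they are engine-agnostic.

Pool-level structure summaries are reported unique-weighted (plain mean
over unique sequences) and read-weighted (each unique sequence with
multiplicity equal to its read number), with SEMs as above.

## Distances and families

Sequences are compared by Levenshtein edit distance on the variable
region (the constant regions are shared and contribute zero; full-length
comparison is available).  Structures are compared by ordered tree edit
distance (Zhang–Shasha, unit insert/delete/relabel costs) on a tree
encoding where each base pair is a `P` node, each unpaired base a `U`
leaf, and a virtual root holds the exterior; this encoding is internally
consistent but not numerically identical to external "full tree"
conventions, so thresholds are configurable.  The Zhang–Shasha kernel is
JIT-compiled (numba) to keep the O(n²) all-pairs pass practical at
thousands of structures; identical strings are deduplicated first and
pairs whose lengths differ by more than the distance cap are skipped
outright (both exact optimizations).

Families are connected components of the threshold graph: sequence
families at edit distance ≤ 1, structure families from tree-distance
components at 3 grown per-family up to 6 — each family (processed in
descending read order) absorbs nodes reachable at higher thresholds until
a step would merge it with another family's members.  Components of size
1 are singletons, not families.  Merge heights over increasing integer
thresholds form a single-linkage dendrogram (union-find over
distance-sorted edges; verified against textbook single-linkage
clustering), exportable as Newick.  Family labels are Roman numerals
(sequence) and letters (structure) in descending total-read order.

## Enrichment scoring and candidates

Counts are normalized within each round, `a_r = max(c_r, 1)/T_r`; a read
number of 1 is substituted for zeros before division so ratios stay
finite.  The alternative grand-total denominator is available by flag and
noted in output metadata.  Over a window of rounds (defaults 1–3, 1–8,
3–8, 6–8; only sequenced rounds are used, and windows with fewer than two
sequenced rounds are unscored):

* fold enrichment `FE = a_late/a_early`;
* rate enrichment `RE = (a_late − a_early)/(round_late − round_early)`,
  reported in reads-per-million per round for readability;
* rising `ρ` = Pearson correlation of abundance with round number
  (Spearman variant by flag; 0 by convention for constant abundance;
  undefined below three rounds).

One representative per family per window is the member maximizing
(FE, then RE, then total reads, then smallest id) — a total order, so
selection is independent of input ordering.  The candidate set is the
union over windows from both family kinds plus orphans: sequences in no
family with total reads ≥ 100 (configurable; chosen well below the
published orphan's 506 reads).  Edit-only/both/tree-only counts summarize
the two candidate sets.

Candidate metrics are correlated with measured fold internalization by
Spearman's rank correlation: Pearson on mid-ranks (average ranks for
ties), two-tailed p from the exact permutation distribution for n ≤ 9
and the t approximation with n − 2 df otherwise; Shapiro–Wilk normality
p-values are annotations only.  Raw p-values are reported without
multiple-testing correction across the grid, mirroring common practice
for this screen; treat borderline cells accordingly.

## Synthetic data generator

The generator emulates the study design at desk scale: a background
library of distinct random 20-nt regions (default 10,000 — large enough
that round 0 is only partially saturated at the default depth, small
enough for fast end-to-end runs); planted families, each a founder plus
n distinct variants at edit distance exactly 1, with founder fitness f
(≥ 1) and variants at `0.9 f` by default (mutational load: the founder is
the fittest member, which is what makes founder recovery a meaningful
target); seven pools labelled 0–6 at default depth 10,000 each.  Round 0
is the unselected library; selection acts from round 1, with the true
abundance following `a_r(i) ∝ a_0(i)·fitness(i)^r` exactly (closed form
verified in tests) and reads drawn multinomially at each round's depth.
Substitution/insertion/deletion noise is applied per base to the variable
region after sampling (sequencing/PCR error, not heritable); a heritable
mode applies mutant lineages to the pool instead.  Reads are emitted as
barcode + 5′ flank + region + 3′ flank in FASTQ with constant qualities.
A single seeded generator with documented draw order (families, then
background, then per-round sampling and errors) makes output byte-
reproducible.

What the generator does **not** emulate: position-dependent sequencing
error and quality profiles, PCR amplification bias, binding-site sequence
structure (fitness is assigned, not computed from structure), or the
10^14-scale diversity of a real round-0 library.  Passing recovery tests
therefore demonstrate the pipeline's correctness under the stated noise
and enrichment model, not performance on any particular real selection.

## Problem sizes and numerical choices

End-to-end validation runs 20 replicates of six selection rounds at depth
10^4 with three planted families (five 1-edit variants each, fitness 10,
substitution rate 1e-3) and checks founder recovery among candidates,
member-to-family assignment, and monotone increase of % Enrichment across
the selection rounds 1–6.  Round 0 → 1 is excluded from the monotonicity
check: before selection has acted twice the expected enrichment increment
(~0.006 at these depths) is below the sampling noise floor of the
unique-read count, so monotonicity there would test the noise, not the
method.  The windows used for the six-round design are 1–3, 1–6, 3–6 and
4–6, the same early/full/post-change/late structure as the published
eight-round windows.

Energies are sums of exactly representable halves, so MFE traceback uses
exact float equality; partition functions stay well inside float64 range
for sequences up to ~100 nt (no rescaling).  Ties in family ordering are
broken by smallest member id; all orderings in serialized artifacts are
deterministic.  Degenerate inputs are contracts, not crashes: empty pools,
constant enrichment (sigmoid fit), constant variables (correlation) and
zero-width windows raise typed errors; unpairable sequences fold to the
open chain at 0 kcal/mol with Z = 1, P = 1, D = 0.

## Known limitations

* The builtin energy model's absolute values are not comparable to
  nearest-neighbor engines; only qualitative trends (and anything
  computed from dot-brackets) transfer.  The external adapter covers the
  realistic case, including its `-d2` dangle treatment, which the builtin
  model does not implement.
* The lonely-pair definition is exact for the builtin grammar but only
  approximately matches the external engine's `--noLP`.
* Automated family calling replaces manual alignment curation; on real
  data the family count may differ from a curated count, and the adaptive
  structure-threshold rule is one deterministic reading of per-family
  thresholds "between 3 and 6".
* Whether a real analysis's cluster-size rule used max-per-round or total
  reads is ambiguous; both are computable here, max-per-round is the
  default.
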