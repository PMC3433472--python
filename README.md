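# selexkit

Bioinformatics analysis of **cell-internalization SELEX** sequencing
data.  A cell-based aptamer selection enriches, over successive rounds,
for RNA sequences that internalize into a target cell type; Illumina
sequencing of each round then yields millions of reads from which the
"winner" aptamers must be identified.  `selexkit` implements the full
computational arm of that experiment, for anyone running (or simulating)
a multi-round nucleic-acid selection:

1. **Preprocessing** — demultiplex per-round reads by barcode, extract
   the 18–22-nt variable region between the library's constant flanks,
   collapse duplicates, and build the non-redundant cross-round sequence
   database (published CSV layout).
2. **Round metrics** — per-round complexity `C = U/T` and
   % Enrichment `E = 1 − U/T`, with a four-parameter logistic fit
   locating the round of 50% enrichment; read-weighted variable-region
   length distributions; recurrence (rounds-present) and cluster-size
   histograms; the *true-selected* filter (≥ 2 rounds and cluster
   size ≥ 3).
3. **Structure** — one MFE secondary structure per sequence plus
   ensemble statistics (`G_ens = −RT ln Z`,
   `P_mfe = e^{−G_mfe/RT}/Z`, diversity `D = Σ 2p_ij(1−p_ij)`) from a
   builtin simplified thermodynamic engine that is exactly verifiable by
   enumeration, or from an external engine (ViennaRNA `RNAfold` console
   output is parsed).
4. **Families** — pairwise Levenshtein edit distance on variable regions
   and Zhang–Shasha tree edit distance on structures; threshold-graph
   connected components become sequence families (edit distance ≤ 1) and
   structure families (tree distance 3–6, per-family adaptive);
   single-linkage dendrograms with integer merge heights.
5. **Ranking** — normalized abundances with a read-number-1 substitution
   for zeros; fold enrichment, rate enrichment, and *rising* over round
   windows; one representative per family per window; orphan detection;
   edit-vs-tree candidate comparison.
6. **Correlation** — Spearman rank correlation (exact permutation p at
   small n) of candidate metrics against measured fold internalization.

A first-class synthetic-data generator (`selexkit.selexsim`) simulates
whole selections with planted enriched families and ground-truth
manifests, so every stage is testable end to end without any external
data.

## Worked example

Simulate a five-round selection over a 5,000-member library with two
planted families (founder fitness 10, three 1-edit variants each at 70%
of the founder's fitness), then run the full pipeline:

```python
from selexkit.selexsim import SimConfig, PlantedFamily, simulate_selex, evaluate_recovery
from selexkit.pipeline import PipelineConfig, run_from_reads

config = SimConfig(
    seed=42, library_size=5000, depths=(4000,) * 5,
    planted_families=[PlantedFamily("ACGTACGTACGTACGTACGT", 3, 10.0),
                      PlantedFamily("TTGGCCAATTGGCCAATTGG", 3, 10.0)],
    variant_fitness_factor=0.7,
    substitution_rate=0.001,
)
sim = simulate_selex(config)
reads = [r for rnd in sorted(sim.reads) for r in sim.reads[rnd]]

pipe = PipelineConfig(barcodes=config.barcode_map, fold_engine="builtin",
                      windows=((1, 2), (1, 4), (2, 4)))
result = run_from_reads(reads, pipe)

for s in result.summaries:
    print(f"round {s.round_label}: {s.total_reads} reads, "
          f"{s.unique_reads} unique, enrichment {s.enrichment:.1%}")
print("true-selected:", len(result.true_selected))
print("sequence families:",
      [(f.label, len(f.members)) for f in result.sequence_families])
print("candidates:", len(result.candidates.all_ids),
      "venn (edit-only, both, tree-only):", result.candidates.venn)
report = evaluate_recovery(result.true_selected, result.candidates.all_ids, sim.truth)
print(f"founder recovery: {report.seed_recovery:.0%}, "
      f"member assignment: {report.member_assignment:.0%}")
```

Output:

```
round 0: 4000 reads, 2790 unique, enrichment 30.2%
round 1: 4000 reads, 2784 unique, enrichment 30.4%
round 2: 4000 reads, 2631 unique, enrichment 34.2%
round 3: 4000 reads, 1844 unique, enrichment 53.9%
round 4: 4000 reads, 537 unique, enrichment 86.6%
true-selected: 328
sequence families: [('I', 4), ('II', 4)]
candidates: 25 venn (edit-only, both, tree-only): (1, 2, 22)
founder recovery: 100%, member assignment: 100%
```

Reading this: enrichment stays near the round-0 baseline while the
planted families are rare, then climbs steeply (30% → 87%) as they take
over the pool.  The true-selected filter cuts ~2,800 unique sequences per
round down to 328 recurrent, clustered ones; both planted families are
called exactly (founder + 3 variants each, labels I and II by read
count), both founders are nominated as representatives, and every planted
member lands in its founder's family.  Structure families contribute
additional tree-only candidates — structurally related sequences an
edit-distance analysis alone would miss.

## Command line

Each stage is also a subcommand of the `selexkit` console script:

```bash
selexkit simulate   --config sim.yaml --out-dir sim/
selexkit preprocess --reads sim/R0.fastq --reads sim/R1.fastq ... \
                    --barcodes barcodes.tsv --out db.csv
selexkit metrics    --db db.csv --out summary.csv
selexkit fold       --db db.csv --engine builtin --out db.folded.csv
selexkit families   --db db.folded.csv --seq-dist 1 --tree-dist 3:6 \
                    --out db.labeled.csv
selexkit rank       --db db.labeled.csv --out candidates.csv
selexkit correlate  --candidates db.labeled.csv \
                    --internalization measurements.csv --out tables.csv
selexkit run        --config pipeline.yaml   # everything, one YAML
```

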