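# cvvscan

Mining virome assemblies for virophages, their giant-virus hosts, and the
evidence that links them.

Virophages are small dsDNA viruses (13–30 kbp genomes) that can only
replicate inside the viral factory of a large nucleocytoplasmic DNA virus
(NCLDV) co-infecting the same eukaryotic cell — a cell–virus–virophage
(C–V–v) trisome. In assembled viromes neither partner announces itself:
virophages are recognised by a handful of conserved genes (major capsid
protein MCP, minor capsid protein mCP, packaging ATPase, cysteine protease),
large viruses by a core set of NCLDV orthologous genes (NCVOGs), and the
pairing between a virophage and its host virus has to be inferred
indirectly. `cvvscan` implements that whole chain of inference as a tested,
reusable pipeline, exercised end-to-end on a seeded synthetic virome with
planted ground truth so every stage is scored against what was actually put
into the sequence.

## What the pipeline computes

1. **Virophage screen** — a contig is a virophage candidate iff
   length > 5 kb, it has an MCP hit, and ≥ 2 distinct conserved-gene
   families hit overall (local protein alignment, E < 10⁻⁵).
2. **Large-virus screen** — a contig is a candidate iff ≥ 3 of 5 NCVOG
   families hit, searched two ways: iterated consensus-profile search
   (E < 10⁻⁵) and direct pairwise search against redundancy-reduced
   references (E < 10⁻¹⁰, CD-HIT-style greedy clustering at ≥ 98 %
   identity, length-ratio 0.8). The two candidate sets are merged with
   inclusion–exclusion accounting.
3. **Topology** — circular genome iff the contig ends in an exact copy of
   its start (terminal direct repeat ≥ 20 bp); linear-complete iff it
   carries terminal inverted repeats strictly longer than 100 bp; else
   fragment.
4. **Defense scan** — virophage sequences are broken into k-mers
   (k ∈ {15, 20, 25, 30, 35, 40}) and matched in large-virus contigs on
   both strands with ≤ 1 mismatch (Hamming, no indels); exact direct
   repeats flanking each hit are inventoried, MIMIVIRE-style.
5. **Codon usage** — 64-codon frequency vectors over all predicted ORFs per
   genome, Euclidean distances, average-linkage clustering.
6. **Association** — virophage/large-virus pairs are linked by shared
   proteins (E < 10⁻⁵, coverage ≥ 50 %, identity ≥ 30 %) and by codon-usage
   co-clustering; pairs supported by both evidence types outrank
   single-evidence pairs.

ORFs are called on all six frames with start codons ATG/CTG/TTG and a
minimum protein length of 50 aa. Alignments are optimal local
Smith–Waterman under BLOSUM62 (gap open 11 / extend 1) with Karlin–Altschul
statistics (λ = 0.267, K = 0.041). Full model details and every tunable are
in [docs/methods.md](docs/methods.md).

The synthetic generator (`cvvscan.synthetic`) plants all of the above:
marker genes back-translated through per-genome codon preferences, terminal
repeats, spacer k-mers with controlled mismatch counts, codon-usage
coupling between designated pairs, and a shared protein — and emits a truth
table recording every feature's coordinates.

## Worked example

```bash
cvvscan run --seed 1 --outdir out/
```

generates the default benchmark virome (200 background contigs, 10 planted
virophages of which 8 are complete, 5 large viruses above 100 kb) and runs
every stage. The printed summary:

```json
{
  "virophage_candidates": 10,
  "complete_genomes": {"circular": 7, "linear": 1, "total": 8},
  "large_virus_candidates": 5,
  "spacer_hits": 9351,
  "pairs": 1
}
```

All 10 planted virophages and all 5 large viruses are recovered with no
background false positives. The 8 complete genomes split into 7 circular
and 1 linear, matching the planted topology mix. The spacer scan reports
the planted 20-mer at its true coordinates with 1 mismatch; the remaining
hits are chance 15-mer matches, which are expected at genomic scale under a
1-mismatch tolerance and carry no flanking-repeat support. The single
ranked pair (`vp_01`–`lv_01`, support 2) is exactly the planted couple: it
shares a protein *and* co-clusters by codon usage — the dual-evidence
signature used to nominate C–V–v partnerships. Stage-by-stage tables
(screen TSVs, topology calls, spacer hits + BED, codon profiles/distances/
tree, ranked associations) and `report.json` land in `out/`.

## Package layout

| module | role |
| --- | --- |
| `cvvscan.synthetic` | seeded virome generator + ground truth |
| `cvvscan.orfs` | six-frame ORF finder, GFF3/FASTA export |
| `cvvscan.align` | local protein alignment, E-values, hit filter |
| `cvvscan.screen` | virophage / NCVOG screens, redundancy reduction, union accounting |
| `cvvscan.topology` | circular / linear / fragment classification |
| `cvvscan.defense` | multi-k spacer scan + flanking-repeat inventory |
| `cvvscan.codon` | codon-usage profiles, distances, clustering |
| `cvvscan.assoc` | shared-protein + codon evidence, ranked pairs |
| `cvvscan.pipeline` / `cvvscan.cli` | orchestration, report, `cvvscan` CLI |

Reference protein sets under `src/cvvscan/data/` are synthetic families
(see `scripts/make_references.py`), sufficient to exercise every screening
rule; they are not biological sequences.
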