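# Methods

This note records the models, rules, and numerical choices behind
`cvvscan`, and what the synthetic benchmark does and does not demonstrate.

## ORF calling

All six frames are scanned. Within each frame, stop codons partition the
sequence into segments; in each segment the single longest ORF — from the
first valid start codon (ATG, CTG or TTG, always translated as M in start
position) to the segment's stop — is reported, if its protein is at least
50 aa. Segments that reach the contig edge without a stop are reported with
`partial_end` set, because assembly fragments routinely truncate genes.
Codons containing N translate to X, and X counts toward the length
threshold. Coordinates are 1-based inclusive on the forward strand and span
start codon through stop codon. Nested starts inside a segment are not
reported separately (longest-per-stop convention shared by common ORF
callers); coding-potential models, RBS scoring and GC-frame statistics are
deliberately out of scope.

## Alignment model and statistics

All protein homology decisions use one engine: optimal affine-gap local
alignment (BLOSUM62, gap open 11, gap extend 1 — a gap of length *g* costs
11 + *g*). Raw scores are converted to bit scores with fixed gapped
Karlin–Altschul constants for this scheme, λ = 0.267 and K = 0.041, and
E-values are `search_space × 2^(−bits)` with the effective search space
taken as (total database residues) × (query length), without length
correction. These constants make thresholds comparable across stages; no
claim of numerical equivalence with any particular BLAST build is made, and
all screening thresholds are validated against the synthetic benchmark
rather than against external search tools. X scores 0 against every
residue (neutral handling of ambiguous translations). A raw score ≤ 0 is
"no alignment". Identity is identical columns over aligned columns (gaps
included); query coverage is the aligned query span over query length. Hit
filters are strict on the E-value and inclusive on coverage and identity,
so identity exactly 30 % passes a ≥ 30 % filter while an E-value exactly at
the cutoff fails.

The screens gate the quadratic alignment behind an exact shared 5-mer
prefilter (≥ 2 distinct shared words between ORF and reference family, with
≥ 1 word against the specific reference; the association search uses the
same ≥ 2-word gate via an inverted index). At the divergence these screens
target — conserved genes at ≥ 50–70 % identity over hundreds of residues —
true homologs share dozens of exact 5-mers, and any alignment that can
clear E < 10⁻⁵ contains a long high-scoring run; the gate exists to skip
hopeless background pairs, and the all-pairs oracle tests confirm it drops
nothing that would pass the filters.

## Candidate rules

**Virophage**: length > 5000 bp (strict), an MCP hit, and ≥ 2 distinct
conserved-gene families (MCP, mCP, ATPase, cysteine protease) at
E < 10⁻⁵. MCP is mandatory by design: capsid-seeded screens never surface
MCP-less contigs, so treating MCP as optional would claim a sensitivity the
search strategy does not have. Families are counted once per contig — three
ATPase ORFs are one family — and the best alignment per family is kept,
ties broken by bit score then reference ID.

**Large virus**: ≥ 3 distinct NCVOG families among NCVOG0038 (DNA
polymerase B), NCVOG0023 (D5-like primase-helicase), NCVOG0249 (ATPase),
NCVOG0076 (SFII helicase), NCVOG0262 (VLTF3-like), on contigs > 5 kb.
Profile mode searches a per-family majority-rule consensus (ties broken
alphabetically), then rebuilds the consensus after adding first-round hits
and searches once more — two rounds, a fixed and documented choice standing
in for open-ended iterative profile searching. Pairwise mode searches
redundancy-reduced references directly at E < 10⁻¹⁰. Redundancy reduction
is greedy incremental clustering: sort by length descending, join the first
representative with global identity ≥ 0.98 and length ratio ≥ 0.8, where
global identity is 1 − Levenshtein/max(length). Candidate sets from the
two modes are merged with inclusion–exclusion bookkeeping.

## Topology

Circularity: the longest proper border of the sequence (longest exact
prefix that is also a suffix, computed with the KMP failure function) must
be ≥ 20 bp. The 20 bp floor is a documented default — chance terminal
overlap at 20 bp has probability ≈ 4⁻²⁰ per comparison, negligible at
assembly scale. Linearity: the longest exact terminal inverted repeat must
be strictly greater than 100 bp; exactly 100 bp is a fragment. Repeats are
exact matches only, and circularity is checked before linearity (a contig
satisfying both is called circular). Sequences shorter than twice the
overlap floor are fragments with a reason, not errors.

## Defense (spacer) scan

Virophage k-mers at k ∈ {15, 20, 25, 30, 35, 40} are matched against
large-virus contigs (both strands) at Hamming distance ≤ 1; indels are out
of contract for words this short. Matching is exact: each k-window's two
halves are base-4 packed into integers, candidate loci come from sorted-
array lookups (a word with ≤ 1 mismatch must match one half exactly), and
candidates are verified by vectorised comparison — the tests prove
equivalence with an all-positions Hamming scan at every k. Overlapping hits
on the same diagonal are collapsed to the strictly largest k, so a planted
40-mer is one hit, not a ladder of sub-word shadows; equal-k neighbours are
genuine distinct matches and are kept. A raw, uncollapsed mode is
available. At k = 15 with one mismatch allowed, chance matches are expected
at genomic scale (≈ 46/4¹⁵ per window pair) and do appear in benchmark
runs; they are not false positives of the matcher but a property of the
parameter set, and flanking-repeat support is what separates candidate
defense loci from that background. Flank repeats are maximal exact
substrings (≥ 18 bp, ≥ 2 copies, within ±500 bp of the hit; all three are
documented tunables, since no external convention fixes them) — maximal
meaning no single-character extension preserves every occurrence.

## Codon usage and clustering

A genome's profile is the fraction of each of the 64 codons over all
retained codons of all its predicted ORFs — raw per-codon frequencies, not
RSCU, so the vector also carries amino-acid composition, matching how
codon-usage tables are usually reported. Trailing stop codons and codons
containing N are excluded. Profiles are compared by Euclidean distance and
clustered agglomeratively with average linkage (genomes sorted by ID first,
making ties deterministic). The flat cut defaults to half the median
pairwise distance: unrelated genomes, whose mutual distances concentrate
near the median, stay apart, while a planted coupling at bias 0.8 sits far
below the cut. Metric, linkage and cut height are configurable; cluster
membership, not dendrogram shape, is the supported output.

## Association and ranking

Shared-protein links require one protein pair passing E < 10⁻⁵,
coverage ≥ 50 %, identity ≥ 30 %; the best-scoring pair is the link's
detail. Codon links are shared flat-cluster membership. Pairs are ranked by
(evidence count desc, best shared-protein bit score desc, codon distance
asc, lexicographic IDs) — a composite chosen so that dual-evidence pairs
always outrank single-evidence pairs and the rest of the key merely breaks
ties deterministically.

## Synthetic benchmark: what it emulates

Generated genomes are gene-dense: coding blocks (in-frame TAA guard, start
codon, back-translated body, stop) alternate with 40–120 bp random
intergenic gaps, which makes whole-genome codon usage meaningful and every
planted ORF exactly recoverable by the ORF caller. Each genome draws a
codon preference (per-amino-acid Dirichlet, α = 0.5 — strong, distinctive
biases); marker genes are references point-mutated to 70 % protein
identity, then back-translated through that preference, coupling marker
planting to codon planting. Codon coupling resamples each synonymous codon
of the virophage toward its partner's profile with probability equal to the
bias strength (0.8 by default), leaving proteins untouched. Spacers are
copied from the virophage into an intergenic gap of the large virus with an
exact, controlled mismatch count. Complete circular genomes end in a
40–100 bp copy of their start; linear ones carry 120–200 bp terminal
inverted repeats. Background contigs are i.i.d. nucleotides at a per-contig
GC drawn from 0.35–0.50 — the simplest null that cannot carry markers
except by alignment-level chance, which the E-value threshold controls.

Default composition: 200 background contigs (5–20 kb), 10 virophages
(13–30 kb; 8 complete: 7 circular + 1 linear; complete genomes carry all
four conserved genes, fragments three), 5 large viruses (100–130 kb, five
NCVOGs each), one spacer plant (k = 20, 1 mismatch), one codon couple at
bias 0.8 that also shares one planted protein. Sites rotate round-robin
through seven ocean-region labels.

What passing does **not** show: real viromes have host contamination,
assembly chimeras and repeat-collapse artifacts, phylogenetically
structured divergence rather than i.i.d. point substitutions, and much
weaker, composition-confounded codon signals. Recovery here demonstrates
that the implementations honour their contracts exactly at the stated
thresholds — not that those thresholds are optimal on ocean data.

## Determinism and problem sizes

Every stochastic step flows from one integer seed through a single
`numpy` generator; identical configs give byte-identical FASTA, TSV and
JSON outputs, and pipeline re-runs are idempotent. Test oracles run at desk
scale chosen to finish comfortably on one CPU (e.g. the Hamming-scan oracle
uses a 2 kb × 8 kb pair with planted words at every k; the alignment oracle
uses ≤ 25-aa peptides), while the benchmark pipeline itself runs at the
full default composition above. The packaged reference families are
synthetic (random founder proteins with 12 %-diverged variants and a few
99 % near-duplicates so redundancy reduction has work to do); screens only
ever compare query ORFs *against* them, so their randomness is immaterial —
what matters, and what the tests pin down, is the rule logic at the stated
thresholds.

## Known limitations

- Profile mode is consensus-sequence search, not a position-specific model;
  it structurally mirrors iterative profile searching but will diverge from
  true HMM scores on gappy families.
- E-values use fixed Karlin–Altschul constants and uncorrected search
  spaces; absolute values are approximate, thresholds are calibrated.
- The spacer scan's Hamming-only contract ignores indelled spacers.
- Codon clustering assumes comparable ORF inventories; genomes with very
  few ORFs produce noisy profiles (profiles with zero retained codons are
  excluded outright).
- PLV (polinton-like virus) removal is a no-op hook: candidates that a
  dedicated classifier would strip as PLVs are retained here.
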