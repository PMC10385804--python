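"""Candidate screens for virophages and large viruses.

Virophage rule: a contig is a virophage candidate iff it is longer than 5 kb,
has a major capsid protein (MCP) hit, and hits at least two distinct
conserved-gene families overall (MCP, mCP, ATPase, cysteine protease).  The
MCP requirement reflects how such screens are seeded: contigs without an MCP
match are never pulled out of the assembly in the first place.

Large-virus rule: a contig is a candidate iff its ORFs hit at least three of
the five NCLDV core-gene families (NCVOGs).  Two search modes are provided:
``profile`` scores ORFs against a per-family consensus sequence and runs a
second round after augmenting each family with its first-round hits
(a lightweight stand-in for iterative profile searches, E < 1e-5);
``pairwise`` searches ORFs against redundancy-reduced reference sequences
directly at a stricter E < 1e-10.

A shared-word prefilter (exact 5-mer peptide match) gates the full
dynamic-programming alignment; at the divergence levels this screen targets
(>= ~50% identity over hundreds of residues) true homologs always share many
exact words, so the prefilter only trims the quadratic background work.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import edlib

from .align import Alignment, ScoringScheme, local_align
from .records import Contig, OrfRecord
from .references import (
    MANDATORY_VIROPHAGE_FAMILY,
    NCVOG_FAMILIES,
    VIROPHAGE_FAMILIES,
    ncvog_refs,
    virophage_marker_refs,
)

PREFILTER_WORD = 5  # exact shared peptide word gating full DP


@dataclass(frozen=True)
class MarkerHit:
    contig_id: str
    orf_id: str
    marker_family: str
    alignment: Alignment


@dataclass(frozen=True)
class ScreenResult:
    contig_id: str
    category: str  # virophage_candidate | large_virus_candidate | rejected
    distinct_markers: frozenset[str]
    length: int
    reason: str


def _words(protein: str, k: int = PREFILTER_WORD) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def _family_word_index(refs: dict[str, list[tuple[str, str]]], k: int = PREFILTER_WORD):
    """Per family: (union word set, per-reference word sets)."""
    out = {}
    for fam, seqs in refs.items():
        per_ref = [_words(seq, k) for _, seq in seqs]
        union = set().union(*per_ref) if per_ref else set()
        out[fam] = (union, per_ref)
    return out


def _best_hits(
    orfs: Sequence[OrfRecord],
    refs: dict[str, list[tuple[str, str]]],
    max_e: float,
    scoring: ScoringScheme,
) -> dict[tuple[str, str], MarkerHit]:
    """Best hit per (contig, family); ties broken by (bit desc, target id asc)."""
    db_len = sum(len(seq) for seqs in refs.values() for _, seq in seqs)
    word_index = _family_word_index(refs)
    best: dict[tuple[str, str], MarkerHit] = {}
    for orf in orfs:
        if len(orf.protein) < PREFILTER_WORD:
            continue
        orf_words = _words(orf.protein)
        space = db_len * len(orf.protein)
        scheme = ScoringScheme(
            matrix_name=scoring.matrix_name, gap_open=scoring.gap_open,
            gap_extend=scoring.gap_extend, lam=scoring.lam, k=scoring.k,
            search_space=space,
        )
        for family, seqs in refs.items():
            union, per_ref = word_index[family]
            inter = orf_words & union
            # true homologs at screen-level divergence share dozens of exact
            # words; <2 shared words cannot clear the E-value threshold
            if len(inter) < 2:
                continue
            for (ref_id, ref_seq), ref_words in zip(seqs, per_ref):
                if not inter & ref_words:
                    continue
                aln = local_align(orf.protein, ref_seq, scheme,
                                  query_id=orf.id, target_id=ref_id)
                if aln is None or not aln.e_value < max_e:
                    continue
                key = (orf.contig_id, family)
                cur = best.get(key)
                if cur is None or (
                    (-aln.bit_score, aln.target_id)
                    < (-cur.alignment.bit_score, cur.alignment.target_id)
                ):
                    best[key] = MarkerHit(orf.contig_id, orf.id, family, aln)
    return best


def _validate_ids(contigs: Sequence[Contig], orfs: Sequence[OrfRecord]) -> None:
    contig_ids = {c.id for c in contigs}
    missing = {o.contig_id for o in orfs} - contig_ids
    if missing:
        raise ValueError(f"ORFs reference unknown contigs: {sorted(missing)[:5]}")


def screen_virophages(
    contigs: Sequence[Contig],
    orfs: Sequence[OrfRecord],
    marker_refs: Optional[dict[str, list[tuple[str, str]]]] = None,
    max_e: float = 1e-5,
    min_length: int = 5000,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[ScreenResult]:
    """Apply the >5 kb / MCP-anchored / >=2 conserved-gene virophage rule."""
    _validate_ids(contigs, orfs)
    refs = marker_refs if marker_refs is not None else virophage_marker_refs()
    hits = _best_hits(orfs, refs, max_e, scoring)
    by_contig: dict[str, set[str]] = defaultdict(set)
    for (contig_id, family) in hits:
        by_contig[contig_id].add(family)
    results = []
    for c in contigs:
        fams = frozenset(by_contig.get(c.id, set()))
        if not fams:
            cat, reason = "rejected", "no hits"
        elif MANDATORY_VIROPHAGE_FAMILY not in fams:
            cat, reason = "rejected", "no MCP hit"
        elif len(fams) < 2:
            cat, reason = "rejected", "fewer than 2 conserved gene families"
        elif len(c) <= min_length:
            cat, reason = "rejected", f"length <= {min_length} bp"
        else:
            cat, reason = "virophage_candidate", f"{len(fams)} conserved gene families"
        results.append(ScreenResult(c.id, cat, fams, len(c), reason))
    return results


def consensus_sequence(seqs: Sequence[str]) -> str:
    """Column-wise majority consensus; sequences padded to the longest member.

    Ties break alphabetically, which keeps the consensus deterministic.
    """
    if not seqs:
        raise ValueError("cannot build a consensus from no sequences")
    width = max(len(s) for s in seqs)
    cols = []
    for i in range(width):
        counts: dict[str, int] = defaultdict(int)
        for s in seqs:
            if i < len(s):
                counts[s[i]] += 1
        cols.append(min(counts, key=lambda a: (-counts[a], a)))
    return "".join(cols)


def screen_large_viruses(
    contigs: Sequence[Contig],
    orfs: Sequence[OrfRecord],
    refs: Optional[dict[str, list[tuple[str, str]]]] = None,
    mode: str = "profile",
    max_e: Optional[float] = None,
    min_families: int = 3,
    min_length: int = 5000,
    scoring: ScoringScheme = ScoringScheme(),
) -> list[ScreenResult]:
    """Apply the >=3-distinct-NCVOG large-virus rule in one of two modes."""
    if mode not in ("profile", "pairwise"):
        raise ValueError(f"unknown mode {mode!r}")
    _validate_ids(contigs, orfs)
    refs = refs if refs is not None else ncvog_refs()
    if max_e is None:
        max_e = 1e-5 if mode == "profile" else 1e-10

    if mode == "profile":
        consensus = {fam: [(f"{fam}_consensus", consensus_sequence([s for _, s in seqs]))]
                     for fam, seqs in refs.items() if seqs}
        round1 = _best_hits(orfs, consensus, max_e, scoring)
        proteins_by_id = {o.id: o.protein for o in orfs}
        augmented = {
            fam: seqs + [
                (hit.orf_id, proteins_by_id[hit.orf_id])
                for (cid, f), hit in sorted(round1.items())
                if f == fam
            ]
            for fam, seqs in refs.items()
        }
        consensus2 = {fam: [(f"{fam}_consensus", consensus_sequence([s for _, s in seqs]))]
                      for fam, seqs in augmented.items() if seqs}
        hits = _best_hits(orfs, consensus2, max_e, scoring)
    else:
        pooled = [(rid, seq) for fam, seqs in refs.items() for rid, seq in seqs]
        reps = reduce_redundancy(pooled)
        rep_refs: dict[str, list[tuple[str, str]]] = {fam: [] for fam in refs}
        for rid, seq in reps:
            rep_refs[rid.rsplit("_", 1)[0]].append((rid, seq))
        hits = _best_hits(orfs, rep_refs, max_e, scoring)

    by_contig: dict[str, set[str]] = defaultdict(set)
    for (contig_id, family) in hits:
        by_contig[contig_id].add(family)
    results = []
    for c in contigs:
        fams = frozenset(by_contig.get(c.id, set()))
        if len(c) <= min_length:
            cat, reason = "rejected", f"length <= {min_length} bp"
        elif len(fams) >= min_families:
            cat, reason = "large_virus_candidate", f"{len(fams)} NCVOG families ({mode})"
        else:
            cat, reason = "rejected", f"only {len(fams)} NCVOG families"
        results.append(ScreenResult(c.id, cat, fams, len(c), reason))
    return results


def global_identity(a: str, b: str) -> float:
    """Global identity defined as 1 - levenshtein(a, b) / max(len(a), len(b))."""
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def reduce_redundancy(
    proteins: Sequence[tuple[str, str]],
    min_identity: float = 0.98,
    length_ratio: float = 0.8,
) -> list[tuple[str, str]]:
    """Greedy incremental clustering in the CD-HIT style.

    Sequences are sorted by length descending (ID ascending on ties); each
    joins the first representative with global identity >= ``min_identity``
    and shorter/longer length ratio >= ``length_ratio``, otherwise it founds
    a new cluster.  Representatives are returned in founding order.
    """
    if not proteins:
        raise ValueError("empty protein set")
    ordered = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    reps: list[tuple[str, str]] = []
    for pid, seq in ordered:
        placed = False
        for rid, rseq in reps:
            ratio = min(len(seq), len(rseq)) / max(len(seq), len(rseq))
            if ratio >= length_ratio and global_identity(seq, rseq) >= min_identity:
                placed = True
                break
        if not placed:
            reps.append((pid, seq))
    return reps


def merge_candidate_sets(set_a: Iterable[str], set_b: Iterable[str]) -> dict[str, int]:
    """Union accounting for two candidate sets with inclusion-exclusion bookkeeping."""
    a, b = set(set_a), set(set_b)
    return {
        "a": len(a),
        "b": len(b),
        "intersection": len(a & b),
        "union": len(a | b),
    }


def write_screen_tsv(results: Sequence[ScreenResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tcategory\tmarkers\tlength\treason\n")
        for r in results:
            fh.write("\t".join([
                r.contig_id, r.category, ",".join(sorted(r.distinct_markers)),
                str(r.length), r.reason,
            ]) + "\n")
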