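"""Virophage / large-virus association from two evidence streams.

Shared-protein evidence: a virophage and a large virus are linked when at
least one protein pair aligns with E < 1e-5, query coverage >= 50% and
identity >= 30% (the best-scoring pair is kept as detail).  Codon evidence:
the two genomes fall into the same flat codon-usage cluster.  Pairs backed
by both evidence types outrank single-evidence pairs; within a support
level, ranking is by best shared-protein bit score (descending), codon
distance (ascending), then lexicographic IDs — fully deterministic.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Optional, Sequence

from .align import Alignment, ScoringScheme, local_align, passes_filter
from .codon import ClusterResult

_WORD = 5  # exact shared peptide word gating full alignment


@dataclass(frozen=True)
class AssociationLink:
    virophage_id: str
    large_virus_id: str
    evidence: str  # shared_protein | codon_cluster
    alignment: Optional[Alignment] = None   # for shared_protein
    cluster_id: Optional[int] = None        # for codon_cluster
    codon_distance: Optional[float] = None


@dataclass(frozen=True)
class CvvCandidate:
    virophage_id: str
    large_virus_id: str
    support_count: int
    rank: int
    best_bit_score: float
    codon_distance: Optional[float]


def _words(p: str) -> set[str]:
    return {p[i:i + _WORD] for i in range(len(p) - _WORD + 1)}


def shared_proteins(
    vp_proteins: Sequence[tuple[str, str, str]],  # (genome_id, protein_id, seq)
    lv_proteins: Sequence[tuple[str, str, str]],
    max_e: float = 1e-5,
    min_cov: float = 0.5,
    min_id: float = 0.3,
    scoring: ScoringScheme = ScoringScheme(),
    min_shared_words: int = 2,
) -> list[AssociationLink]:
    """One link per (virophage, large virus) pair with a passing protein pair.

    Full alignment is gated by ``min_shared_words`` distinct exact 5-mer
    matches between the protein pair; any alignment able to clear the E-value
    threshold carries a long high-scoring segment and therefore many exact
    words, so the gate only removes hopeless background pairs.
    """
    if not vp_proteins or not lv_proteins:
        return []
    db_len = sum(len(s) for _, _, s in lv_proteins)
    word_index: dict[str, list[int]] = defaultdict(list)
    for idx, (_, _, s) in enumerate(lv_proteins):
        for w in _words(s):
            word_index[w].append(idx)
    best: dict[tuple[str, str], Alignment] = {}
    for vp_genome, vp_pid, vp_seq in vp_proteins:
        if len(vp_seq) < _WORD:
            continue
        shared: dict[int, int] = defaultdict(int)
        for w in _words(vp_seq):
            for idx in word_index.get(w, ()):
                shared[idx] += 1
        scheme = ScoringScheme(
            matrix_name=scoring.matrix_name, gap_open=scoring.gap_open,
            gap_extend=scoring.gap_extend, lam=scoring.lam, k=scoring.k,
            search_space=db_len * len(vp_seq),
        )
        for idx in sorted(i for i, n in shared.items() if n >= min_shared_words):
            lv_genome, lv_pid, lv_seq = lv_proteins[idx]
            aln = local_align(vp_seq, lv_seq, scheme,
                              query_id=vp_pid, target_id=lv_pid)
            if aln is None or not passes_filter(aln, max_e, min_cov, min_id):
                continue
            key = (vp_genome, lv_genome)
            cur = best.get(key)
            if cur is None or (
                (-aln.bit_score, aln.query_id, aln.target_id)
                < (-cur.bit_score, cur.query_id, cur.target_id)
            ):
                best[key] = aln
    return [
        AssociationLink(vp, lv, "shared_protein", alignment=aln)
        for (vp, lv), aln in sorted(best.items())
    ]


def codon_links(
    clusters: ClusterResult,
    virophage_ids: Sequence[str],
    large_virus_ids: Sequence[str],
    distances: Optional[dict[tuple[str, str], float]] = None,
) -> list[AssociationLink]:
    """Links for every virophage/large-virus pair sharing a flat codon cluster."""
    vp_set, lv_set = set(virophage_ids), set(large_virus_ids)
    links = []
    for vp in sorted(vp_set & clusters.flat.keys()):
        for lv in sorted(lv_set & clusters.flat.keys()):
            if clusters.flat[vp] == clusters.flat[lv]:
                dist = distances.get((vp, lv)) if distances else None
                links.append(AssociationLink(
                    vp, lv, "codon_cluster",
                    cluster_id=clusters.flat[vp], codon_distance=dist))
    return links


def pair_candidates(links: Sequence[AssociationLink]) -> list[CvvCandidate]:
    """Rank pairs: dual-evidence first, then bit score, codon distance, IDs."""
    by_pair: dict[tuple[str, str], dict] = defaultdict(
        lambda: {"evidence": set(), "bit": float("-inf"), "dist": None})
    for link in links:
        slot = by_pair[(link.virophage_id, link.large_virus_id)]
        slot["evidence"].add(link.evidence)
        if link.alignment is not None:
            slot["bit"] = max(slot["bit"], link.alignment.bit_score)
        if link.codon_distance is not None:
            slot["dist"] = (link.codon_distance if slot["dist"] is None
                            else min(slot["dist"], link.codon_distance))
    def sort_key(item):
        (vp, lv), slot = item
        dist = slot["dist"] if slot["dist"] is not None else float("inf")
        return (-len(slot["evidence"]), -slot["bit"], dist, vp, lv)
    ranked = sorted(by_pair.items(), key=sort_key)
    return [
        CvvCandidate(vp, lv, support_count=len(slot["evidence"]), rank=i,
                     best_bit_score=slot["bit"], codon_distance=slot["dist"])
        for i, ((vp, lv), slot) in enumerate(ranked, start=1)
    ]


def write_candidates_tsv(candidates: Sequence[CvvCandidate], path) -> None:
    with open(path, "w") as fh:
        fh.write("virophage\tlarge_virus\tsupport_count\tbest_bit_score\tcodon_distance\trank\n")
        for c in candidates:
            dist = f"{c.codon_distance:.6f}" if c.codon_distance is not None else ""
            bit = f"{c.best_bit_score:.1f}" if c.best_bit_score > float("-inf") else ""
            fh.write(f"{c.virophage_id}\t{c.large_virus_id}\t{c.support_count}\t"
                     f"{bit}\t{dist}\t{c.rank}\n")
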