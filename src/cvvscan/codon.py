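"""Per-genome codon usage profiles and hierarchical clustering.

A genome's codon usage profile is the fraction of each of the 64 codons over
all retained codons of all its predicted ORFs (stop codons and codons
containing N are excluded).  Profiles are compared by Euclidean distance and
clustered agglomeratively with average linkage; a virophage and a large virus
falling into the same flat cluster is used downstream as association
evidence, mirroring how shared codon preference hints at a shared
translational environment.
"""
from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

#: the 64 codons in lexicographic order (AAA .. TTT)
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product("ACGT", repeat=3)
)
_CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

_STOPS = frozenset(("TAA", "TAG", "TGA"))


@dataclass(frozen=True)
class CodonProfile:
    genome_id: str
    freq: np.ndarray  # 64 fractions, lexicographic codon order
    total_codons: int

    @property
    def usable(self) -> bool:
        return self.total_codons > 0

    def __post_init__(self) -> None:
        if self.freq.shape != (64,):
            raise ValueError("codon frequency vector must have 64 entries")
        if self.total_codons > 0 and abs(float(self.freq.sum()) - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")


def profile(genome_id: str, cds_sequences: Sequence[str]) -> CodonProfile:
    """Codon usage over a genome's coding sequences.

    Each CDS is read in frame; a trailing stop codon and any codon containing
    N are excluded from the tally.  A genome with zero retained codons yields
    an all-zero profile flagged unusable.
    """
    counts = np.zeros(64, dtype=np.int64)
    for cds in cds_sequences:
        cds = cds.upper()
        n = len(cds) // 3 * 3
        for i in range(0, n, 3):
            codon = cds[i:i + 3]
            if codon in _STOPS and i == n - 3:
                continue
            idx = _CODON_INDEX.get(codon)
            if idx is not None:  # codons containing N are skipped
                counts[idx] += 1
    total = int(counts.sum())
    freq = counts / total if total else counts.astype(float)
    return CodonProfile(genome_id, freq, total)


def distance_matrix(profiles: Sequence[CodonProfile]) -> tuple[list[str], np.ndarray]:
    """Euclidean distance between usable profiles (symmetric, zero diagonal)."""
    usable = [p for p in profiles if p.usable]
    dropped = [p.genome_id for p in profiles if not p.usable]
    if dropped:
        warnings.warn(f"excluding unusable codon profiles: {dropped}")
    if len(usable) < 2:
        raise ValueError("need at least 2 usable profiles")
    ids = [p.genome_id for p in usable]
    mat = np.stack([p.freq for p in usable])
    diff = mat[:, None, :] - mat[None, :, :]
    dm = np.sqrt((diff ** 2).sum(axis=2))
    np.fill_diagonal(dm, 0.0)
    return ids, dm


@dataclass
class ClusterResult:
    ids: list[str]
    linkage: np.ndarray          # scipy linkage matrix
    height: float                # flat-cluster cut height used
    flat: dict[str, int]         # genome_id -> flat cluster label


def cluster(
    ids: Sequence[str],
    matrix: np.ndarray,
    method: str = "average",
    height: Optional[float] = None,
) -> ClusterResult:
    """Agglomerative clustering of a distance matrix with a flat cut.

    Genomes are ordered by ID before linkage so ties resolve deterministically.
    When ``height`` is None the cut defaults to half the median pairwise
    distance: planted couplings sit well below it while unrelated genomes,
    whose distances concentrate around the median, stay apart.
    """
    if len(ids) < 2:
        return ClusterResult(list(ids), np.empty((0, 4)), 0.0,
                             {i: 1 for i in ids})
    order = np.argsort(np.asarray(ids, dtype=object))
    ids_sorted = [ids[i] for i in order]
    mat = matrix[np.ix_(order, order)]
    condensed = squareform(mat, checks=False)
    Z = hierarchy.linkage(condensed, method=method)
    h = height if height is not None else float(np.median(condensed)) / 2.0
    labels = hierarchy.fcluster(Z, t=h, criterion="distance")
    return ClusterResult(ids_sorted, Z, h,
                         {g: int(l) for g, l in zip(ids_sorted, labels)})


def to_newick(result: ClusterResult) -> str:
    """Export the dendrogram as a Newick string with merge-height branch lengths."""
    if result.linkage.size == 0:
        return "(" + ",".join(result.ids) + ");"
    tree = hierarchy.to_tree(result.linkage)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{result.ids[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def write_profiles_tsv(profiles: Sequence[CodonProfile], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(CODONS) + "\ttotal_codons\n")
        for p in profiles:
            fh.write(p.genome_id + "\t"
                     + "\t".join(f"{x:.6f}" for x in p.freq)
                     + f"\t{p.total_codons}\n")


def write_matrix_tsv(ids: Sequence[str], matrix: np.ndarray, path) -> None:
    with open(path, "w") as fh:
        fh.write("genome\t" + "\t".join(ids) + "\n")
        for i, gid in enumerate(ids):
            fh.write(gid + "\t" + "\t".join(f"{x:.6f}" for x in matrix[i]) + "\n")
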