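"""Spacer scan for giant-virus CRISPR-like defense loci.

Some giant viruses carry short fragments of their parasite's genome flanked
by repeats — a MIMIVIRE-like defense system.  This module hunts for such
candidate loci: every virophage sequence is broken into k-mers at
k in {15, 20, 25, 30, 35, 40} and matched against large-virus contigs on
both strands allowing at most one mismatch (Hamming distance; no indels).
Overlapping hits on a shared diagonal are collapsed to the largest k, so a
long planted word is reported once rather than shadowed by its own sub-words.
Exact direct repeats flanking a hit are then inventoried as supporting
evidence.

Matching is exact-arithmetic: k-mer halves are base-4 packed into integers,
candidate positions come from sorted-array lookups of either half (a word
with <= 1 mismatch must have one exact half), and candidates are verified by
vectorised Hamming comparison.  This is equivalent to an all-positions scan.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .orfs import reverse_complement
from .records import Contig

ALLOWED_KS = (15, 20, 25, 30, 35, 40)

_NT_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _NT_CODE[_b] = _i


@dataclass(frozen=True)
class FlankRepeat:
    unit_length: int
    copy_count: int
    positions: tuple[int, ...]  # 1-based starts on the large-virus contig
    unit: str


@dataclass
class SpacerHit:
    virophage_id: str
    large_virus_id: str
    k: int
    virophage_pos: int    # 1-based
    large_virus_pos: int  # 1-based, forward strand of the large virus
    strand: str           # '+' or '-'
    mismatches: int
    flank_repeats: list[FlankRepeat] = field(default_factory=list)


def _encode(seq: str) -> np.ndarray:
    return _NT_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def kmerize(seq: str, k: int) -> list[tuple[int, str]]:
    """All k-length windows as (1-based position, k-mer); windows with N skipped."""
    if k < 1:
        raise ValueError("k must be >= 1")
    seq = seq.upper()
    return [
        (i + 1, seq[i:i + k])
        for i in range(len(seq) - k + 1)
        if "N" not in seq[i:i + k]
    ]


def _window_hashes(code: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(positions, packed hashes) for all N-free k-windows of an encoded sequence."""
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    acc = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = code[j:j + n]
        valid &= c != 255
        acc = acc * 4 + c
    pos = np.nonzero(valid)[0]
    return pos, acc[pos]


def _half_lookup(code: np.ndarray, k: int, offset: int, h: int):
    """Sorted hashes of the h-length sub-window at ``offset`` of each k-window."""
    n = len(code) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    sub_pos, sub_hash = _window_hashes(code, h)
    # keep sub-windows that start a valid k-window half: position - offset in [0, n)
    keep = (sub_pos >= offset) & (sub_pos - offset < n)
    win_pos = sub_pos[keep] - offset
    hashes = sub_hash[keep]
    order = np.argsort(hashes, kind="stable")
    return hashes[order], win_pos[order]


def _vp_half_queries(vp_code: np.ndarray, k: int):
    """Per half: (window positions, half hashes) for all k-windows of the query."""
    h1 = k // 2
    out = []
    for offset, h in ((0, h1), (h1, k - h1)):
        vp_sub_pos, vp_sub_hash = _window_hashes(vp_code, h)
        keep = (vp_sub_pos >= offset) & (vp_sub_pos - offset <= len(vp_code) - k)
        out.append((offset, vp_sub_pos[keep] - offset, vp_sub_hash[keep]))
    return out


def _match_one_strand(vp_code: np.ndarray, lv_code: np.ndarray, k: int,
                      max_mismatch: int,
                      vp_queries=None, lv_lookups=None) -> list[tuple[int, int, int]]:
    """(vp_pos0, lv_pos0, mismatches) for all k-windows within Hamming distance.

    ``vp_queries`` / ``lv_lookups`` allow callers scanning many pairs to reuse
    the per-sequence hash tables; results are identical either way.
    """
    h1 = k // 2
    vp_pos, _ = _window_hashes(vp_code, k)
    if len(vp_pos) == 0:
        return []
    if vp_queries is None:
        vp_queries = _vp_half_queries(vp_code, k)
    if lv_lookups is None:
        lv_lookups = {offset: _half_lookup(lv_code, k, offset, h)
                      for offset, h in ((0, h1), (h1, k - h1))}
    pairs = []
    for offset, vwin, vhash in vp_queries:
        lv_hashes, lv_pos = lv_lookups[offset]
        if len(lv_hashes) == 0 or len(vwin) == 0:
            continue
        lo = np.searchsorted(lv_hashes, vhash, side="left")
        hi = np.searchsorted(lv_hashes, vhash, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            continue
        vp_rep = np.repeat(vwin, counts)
        # flattened [arange(lo_i, hi_i) for all i] without a Python loop
        csum = np.cumsum(counts)
        idx = np.arange(total) - np.repeat(csum - counts, counts) + np.repeat(lo, counts)
        lv_rep = lv_pos[idx]
        # pack each (vp, lv) pair into one int64 so dedup is a scalar sort
        pairs.append(vp_rep.astype(np.int64) * (len(lv_code) + 1) + lv_rep)
    if not pairs:
        return []
    keys = np.unique(np.concatenate(pairs))
    cand_vp = keys // (len(lv_code) + 1)
    cand_lv = keys % (len(lv_code) + 1)
    # restrict to valid (N-free) vp k-windows
    vp_valid = np.zeros(len(vp_code), dtype=bool)
    vp_valid[vp_pos] = True
    good = vp_valid[cand_vp]
    cand_vp, cand_lv = cand_vp[good], cand_lv[good]
    if len(cand_vp) == 0:
        return []
    offs = np.arange(k)
    vp_mat = vp_code[cand_vp[:, None] + offs[None, :]]
    lv_mat = lv_code[cand_lv[:, None] + offs[None, :]]
    mism = (vp_mat != lv_mat).sum(axis=1)
    ok = mism <= max_mismatch
    return [(int(v), int(l), int(m))
            for v, l, m in zip(cand_vp[ok], cand_lv[ok], mism[ok])]


def _subsume(hits: list[SpacerHit]) -> list[SpacerHit]:
    """Collapse overlapping same-diagonal hits to the largest k."""
    groups: dict[tuple[str, str, str, int], list[SpacerHit]] = defaultdict(list)
    for hit in hits:
        if hit.strand == "+":
            diag = hit.large_virus_pos - hit.virophage_pos
        else:
            diag = hit.large_virus_pos + hit.k + hit.virophage_pos
        groups[(hit.virophage_id, hit.large_virus_id, hit.strand, diag)].append(hit)
    kept: list[SpacerHit] = []
    for group in groups.values():
        group.sort(key=lambda h: (-h.k, h.large_virus_pos))
        chosen: list[SpacerHit] = []
        for h in group:
            s, e = h.large_virus_pos, h.large_virus_pos + h.k - 1
            # only a strictly larger k absorbs a hit; equal-k neighbors are
            # distinct matches, not shadows
            if any(c.k > h.k
                   and not (e < c.large_virus_pos or s > c.large_virus_pos + c.k - 1)
                   for c in chosen):
                continue
            chosen.append(h)
        kept.extend(chosen)
    kept.sort(key=lambda h: (h.virophage_id, h.large_virus_id, h.strand,
                             h.large_virus_pos, -h.k))
    return kept


def scan(
    virophages: Sequence[Contig],
    large_viruses: Sequence[Contig],
    ks: Sequence[int] = ALLOWED_KS,
    max_mismatch: int = 1,
    subsume: bool = True,
) -> list[SpacerHit]:
    """Match virophage k-mers in large-virus contigs on both strands.

    Every occurrence with Hamming distance <= ``max_mismatch`` is reported
    once per (k, position pair, strand); with ``subsume`` (default) smaller-k
    shadows of a larger hit on the same diagonal are collapsed.
    """
    bad = sorted(set(ks) - set(ALLOWED_KS))
    if bad:
        raise ValueError(f"k values {bad} outside allowed set {ALLOWED_KS}")
    hits: list[SpacerHit] = []
    lv_codes = {}
    lv_lookups = {}
    for lv in large_viruses:
        fwd = _encode(lv.seq.upper())
        rev = _encode(reverse_complement(lv.seq.upper()))
        lv_codes[lv.id] = (fwd, rev, len(lv))
        for k in sorted(set(ks)):
            h1 = k // 2
            for strand, code in (("+", fwd), ("-", rev)):
                lv_lookups[(lv.id, strand, k)] = {
                    offset: _half_lookup(code, k, offset, h)
                    for offset, h in ((0, h1), (h1, k - h1))
                }
    for vp in virophages:
        vp_code = _encode(vp.seq.upper())
        vp_queries = {k: _vp_half_queries(vp_code, k) for k in sorted(set(ks))}
        for lv in large_viruses:
            fwd, rev, n_lv = lv_codes[lv.id]
            for k in sorted(ks):
                for strand, code in (("+", fwd), ("-", rev)):
                    for vpos0, lpos0, mism in _match_one_strand(
                            vp_code, code, k, max_mismatch,
                            vp_queries=vp_queries[k],
                            lv_lookups=lv_lookups[(lv.id, strand, k)]):
                        if strand == "+":
                            lv_pos = lpos0 + 1
                        else:
                            # map revcomp window start back to forward coordinates
                            lv_pos = n_lv - (lpos0 + k) + 1
                        hits.append(SpacerHit(
                            virophage_id=vp.id, large_virus_id=lv.id, k=k,
                            virophage_pos=vpos0 + 1, large_virus_pos=lv_pos,
                            strand=strand, mismatches=mism,
                        ))
    return _subsume(hits) if subsume else hits


def find_flank_repeats(
    large_virus: Contig,
    hit: SpacerHit,
    window: int = 500,
    min_unit: int = 18,
    min_copies: int = 2,
) -> list[FlankRepeat]:
    """Maximal exact repeats within +-``window`` bp of a spacer hit.

    A repeat record is a substring of length >= ``min_unit`` occurring
    >= ``min_copies`` times in the window whose every one-character extension
    occurs fewer times (i.e. a maximal repeat).  Windows truncated by contig
    edges are clipped.  Results are attached to ``hit.flank_repeats``.
    """
    seq = large_virus.seq.upper()
    n = len(seq)
    if not (1 <= hit.large_virus_pos <= n - hit.k + 1):
        raise ValueError("hit coordinates outside the contig")
    w_start = max(0, hit.large_virus_pos - 1 - window)
    w_end = min(n, hit.large_virus_pos - 1 + hit.k + window)
    win = seq[w_start:w_end]

    # enumerate substring counts length by length; repeated substrings only
    # get rarer as they grow, so the loop stops as soon as a length yields no
    # candidate (instantly on repeat-free windows)
    found: dict[str, tuple[int, ...]] = {}
    length = min_unit
    while length <= len(win):
        occs_by_word: dict[str, list[int]] = defaultdict(list)
        for i in range(len(win) - length + 1):
            occs_by_word[win[i:i + length]].append(i)
        candidates = {w: o for w, o in occs_by_word.items()
                      if len(o) >= min_copies and "N" not in w}
        if not candidates:
            break
        for word, occs in candidates.items():
            # maximal iff no one-character extension keeps every occurrence
            left = {win[o - 1] if o > 0 else None for o in occs}
            right = {win[o + length] if o + length < len(win) else None for o in occs}
            if (len(left) > 1 or None in left) and (len(right) > 1 or None in right):
                found[word] = tuple(occs)
        length += 1
    repeats = [
        FlankRepeat(unit_length=len(unit), copy_count=len(occs),
                    positions=tuple(w_start + o + 1 for o in occs), unit=unit)
        for unit, occs in sorted(found.items(), key=lambda kv: (kv[1][0], kv[0]))
    ]
    hit.flank_repeats = repeats
    return repeats


def write_hits_tsv(hits: Sequence[SpacerHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("virophage\tlarge_virus\tk\tvp_pos\tlv_pos\tstrand\tmismatches\tflank_repeats\n")
        for h in hits:
            fr = ";".join(f"{r.unit_length}x{r.copy_count}@{','.join(map(str, r.positions))}"
                          for r in h.flank_repeats)
            fh.write(f"{h.virophage_id}\t{h.large_virus_id}\t{h.k}\t"
                     f"{h.virophage_pos}\t{h.large_virus_pos}\t{h.strand}\t"
                     f"{h.mismatches}\t{fr}\n")


def write_hits_bed(hits: Sequence[SpacerHit], path) -> None:
    """BED (0-based half-open) intervals of hit loci and their flank repeats."""
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.large_virus_id}\t{h.large_virus_pos - 1}\t"
                     f"{h.large_virus_pos - 1 + h.k}\t"
                     f"spacer_{h.virophage_id}_k{h.k}\t{h.mismatches}\t{h.strand}\n")
            for r in h.flank_repeats:
                for p in r.positions:
                    fh.write(f"{h.large_virus_id}\t{p - 1}\t{p - 1 + r.unit_length}\t"
                             f"flank_repeat_u{r.unit_length}\t{r.copy_count}\t+\n")
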