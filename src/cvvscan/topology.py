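"""Genome completeness and topology classification.

An assembled viral contig that runs past its own origin carries an identical
sequence at both ends (a terminal direct repeat / overlap): evidence of a
circular genome.  A linear complete genome instead carries terminal inverted
repeats (TIRs).  This module classifies a contig as circular (terminal exact
overlap of at least ``min_overlap`` bp), linear (TIR strictly longer than
100 bp), or fragment.  Circularity is checked first; repeats are exact
matches only.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .orfs import reverse_complement
from .records import Contig


@dataclass(frozen=True)
class TopologyCall:
    contig_id: str
    verdict: str  # circular | linear | fragment
    repeat_length: int
    repeat_kind: str  # direct | inverted | none
    repeat_coordinates: Optional[tuple[tuple[int, int], tuple[int, int]]]  # 1-based
    reason: str = ""


def longest_terminal_direct_repeat(seq: str) -> int:
    """Longest L < n with seq[:L] == seq[-L:] (the longest proper border).

    Computed with the KMP failure function in O(n).
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k > 0 and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    return fail[-1]


def longest_terminal_inverted_repeat(seq: str) -> int:
    """Longest L <= n//2 with seq[:L] reverse-complementing seq[-L:]."""
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    m = n // 2
    if m == 0:
        return 0
    a = np.frombuffer(seq[:m].encode(), dtype=np.uint8)
    b = np.frombuffer(reverse_complement(seq)[:m].encode(), dtype=np.uint8)
    neq = a != b
    idx = int(np.argmax(neq))
    return m if not neq.any() else idx


def classify(contig: Contig, min_overlap: int = 20, min_tir: int = 100,
             max_tir_offset: int = 0) -> TopologyCall:
    """Classify a contig as circular, linear-complete, or fragment.

    ``min_tir`` is strict: a TIR of exactly ``min_tir`` bp does not qualify.
    ``max_tir_offset`` allows the TIR to start within that many bp of either
    end (0 = exactly terminal).  Sequences shorter than ``2 * min_overlap``
    are returned as fragments with a reason, not raised.
    """
    seq = contig.seq.upper()
    n = len(seq)
    if n < 2 * min_overlap:
        return TopologyCall(contig.id, "fragment", 0, "none", None,
                            reason=f"sequence shorter than {2 * min_overlap} bp")
    dr = longest_terminal_direct_repeat(seq)
    if dr >= min_overlap:
        return TopologyCall(
            contig.id, "circular", dr, "direct",
            ((1, dr), (n - dr + 1, n)),
            reason="terminal overlap",
        )
    best_tir, best_off = 0, 0
    for off in range(max_tir_offset + 1):
        trimmed = seq[off:n - off] if off else seq
        if len(trimmed) < 2:
            break
        tir = longest_terminal_inverted_repeat(trimmed)
        if tir > best_tir:
            best_tir, best_off = tir, off
    if best_tir > min_tir:
        s = best_off
        return TopologyCall(
            contig.id, "linear", best_tir, "inverted",
            ((s + 1, s + best_tir), (n - s - best_tir + 1, n - s)),
            reason="terminal inverted repeat",
        )
    return TopologyCall(contig.id, "fragment", 0, "none", None,
                        reason="no terminal repeat evidence")
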