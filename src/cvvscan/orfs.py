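"""Six-frame ORF prediction with alternative start codons.

Calls open reading frames on both strands of a contig with the parameter set
used throughout this package: start codons ATG/CTG/TTG, a minimum protein
length of 50 aa, and the standard genetic code.  Within each stop-delimited
segment of each frame the longest ORF (earliest valid start to the stop) is
reported; ORFs that run off the contig edge are kept and flagged as partial.
"""
from __future__ import annotations

from typing import Iterable

from Bio.Data.CodonTable import unambiguous_dna_by_id

from .records import Contig, OrfRecord

_STANDARD = unambiguous_dna_by_id[1]

START_CODONS = ("ATG", "CTG", "TTG")
STOP_CODONS = tuple(sorted(_STANDARD.stop_codons))  # TAA, TAG, TGA

#: codon -> amino acid for all 64 codons, '*' for stops
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> tuple of synonymous codons (stops excluded)
SYNONYMOUS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_STANDARD.forward_table.items()):
    SYNONYMOUS.setdefault(_aa, ())
    SYNONYMOUS[_aa] = SYNONYMOUS[_aa] + (_codon,)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_NT = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aa_for(codon: str) -> str:
    """Translate one codon; any codon containing N becomes X."""
    if "N" in codon:
        return "X"
    return CODON_TO_AA[codon]


def translate(nt: str, alt_start: bool = True) -> str:
    """Translate an in-frame nucleotide sequence with the standard code.

    A trailing stop codon is trimmed; internal stops are kept as ``*``.  With
    ``alt_start`` (the default, CDS semantics) a leading ATG/CTG/TTG codon is
    rendered as M.  Codons containing N translate to X.

    Raises ``ValueError`` if the length is not divisible by 3.
    """
    if len(nt) % 3 != 0:
        raise ValueError(f"sequence length {len(nt)} not divisible by 3")
    nt = nt.upper()
    aas = [_aa_for(nt[i:i + 3]) for i in range(0, len(nt), 3)]
    if aas and aas[-1] == "*":
        aas.pop()
    if alt_start and aas and nt[:3] in START_CODONS:
        aas[0] = "M"
    return "".join(aas)


def _frame_orfs(s: str, frame: int, min_aa: int):
    """Yield (start_codon_idx, n_codons, has_stop, protein) per segment.

    ``start_codon_idx`` counts codons from the beginning of the frame;
    positions are later mapped to forward-strand coordinates by the caller.
    """
    sub = s[frame:]
    n_codons = len(sub) // 3
    if n_codons == 0:
        return
    aa = "".join(_aa_for(sub[3 * i:3 * i + 3]) for i in range(n_codons))
    seg_start = 0
    while seg_start <= n_codons:
        stop_idx = aa.find("*", seg_start)
        seg_end = stop_idx if stop_idx != -1 else n_codons  # codons [seg_start, seg_end)
        has_stop = stop_idx != -1
        # earliest valid start leaving >= min_aa codons before the stop/edge
        for i in range(seg_start, seg_end - min_aa + 1):
            codon = sub[3 * i:3 * i + 3]
            if codon in START_CODONS:
                protein = "M" + aa[i + 1:seg_end]
                yield i, seg_end - i, has_stop, protein, codon
                break
        if not has_stop:
            return
        seg_start = stop_idx + 1


def find_orfs(contig: Contig, min_aa: int = 50) -> list[OrfRecord]:
    """Predict ORFs on all six frames of ``contig``.

    Raises ``ValueError`` on characters outside A/C/G/T/N or ``min_aa`` < 1.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = contig.seq.upper()
    if not set(seq) <= _VALID_NT:
        bad = sorted(set(seq) - _VALID_NT)
        raise ValueError(f"contig {contig.id}: invalid characters {bad}")
    n = len(seq)
    raw: list[tuple[int, int, str, int, str, bool, str]] = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            for i, length, has_stop, protein, start_codon in _frame_orfs(s, frame, min_aa):
                # nt span on strand s, 1-based inclusive, including the stop codon
                s_start = frame + 3 * i + 1
                s_end = frame + 3 * (i + length) + (3 if has_stop else 0)
                if strand == "+":
                    f_start, f_end = s_start, s_end
                else:
                    f_start, f_end = n - s_end + 1, n - s_start + 1
                raw.append((f_start, f_end, strand, frame, start_codon,
                            not has_stop, protein))
    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    return [
        OrfRecord(
            id=f"{contig.id}_{i}", contig_id=contig.id, start=st, end=en,
            strand=strand, frame=frame, start_codon=sc, partial_end=pe,
            protein=prot,
        )
        for i, (st, en, strand, frame, sc, pe, prot) in enumerate(raw, start=1)
    ]


def orf_nt(contig: Contig, orf: OrfRecord) -> str:
    """Extract the coding nucleotide sequence of an ORF (stop included if present)."""
    sub = contig.seq[orf.start - 1:orf.end]
    return sub if orf.strand == "+" else reverse_complement(sub)


def write_gff3(orfs: Iterable[OrfRecord], path) -> None:
    """One CDS feature per ORF, GFF3 with 1-based inclusive coordinates."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for o in orfs:
            attrs = f"ID={o.id};start_codon={o.start_codon};partial_end={str(o.partial_end).lower()}"
            fh.write("\t".join([
                o.contig_id, "cvvscan", "CDS", str(o.start), str(o.end),
                ".", o.strand, "0", attrs,
            ]) + "\n")


def write_protein_fasta(orfs: Iterable[OrfRecord], path) -> None:
    with open(path, "w") as fh:
        for o in orfs:
            fh.write(f">{o.id}\n")
            for i in range(0, len(o.protein), 70):
                fh.write(o.protein[i:i + 70] + "\n")
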