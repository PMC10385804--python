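"""Core record types shared across the pipeline.

A :class:`Contig` is the universal input unit (one nucleotide sequence from a
virome assembly, optionally tagged with its sampling site).  A
:class:`TruthRecord` carries the planted ground truth emitted by the synthetic
generator so that every downstream stage can be scored against what was
actually placed in the sequence.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Contig:
    """A named nucleotide sequence (uppercase A/C/G/T/N) with an optional site label."""

    id: str
    seq: str
    site: Optional[str] = None

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class OrfRecord:
    """A predicted coding region on a contig.

    Coordinates are 1-based inclusive on the forward strand of the input and
    span the start codon through the stop codon (when a stop exists).  The
    protein excludes the stop.  ``frame`` is the reading-frame offset (0-2) on
    the ORF's own strand; ``partial_end`` marks ORFs that run off the contig
    edge without reaching a stop.
    """

    id: str
    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    frame: int
    start_codon: str
    partial_end: bool
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start + 1) % 3 != 0:
            raise ValueError(f"ORF {self.id}: span not divisible by 3")
        if self.strand not in "+-":
            raise ValueError(f"ORF {self.id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class PlantedMarker:
    family: str
    start: int  # 1-based inclusive, spans start codon..stop codon
    end: int
    strand: str


@dataclass(frozen=True)
class PlantedSpacer:
    partner_id: str
    k: int
    mismatches: int
    position_in_virophage: int  # 1-based
    position_in_large_virus: int  # 1-based


@dataclass
class TruthRecord:
    """Ground-truth labels for one generated contig."""

    contig_id: str
    category: str  # background | virophage | large_virus
    planted_markers: list[PlantedMarker] = field(default_factory=list)
    topology: str = "fragment"  # circular | linear | fragment
    planted_spacers: list[PlantedSpacer] = field(default_factory=list)
    codon_partner: Optional[str] = None
    site: Optional[str] = None

    def to_tsv_row(self) -> list[str]:
        markers = json.dumps(
            [[m.family, m.start, m.end, m.strand] for m in self.planted_markers]
        )
        spacers = json.dumps(
            [
                [s.partner_id, s.k, s.mismatches,
                 s.position_in_virophage, s.position_in_large_virus]
                for s in self.planted_spacers
            ]
        )
        return [
            self.contig_id, self.category, markers, self.topology,
            spacers, self.codon_partner or "", self.site or "",
        ]

    @classmethod
    def from_tsv_row(cls, row: list[str]) -> "TruthRecord":
        markers = [PlantedMarker(f, int(s), int(e), st)
                   for f, s, e, st in json.loads(row[2])]
        spacers = [PlantedSpacer(p, int(k), int(m), int(pv), int(pl))
                   for p, k, m, pv, pl in json.loads(row[4])]
        return cls(
            contig_id=row[0], category=row[1], planted_markers=markers,
            topology=row[3], planted_spacers=spacers,
            codon_partner=row[5] or None, site=row[6] or None,
        )


TRUTH_TSV_HEADER = [
    "contig_id", "category", "planted_markers", "topology",
    "planted_spacers", "codon_partner", "site",
]
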