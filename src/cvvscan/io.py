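"""Readers and writers for the package's on-disk formats.

Contigs travel as multi-FASTA (sampling site carried as a ``site=`` token in
the description), ground truth as a TSV with a header row, and configs as
flat JSON.
"""
from __future__ import annotations

import csv
import json
from typing import Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import TRUTH_TSV_HEADER, Contig, TruthRecord


def write_fasta(contigs: Sequence[Contig], path) -> None:
    records = []
    for c in contigs:
        desc = f"site={c.site}" if c.site else ""
        records.append(SeqRecord(Seq(c.seq), id=c.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[Contig]:
    contigs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        site = None
        for token in rec.description.split():
            if token.startswith("site="):
                site = token[5:] or None
        contigs.append(Contig(id=rec.id, seq=str(rec.seq).upper(), site=site))
    return contigs


def write_truth_tsv(truths: Sequence[TruthRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TRUTH_TSV_HEADER)
        for t in truths:
            writer.writerow(t.to_tsv_row())


def read_truth_tsv(path) -> list[TruthRecord]:
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header != TRUTH_TSV_HEADER:
            raise ValueError(f"unexpected truth table header: {header}")
        return [TruthRecord.from_tsv_row(row) for row in reader]


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
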