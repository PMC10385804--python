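"""Packaged marker reference protein sets.

Two synthetic FASTA files ship with the package (see
``scripts/make_references.py`` in the repository): one with the four
conserved virophage gene families (MCP, mCP, ATPase, CysProt) and one with
the five NCLDV core-gene families (NCVOG0038 DNA polymerase B, NCVOG0023
D5-like helicase-primase, NCVOG0249 ATPase, NCVOG0076 SFII helicase,
NCVOG0262 VLTF3-like).  Record IDs are ``<family>_<nn>``.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources

from Bio import SeqIO

VIROPHAGE_FAMILIES = ("MCP", "mCP", "ATPase", "CysProt")
NCVOG_FAMILIES = ("NCVOG0038", "NCVOG0023", "NCVOG0249", "NCVOG0076", "NCVOG0262")

MANDATORY_VIROPHAGE_FAMILY = "MCP"


def _load(filename: str, families: tuple[str, ...]) -> dict[str, list[tuple[str, str]]]:
    out: dict[str, list[tuple[str, str]]] = {f: [] for f in families}
    ref = resources.files("cvvscan.data").joinpath(filename)
    with ref.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            family = rec.id.rsplit("_", 1)[0]
            if family not in out:
                raise ValueError(f"unknown family {family!r} in {filename}")
            out[family].append((rec.id, str(rec.seq)))
    return out


@lru_cache(maxsize=1)
def virophage_marker_refs() -> dict[str, list[tuple[str, str]]]:
    """family -> list of (record id, protein) for the virophage conserved genes."""
    return _load("virophage_markers_synthetic.faa", VIROPHAGE_FAMILIES)


@lru_cache(maxsize=1)
def ncvog_refs() -> dict[str, list[tuple[str, str]]]:
    """family -> list of (record id, protein) for the five NCLDV core genes."""
    return _load("ncvog_markers_synthetic.faa", NCVOG_FAMILIES)


def load_reference_fasta(path, families: tuple[str, ...]) -> dict[str, list[tuple[str, str]]]:
    """Load a user-supplied reference FASTA with ``<family>_<nn>`` record IDs."""
    out: dict[str, list[tuple[str, str]]] = {f: [] for f in families}
    for rec in SeqIO.parse(str(path), "fasta"):
        family = rec.id.rsplit("_", 1)[0]
        if family not in out:
            raise ValueError(f"unknown family {family!r} in {path}")
        out[family].append((rec.id, str(rec.seq)))
    return out
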