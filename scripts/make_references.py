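#!/usr/bin/env python
"""Regenerate the packaged SYNTHETIC marker reference protein sets.

The screens need reference protein families for the four conserved virophage
genes (MCP, mCP, ATPase, CysProt) and the five NCLDV core genes (NCVOG0038,
NCVOG0023, NCVOG0249, NCVOG0076, NCVOG0262).  This artifact ships synthetic
stand-in families: each family is a random founder protein plus point-mutated
variants, which is enough to exercise homology screening, consensus building,
and redundancy reduction.  They are NOT biological sequences.

Run from the repository root:

    python scripts/make_references.py

Writes src/cvvscan/data/virophage_markers_synthetic.faa and
src/cvvscan/data/ncvog_markers_synthetic.faa deterministically (fixed seed).
"""
from __future__ import annotations

import pathlib
import textwrap

import numpy as np

SEED = 7
N_VARIANTS = 6
VARIANT_DIVERGENCE = 0.12   # per-site substitution probability vs founder
NEAR_DUP_DIVERGENCE = 0.01  # extra near-duplicates (exercise redundancy reduction)

AA = "ACDEFGHIKLMNPQRSTVWY"
# rough database-wide amino acid background frequencies
AA_FREQ = np.array(
    [7.4, 3.3, 5.9, 5.8, 4.0, 7.4, 2.9, 3.8, 7.2, 7.6,
     1.8, 4.4, 5.0, 3.7, 4.2, 8.1, 6.2, 6.8, 1.3, 3.3]
)
AA_FREQ = AA_FREQ / AA_FREQ.sum()

VIROPHAGE_FAMILIES = {"MCP": 430, "mCP": 260, "ATPase": 230, "CysProt": 200}
NCVOG_FAMILIES = {
    "NCVOG0038": 540,  # DNA polymerase family B
    "NCVOG0023": 420,  # D5-like helicase-primase
    "NCVOG0249": 270,  # ATPase
    "NCVOG0076": 440,  # superfamily II helicase
    "NCVOG0262": 240,  # VLTF3-like late transcription factor
}


def random_protein(rng: np.random.Generator, length: int) -> str:
    body = rng.choice(list(AA), size=length - 1, p=AA_FREQ)
    return "M" + "".join(body)


def mutate(rng: np.random.Generator, prot: str, rate: float) -> str:
    """Point-substitute positions (never the leading M) at the given rate."""
    out = list(prot)
    for i in range(1, len(out)):
        if rng.random() < rate:
            choices = [a for a in AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def family_fasta(rng, family: str, length: int, near_dups: int) -> list[str]:
    founder = random_protein(rng, length)
    records = []
    variants = [mutate(rng, founder, VARIANT_DIVERGENCE) for _ in range(N_VARIANTS)]
    for i, v in enumerate(variants, start=1):
        records.append((f"{family}_{i:02d}", v))
    for j in range(near_dups):
        dup = mutate(rng, variants[0], NEAR_DUP_DIVERGENCE)
        records.append((f"{family}_{N_VARIANTS + 1 + j:02d}", dup))
    lines = []
    for rid, seq in records:
        lines.append(f">{rid} synthetic reference, family={family}")
        lines.extend(textwrap.wrap(seq, 70))
    return lines


def main() -> None:
    data_dir = pathlib.Path(__file__).resolve().parents[1] / "src" / "cvvscan" / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)

    vp_lines = []
    for fam, length in VIROPHAGE_FAMILIES.items():
        vp_lines.extend(family_fasta(rng, fam, length, near_dups=0))
    (data_dir / "virophage_markers_synthetic.faa").write_text("\n".join(vp_lines) + "\n")

    nc_lines = []
    for fam, length in NCVOG_FAMILIES.items():
        nc_lines.extend(family_fasta(rng, fam, length, near_dups=2))
    (data_dir / "ncvog_markers_synthetic.faa").write_text("\n".join(nc_lines) + "\n")


if __name__ == "__main__":
    main()
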