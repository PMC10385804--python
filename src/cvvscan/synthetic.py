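"""Seeded synthetic virome generator with planted ground truth.

Emulates a mixed marine virome assembly: background contigs (i.i.d.
nucleotides at a configurable GC), virophage genomes carrying mutated copies
of the packaged conserved-gene references (complete ones with a terminal
direct repeat for circularity or >100 bp terminal inverted repeats for
linearity), large-virus contigs carrying NCLDV core genes, spacer k-mers
shared between designated virophage/large-virus pairs, and codon-usage
coupling between designated pairs.  Every planted feature is recorded in a
machine-readable truth table so downstream stages can be scored exactly.

Genomes are gene-dense: coding blocks (an in-frame stop guard, a start
codon, back-translated codons drawn from the genome's own codon preference,
and a stop) alternate with short random intergenic gaps.  Back-translating
through the per-genome codon preference is what couples marker planting with
codon-bias planting: two genomes given correlated preferences end up with
correlated codon usage across their whole gene complement.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from typing import Optional, Sequence

import numpy as np

from . import codon as codon_mod
from .defense import ALLOWED_KS
from .orfs import START_CODONS, SYNONYMOUS, reverse_complement
from .records import Contig, PlantedMarker, PlantedSpacer, TruthRecord
from .references import NCVOG_FAMILIES, VIROPHAGE_FAMILIES, ncvog_refs, virophage_marker_refs

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_STOPS = ("TAA", "TAG", "TGA")

DEFAULT_SITES = (
    "arctic_ocean", "north_atlantic", "south_atlantic", "indian_ocean",
    "mediterranean", "red_sea", "south_pacific",
)


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic virome.

    Defaults mirror the benchmark composition used throughout the package:
    200 background contigs, 10 virophages of which 8 are complete genomes
    (7 circular, 1 linear, matching the complete-genome topology mix the
    screens are expected to reproduce), 5 large-virus contigs above 100 kb,
    one planted spacer pair, and one codon-coupled pair that also shares a
    planted protein.
    """

    seed: int = 0
    n_background: int = 200
    background_length_range: tuple[int, int] = (5000, 20000)
    n_virophage: int = 10
    n_virophage_complete: int = 8
    n_circular: int = 7
    n_linear: int = 1
    virophage_length_range: tuple[int, int] = (13000, 30000)
    n_large_virus: int = 5
    large_virus_length_range: tuple[int, int] = (100000, 130000)
    markers_per_virophage: int = 3          # complete genomes always carry all 4
    ncvogs_per_large_virus: int = 5
    marker_identity: float = 0.70           # protein identity of planted marker copies
    spacer_plants: list[tuple[str, str, int, int]] = dc_field(
        default_factory=lambda: [("vp_01", "lv_01", 20, 1)])
    codon_couples: list[tuple[str, str, float]] = dc_field(
        default_factory=lambda: [("vp_01", "lv_01", 0.8)])
    shared_protein_plants: list[tuple[str, str]] = dc_field(
        default_factory=lambda: [("vp_01", "lv_01")])
    gc_range: tuple[float, float] = (0.35, 0.50)
    site_labels: tuple[str, ...] = DEFAULT_SITES

    def validate(self) -> None:
        if self.n_circular + self.n_linear != self.n_virophage_complete:
            raise ValueError("n_circular + n_linear must equal n_virophage_complete")
        if self.n_virophage_complete > self.n_virophage:
            raise ValueError("n_virophage_complete cannot exceed n_virophage")
        if self.n_virophage and not (2 <= self.markers_per_virophage <= 4):
            raise ValueError("markers_per_virophage must be in 2..4")
        if self.n_large_virus and not (3 <= self.ncvogs_per_large_virus <= 5):
            raise ValueError("ncvogs_per_large_virus must be in 3..5")
        for vp, lv, k, mm in self.spacer_plants:
            if k not in ALLOWED_KS:
                raise ValueError(f"spacer k={k} not in {ALLOWED_KS}")
            if mm not in (0, 1):
                raise ValueError("spacer mismatches must be 0 or 1")
        for vp, lv, b in self.codon_couples:
            if not 0.0 <= b <= 1.0:
                raise ValueError("bias_strength must be in [0, 1]")
        if not 0.0 < self.marker_identity <= 1.0:
            raise ValueError("marker_identity must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_background": self.n_background,
            "background_length_range": list(self.background_length_range),
            "n_virophage": self.n_virophage,
            "n_virophage_complete": self.n_virophage_complete,
            "n_circular": self.n_circular,
            "n_linear": self.n_linear,
            "virophage_length_range": list(self.virophage_length_range),
            "n_large_virus": self.n_large_virus,
            "large_virus_length_range": list(self.large_virus_length_range),
            "markers_per_virophage": self.markers_per_virophage,
            "ncvogs_per_large_virus": self.ncvogs_per_large_virus,
            "marker_identity": self.marker_identity,
            "spacer_plants": [list(p) for p in self.spacer_plants],
            "codon_couples": [list(p) for p in self.codon_couples],
            "shared_protein_plants": [list(p) for p in self.shared_protein_plants],
            "gc_range": list(self.gc_range),
            "site_labels": list(self.site_labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        cfg = cls()
        for key, value in d.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            if key.endswith("_range"):
                value = tuple(value)
            elif key == "site_labels":
                value = tuple(value)
            elif key == "spacer_plants":
                value = [(a, b, int(k), int(m)) for a, b, k, m in value]
            elif key == "codon_couples":
                value = [(a, b, float(s)) for a, b, s in value]
            elif key == "shared_protein_plants":
                value = [(a, b) for a, b in value]
            setattr(cfg, key, value)
        return cfg


# ---------------------------------------------------------------------------
# sequence construction primitives


def _random_nt(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "M" + "".join(rng.choice(list(_AA20), size=length - 1))


def _mutate_protein(rng: np.random.Generator, prot: str, identity: float) -> str:
    """Point-substitute residues (never the leading one) to the target identity."""
    out = list(prot)
    for i in range(1, len(out)):
        if rng.random() > identity:
            choices = [a for a in _AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _codon_preference(rng: np.random.Generator, alpha: float = 0.5) -> dict[str, np.ndarray]:
    """Per-amino-acid codon preference drawn from a Dirichlet(alpha)."""
    return {aa: rng.dirichlet([alpha] * len(codons))
            for aa, codons in SYNONYMOUS.items()}


def _back_translate(rng: np.random.Generator, protein: str,
                    pref: dict[str, np.ndarray]) -> str:
    """CDS for ``protein``: alt-start, preference-drawn codons, and a stop."""
    start = START_CODONS[rng.integers(len(START_CODONS))]
    codons = [start]
    for aa in protein[1:]:
        syn = SYNONYMOUS[aa]
        codons.append(syn[rng.choice(len(syn), p=pref[aa])])
    codons.append(_STOPS[rng.integers(len(_STOPS))])
    return "".join(codons)


class _GenomeDraft:
    """A genome being assembled: sequence parts plus feature bookkeeping."""

    def __init__(self, genome_id: str):
        self.id = genome_id
        self.parts: list[str] = []
        self.pos = 0  # 0-based length so far
        self.markers: list[PlantedMarker] = []
        self.orf_spans: list[tuple[int, int]] = []  # 1-based inclusive CDS spans
        self.gaps: list[tuple[int, int]] = []       # 1-based inclusive gap spans

    def add(self, part: str) -> None:
        self.parts.append(part)
        self.pos += len(part)

    def add_gap(self, rng: np.random.Generator, lo: int = 40, hi: int = 120,
                gc: float = 0.45) -> None:
        length = int(rng.integers(lo, hi + 1))
        self.gaps.append((self.pos + 1, self.pos + length))
        self.add(_random_nt(rng, length, gc))

    def add_gene(self, rng: np.random.Generator, protein: str,
                 pref: dict[str, np.ndarray], family: Optional[str] = None) -> None:
        """In-frame stop guard + CDS; records the CDS span (start..stop codon)."""
        cds = _back_translate(rng, protein, pref)
        self.add("TAA")  # guard: terminates any upstream in-frame ORF
        start = self.pos + 1
        self.add(cds)
        end = self.pos
        self.orf_spans.append((start, end))
        if family is not None:
            self.markers.append(PlantedMarker(family, start, end, "+"))

    @property
    def seq(self) -> str:
        return "".join(self.parts)


def _assemble_genome(
    rng: np.random.Generator,
    genome_id: str,
    target_length: int,
    marker_genes: Sequence[tuple[str, str]],  # (family, protein)
    extra_genes: Sequence[str],
    pref: dict[str, np.ndarray],
    gc: float,
) -> _GenomeDraft:
    """Alternate gaps and genes until the length budget is spent, then pad."""
    draft = _GenomeDraft(genome_id)
    queue = [(fam, prot) for fam, prot in marker_genes] + \
            [(None, prot) for prot in extra_genes]
    for family, protein in queue:
        draft.add_gap(rng, gc=gc)
        draft.add_gene(rng, protein, pref, family)
    while True:
        remaining = target_length - draft.pos
        # gap (>=40) + guard (3) + start/stop (6) + 3 nt per extra residue
        max_aa = (remaining - 120 - 9) // 3
        if max_aa < 120:
            break
        length = int(rng.integers(120, min(max_aa, 300) + 1))
        draft.add_gap(rng, gc=gc)
        draft.add_gene(rng, _random_protein(rng, length), pref)
    pad = target_length - draft.pos
    if pad > 0:
        draft.gaps.append((draft.pos + 1, draft.pos + pad))
        draft.add(_random_nt(rng, pad, gc))
    return draft


# ---------------------------------------------------------------------------
# public operations


def plant_spacer(
    virophage: Contig,
    large_virus: Contig,
    k: int,
    mismatches: int,
    rng: Optional[np.random.Generator] = None,
    virophage_pos: Optional[int] = None,
    large_virus_pos: Optional[int] = None,
) -> tuple[Contig, Contig, PlantedSpacer]:
    """Copy a k-mer from the virophage into the large virus.

    The virophage window at ``virophage_pos`` (1-based; random when omitted)
    is written into the large virus at ``large_virus_pos`` with exactly
    ``mismatches`` substitutions, so the Hamming distance between the two
    copies equals ``mismatches``.
    """
    if k not in ALLOWED_KS:
        raise ValueError(f"k={k} not in allowed set {ALLOWED_KS}")
    if mismatches not in (0, 1):
        raise ValueError("mismatches must be 0 or 1")
    rng = rng if rng is not None else np.random.default_rng(0)
    if virophage_pos is None:
        virophage_pos = int(rng.integers(1, len(virophage) - k + 2))
    if large_virus_pos is None:
        large_virus_pos = int(rng.integers(1, len(large_virus) - k + 2))
    word = virophage.seq[virophage_pos - 1:virophage_pos - 1 + k]
    copy = list(word)
    if mismatches:
        sites = rng.choice(k, size=mismatches, replace=False)
        for s in sites:
            choices = [b for b in "ACGT" if b != copy[s]]
            copy[s] = choices[rng.integers(len(choices))]
    lv_seq = (large_virus.seq[:large_virus_pos - 1] + "".join(copy)
              + large_virus.seq[large_virus_pos - 1 + k:])
    truth = PlantedSpacer(
        partner_id=large_virus.id, k=k, mismatches=mismatches,
        position_in_virophage=virophage_pos, position_in_large_virus=large_virus_pos,
    )
    return virophage, replace(large_virus, seq=lv_seq), truth


def apply_codon_bias(
    contig: Contig,
    orf_spans: Sequence[tuple[int, int]],
    target_profile: "codon_mod.CodonProfile",
    bias_strength: float,
    rng: Optional[np.random.Generator] = None,
) -> Contig:
    """Resample synonymous codons inside planted ORFs toward a target profile.

    Each non-start, non-stop codon is replaced, with probability
    ``bias_strength``, by a codon drawn from the target profile restricted to
    the same amino acid; the encoded protein is untouched.  ``bias_strength``
    0 is an exact no-op; 1 converges to the target up to amino-acid
    composition constraints.
    """
    if not 0.0 <= bias_strength <= 1.0:
        raise ValueError("bias_strength must be in [0, 1]")
    if bias_strength == 0.0:
        return contig
    rng = rng if rng is not None else np.random.default_rng(0)
    # target distribution over synonymous codons per amino acid
    syn_dist: dict[str, tuple[tuple[str, ...], np.ndarray]] = {}
    for aa, codons in SYNONYMOUS.items():
        weights = np.array([target_profile.freq[codon_mod.CODONS.index(c)] for c in codons])
        total = weights.sum()
        syn_dist[aa] = (codons, weights / total if total > 0 else
                        np.full(len(codons), 1.0 / len(codons)))
    return _apply_bias_impl(contig, orf_spans, syn_dist, bias_strength, rng)


def _apply_bias_impl(contig, orf_spans, syn_dist, bias_strength, rng) -> Contig:
    from .orfs import CODON_TO_AA

    seq = list(contig.seq)
    for start, end in orf_spans:
        cds = contig.seq[start - 1:end]
        n_codons = len(cds) // 3
        for ci in range(1, n_codons - 1):  # keep start codon and stop codon
            cd = cds[3 * ci:3 * ci + 3]
            aa = CODON_TO_AA.get(cd)
            if aa is None or aa == "*":
                continue
            if rng.random() < bias_strength:
                codons, weights = syn_dist[aa]
                new = codons[rng.choice(len(codons), p=weights)]
                pos0 = start - 1 + 3 * ci
                seq[pos0:pos0 + 3] = list(new)
    return replace(contig, seq="".join(seq))


def generate(config: GeneratorConfig) -> tuple[list[Contig], list[TruthRecord]]:
    """Generate the synthetic virome described by ``config``.

    Deterministic for a fixed config (including the seed).  Returns contigs
    (virophages, then large viruses, then background) and one truth record
    per contig.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    vp_refs = virophage_marker_refs()
    nc_refs = ncvog_refs()

    shared_by_pair: dict[tuple[str, str], str] = {}
    for vp_id, lv_id in config.shared_protein_plants:
        length = int(rng.integers(200, 301))
        shared_by_pair[(vp_id, lv_id)] = _random_protein(rng, length)

    # ----- large viruses -------------------------------------------------
    lv_drafts: dict[str, _GenomeDraft] = {}
    lv_prefs: dict[str, dict[str, np.ndarray]] = {}
    for i in range(config.n_large_virus):
        lv_id = f"lv_{i + 1:02d}"
        gc = float(rng.uniform(*config.gc_range))
        pref = _codon_preference(rng)
        lv_prefs[lv_id] = pref
        length = int(rng.integers(*config.large_virus_length_range, endpoint=True))
        fam_idx = rng.choice(len(NCVOG_FAMILIES), size=config.ncvogs_per_large_virus,
                             replace=False)
        marker_genes = []
        for fi in sorted(fam_idx):
            fam = NCVOG_FAMILIES[fi]
            ref_id, ref_seq = nc_refs[fam][rng.integers(len(nc_refs[fam]))]
            marker_genes.append((fam, _mutate_protein(rng, ref_seq, config.marker_identity)))
        extras = [prot for (v, l), prot in shared_by_pair.items() if l == lv_id]
        lv_drafts[lv_id] = _assemble_genome(rng, lv_id, length, marker_genes, extras, pref, gc)

    lv_profiles = {
        lv_id: codon_mod.profile(
            lv_id, [d.seq[s - 1:e] for s, e in d.orf_spans])
        for lv_id, d in lv_drafts.items()
    }
    couples = {vp_id: (lv_id, bias) for vp_id, lv_id, bias in config.codon_couples}

    # ----- virophages -----------------------------------------------------
    vp_contigs: list[Contig] = []
    vp_truths: dict[str, TruthRecord] = {}
    other_families = [f for f in VIROPHAGE_FAMILIES if f != "MCP"]
    for i in range(config.n_virophage):
        vp_id = f"vp_{i + 1:02d}"
        gc = float(rng.uniform(*config.gc_range))
        pref = _codon_preference(rng)
        length = int(rng.integers(*config.virophage_length_range, endpoint=True))
        if i < config.n_circular:
            topo = "circular"
        elif i < config.n_circular + config.n_linear:
            topo = "linear"
        else:
            topo = "fragment"
        complete = topo != "fragment"
        if complete:
            families = list(VIROPHAGE_FAMILIES)
        else:
            extra_idx = rng.choice(len(other_families),
                                   size=config.markers_per_virophage - 1, replace=False)
            families = ["MCP"] + [other_families[j] for j in sorted(extra_idx)]
        marker_genes = []
        for fam in families:
            ref_id, ref_seq = vp_refs[fam][rng.integers(len(vp_refs[fam]))]
            marker_genes.append((fam, _mutate_protein(rng, ref_seq, config.marker_identity)))
        extras = [prot for (v, l), prot in shared_by_pair.items() if v == vp_id]

        if topo == "circular":
            overlap = int(rng.integers(40, 101))
            core_len = length - overlap
            offset = 0
        elif topo == "linear":
            tir = int(rng.integers(120, 201))
            core_len = length - 2 * tir
            offset = tir
        else:
            core_len, offset = length, 0
        draft = _assemble_genome(rng, vp_id, core_len, marker_genes, extras, pref, gc)
        seq = draft.seq

        contig = Contig(vp_id, seq)
        spans = list(draft.orf_spans)
        if vp_id in couples:
            lv_id, bias = couples[vp_id]
            if lv_id not in lv_profiles:
                raise ValueError(f"codon couple references unknown large virus {lv_id}")
            contig = apply_codon_bias(contig, spans, lv_profiles[lv_id], bias, rng)
            seq = contig.seq

        if topo == "circular":
            seq = seq + seq[:overlap]
        elif topo == "linear":
            tir_seq = _random_nt(rng, offset, gc)
            seq = tir_seq + seq + reverse_complement(tir_seq)
        markers = [PlantedMarker(m.family, m.start + offset, m.end + offset, m.strand)
                   for m in draft.markers]
        # remember gap spans (shifted) for spacer placement bookkeeping
        draft.gaps = [(s + offset, e + offset) for s, e in draft.gaps]
        draft.markers = markers
        vp_contigs.append(Contig(vp_id, seq))
        vp_truths[vp_id] = TruthRecord(
            contig_id=vp_id, category="virophage", planted_markers=markers,
            topology=topo, codon_partner=couples.get(vp_id, (None,))[0],
        )

    # ----- spacer planting ------------------------------------------------
    lv_contigs = {lv_id: Contig(lv_id, d.seq) for lv_id, d in lv_drafts.items()}
    lv_spacers: dict[str, list[PlantedSpacer]] = {lv_id: [] for lv_id in lv_contigs}
    vp_by_id = {c.id: c for c in vp_contigs}
    for vp_id, lv_id, k, mm in config.spacer_plants:
        if vp_id not in vp_by_id or lv_id not in lv_contigs:
            raise ValueError(f"spacer plant references unknown contigs {(vp_id, lv_id)}")
        vp = vp_by_id[vp_id]
        lv = lv_contigs[lv_id]
        vp_pos = int(rng.integers(1, len(vp) - k + 2))
        gaps = [(s, e) for s, e in lv_drafts[lv_id].gaps if e - s + 1 >= k]
        if not gaps:
            raise ValueError(f"no intergenic gap of length >= {k} in {lv_id}")
        gs, ge = gaps[int(rng.integers(len(gaps)))]
        lv_pos = int(rng.integers(gs, ge - k + 2))
        _, lv, truth = plant_spacer(vp, lv, k, mm, rng,
                                    virophage_pos=vp_pos, large_virus_pos=lv_pos)
        lv_contigs[lv_id] = lv
        vp_truths[vp_id].planted_spacers.append(truth)
        lv_spacers[lv_id].append(PlantedSpacer(
            partner_id=vp_id, k=k, mismatches=mm,
            position_in_virophage=vp_pos, position_in_large_virus=lv_pos))

    # ----- background -----------------------------------------------------
    bg_contigs = []
    for i in range(config.n_background):
        bg_id = f"bg_{i + 1:03d}"
        gc = float(rng.uniform(*config.gc_range))
        length = int(rng.integers(*config.background_length_range, endpoint=True))
        bg_contigs.append(Contig(bg_id, _random_nt(rng, length, gc)))

    # ----- assemble outputs, assign sites round-robin ---------------------
    lv_truths = {
        lv_id: TruthRecord(
            contig_id=lv_id, category="large_virus",
            planted_markers=lv_drafts[lv_id].markers, topology="fragment",
            planted_spacers=lv_spacers[lv_id],
            codon_partner=next((vp for vp, (lv, _b) in couples.items() if lv == lv_id), None),
        )
        for lv_id in lv_contigs
    }
    contigs = vp_contigs + [lv_contigs[k] for k in sorted(lv_contigs)] + bg_contigs
    truths = [vp_truths[c.id] if c.id in vp_truths else
              lv_truths[c.id] if c.id in lv_truths else
              TruthRecord(contig_id=c.id, category="background")
              for c in contigs]
    sites = config.site_labels
    out_contigs = []
    for idx, (c, t) in enumerate(zip(contigs, truths)):
        site = sites[idx % len(sites)] if sites else None
        t.site = site
        out_contigs.append(replace(c, site=site))
    return out_contigs, truths
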