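"""End-to-end orchestration: generate -> ORFs -> screens -> topology ->
defense scan -> codon clustering -> association -> report.

The run is single-process and fully deterministic for a fixed config: stage
outputs are written as TSV/FASTA/JSON under the configured output directory
and the accounting report is internally consistent (strata sum to totals).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Sequence

from . import assoc as assoc_mod
from . import codon as codon_mod
from . import defense as defense_mod
from . import io as io_mod
from . import orfs as orfs_mod
from . import screen as screen_mod
from . import topology as topology_mod
from .records import Contig, TruthRecord
from .synthetic import GeneratorConfig, generate

logger = logging.getLogger("cvvscan")


@dataclass
class RunConfig:
    """All pipeline thresholds, with the defaults used throughout the package."""

    generator: GeneratorConfig = dc_field(default_factory=GeneratorConfig)
    input_fasta: Optional[str] = None   # analyse an existing assembly instead
    input_truth: Optional[str] = None
    outdir: str = "cvvscan_out"
    min_orf_aa: int = 50
    vp_min_length: int = 5000           # virophage candidates must exceed this
    vp_long_length: int = 10000         # "long" stratum cut
    vp_max_e: float = 1e-5
    lv_profile_max_e: float = 1e-5
    lv_pairwise_max_e: float = 1e-10
    lv_min_families: int = 3
    lv_defense_min_length: int = 100000  # large viruses entering defense/association
    ks: tuple[int, ...] = defense_mod.ALLOWED_KS
    max_mismatch: int = 1
    min_overlap: int = 20
    min_tir: int = 100
    length_bin_edges: tuple[int, ...] = (5000, 50000, 100000)
    assoc_max_e: float = 1e-5
    assoc_min_cov: float = 0.5
    assoc_min_id: float = 0.3
    cluster_height: Optional[float] = None

    def validate(self) -> None:
        self.generator.validate()
        for name in ("vp_max_e", "lv_profile_max_e", "lv_pairwise_max_e", "assoc_max_e"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if not 0 <= self.assoc_min_cov <= 1 or not 0 <= self.assoc_min_id <= 1:
            raise ValueError("coverage/identity thresholds must be fractions")
        if self.max_mismatch not in (0, 1):
            raise ValueError("max_mismatch must be 0 or 1")


def floor_percent(numerator: int, denominator: int) -> int:
    """Integer percentage, truncated (55 of 94 -> 58)."""
    if denominator == 0:
        return 0
    return math.floor(100 * numerator / denominator)


def stratify(lengths: Sequence[int],
             edges: Sequence[int] = (5000, 50000, 100000)) -> dict[str, int]:
    """Bin lengths into left-closed right-open bins, last bin unbounded.

    Lengths below the first edge are tallied under ``below_min`` so counts
    always sum to the total.
    """
    edges = list(edges)
    labels = [f"{edges[i] // 1000}-{edges[i + 1] // 1000}kb" for i in range(len(edges) - 1)]
    labels.append(f">{edges[-1] // 1000}kb")
    counts = {label: 0 for label in labels}
    counts["below_min"] = 0
    for length in lengths:
        if length < edges[0]:
            counts["below_min"] += 1
            continue
        placed = False
        for i in range(len(edges) - 1):
            if edges[i] <= length < edges[i + 1]:
                counts[labels[i]] += 1
                placed = True
                break
        if not placed:
            counts[labels[-1]] += 1
    return counts


def summarize_distribution(
    entries: Sequence[tuple[Optional[str], str]],
) -> dict:
    """Per-site tallies of virophages and large viruses.

    ``entries`` are (site label, category) pairs; categories are
    ``virophage`` / ``large_virus``.  A site with at least one of each is a
    co-occurrence site.  Missing labels are counted under ``unlabeled``.
    """
    per_site: dict[str, dict] = {}
    total = 0
    for site, category in entries:
        site = site if site else "unlabeled"
        slot = per_site.setdefault(site, {"virophage": 0, "large_virus": 0})
        if category not in slot:
            raise ValueError(f"unknown category {category!r}")
        slot[category] += 1
        total += 1
    for site, slot in per_site.items():
        slot["cooccurrence"] = slot["virophage"] > 0 and slot["large_virus"] > 0
        slot["fraction"] = (slot["virophage"] + slot["large_virus"]) / total if total else 0.0
    return {
        "sites": per_site,
        "n_sites": len(per_site),
        "n_cooccurrence_sites": sum(1 for s in per_site.values() if s["cooccurrence"]),
        "total_detections": total,
    }


def _write_topology_tsv(calls, path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tverdict\trepeat_kind\trepeat_length\tcoordinates\n")
        for c in calls:
            coords = ""
            if c.repeat_coordinates:
                (a, b), (x, y) = c.repeat_coordinates
                coords = f"{a}-{b};{x}-{y}"
            fh.write(f"{c.contig_id}\t{c.verdict}\t{c.repeat_kind}\t"
                     f"{c.repeat_length}\t{coords}\n")


def virophage_strata(candidates, long_length: int = 10000) -> dict[str, int]:
    """Accounting strata for virophage candidates.

    ``ge3_markers`` + ``eq2_markers`` always equals ``candidates``;
    ``long_multi_marker`` counts candidates with 3-4 marker families longer
    than ``long_length``, with its truncated integer percentage.
    """
    n_ge3 = sum(1 for r in candidates if len(r.distinct_markers) >= 3)
    n_eq2 = sum(1 for r in candidates if len(r.distinct_markers) == 2)
    long_multi = sum(
        1 for r in candidates
        if len(r.distinct_markers) in (3, 4) and r.length > long_length)
    return {
        "candidates": len(candidates),
        "ge3_markers": n_ge3,
        "eq2_markers": n_eq2,
        "long_multi_marker": long_multi,
        "long_multi_marker_pct": floor_percent(long_multi, len(candidates)),
    }


def run(config: RunConfig, write_outputs: bool = True,
        return_details: bool = False):
    """Execute the full pipeline and return the run report (JSON-compatible).

    With ``return_details`` the per-stage objects (screen results, topology
    calls, spacer hits, cluster result, ranked pairs, ...) are returned
    alongside the report for downstream scoring against ground truth.
    """
    config.validate()
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    # ----- stage: inputs --------------------------------------------------
    truths: list[TruthRecord] = []
    if config.input_fasta:
        contigs = io_mod.read_fasta(config.input_fasta)
        if config.input_truth:
            truths = io_mod.read_truth_tsv(config.input_truth)
        logger.info("load: %d contigs from %s", len(contigs), config.input_fasta)
    else:
        contigs, truths = generate(config.generator)
        logger.info("generate: %d contigs (seed=%d)", len(contigs), config.generator.seed)
    if write_outputs:
        io_mod.write_fasta(contigs, outdir / "contigs.fasta")
        if truths:
            io_mod.write_truth_tsv(truths, outdir / "truth.tsv")
        io_mod.write_json(config.generator.to_dict(), outdir / "config.json")

    # ----- stage: ORFs ----------------------------------------------------
    orfs = [o for c in contigs for o in orfs_mod.find_orfs(c, min_aa=config.min_orf_aa)]
    logger.info("orfs: %d predicted on %d contigs", len(orfs), len(contigs))
    if write_outputs:
        orfs_mod.write_gff3(orfs, outdir / "orfs.gff3")
        orfs_mod.write_protein_fasta(orfs, outdir / "proteins.faa")

    # ----- stage: screens -------------------------------------------------
    vp_results = screen_mod.screen_virophages(
        contigs, orfs, max_e=config.vp_max_e, min_length=config.vp_min_length)
    vp_candidates = [r for r in vp_results if r.category == "virophage_candidate"]
    lv_profile = screen_mod.screen_large_viruses(
        contigs, orfs, mode="profile", max_e=config.lv_profile_max_e,
        min_families=config.lv_min_families)
    lv_pairwise = screen_mod.screen_large_viruses(
        contigs, orfs, mode="pairwise", max_e=config.lv_pairwise_max_e,
        min_families=config.lv_min_families)
    prof_ids = {r.contig_id for r in lv_profile if r.category == "large_virus_candidate"}
    pair_ids = {r.contig_id for r in lv_pairwise if r.category == "large_virus_candidate"}
    union_report = screen_mod.merge_candidate_sets(prof_ids, pair_ids)
    lv_ids = sorted(prof_ids | pair_ids)
    logger.info("screen: %d virophage candidates, %d large-virus candidates "
                "(profile %d, pairwise %d, both %d)",
                len(vp_candidates), len(lv_ids), len(prof_ids), len(pair_ids),
                union_report["intersection"])
    if write_outputs:
        screen_mod.write_screen_tsv(vp_results, outdir / "virophage_screen.tsv")
        screen_mod.write_screen_tsv(lv_profile, outdir / "large_virus_profile.tsv")
        screen_mod.write_screen_tsv(lv_pairwise, outdir / "large_virus_pairwise.tsv")
        io_mod.write_json(union_report, outdir / "large_virus_union.json")

    by_id = {c.id: c for c in contigs}
    vp_contigs = [by_id[r.contig_id] for r in vp_candidates]
    lv_contigs = [by_id[i] for i in lv_ids]
    lv_big = [c for c in lv_contigs if len(c) >= config.lv_defense_min_length]

    # ----- stage: topology ------------------------------------------------
    calls = [topology_mod.classify(c, min_overlap=config.min_overlap,
                                   min_tir=config.min_tir) for c in vp_contigs]
    n_circ = sum(1 for c in calls if c.verdict == "circular")
    n_lin = sum(1 for c in calls if c.verdict == "linear")
    logger.info("topology: %d circular, %d linear, %d fragments",
                n_circ, n_lin, len(calls) - n_circ - n_lin)
    if write_outputs:
        _write_topology_tsv(calls, outdir / "topology.tsv")

    # ----- stage: defense scan --------------------------------------------
    hits = []
    if vp_contigs and lv_big:
        hits = defense_mod.scan(vp_contigs, lv_big, ks=config.ks,
                                max_mismatch=config.max_mismatch)
        lv_by_id = {c.id: c for c in lv_big}
        for h in hits:
            defense_mod.find_flank_repeats(lv_by_id[h.large_virus_id], h)
    logger.info("defense: %d spacer hits", len(hits))
    if write_outputs:
        defense_mod.write_hits_tsv(hits, outdir / "spacer_hits.tsv")
        defense_mod.write_hits_bed(hits, outdir / "spacer_hits.bed")

    # ----- stage: codon usage ---------------------------------------------
    genomes = vp_contigs + lv_big
    orfs_by_contig: dict[str, list] = {}
    for o in orfs:
        orfs_by_contig.setdefault(o.contig_id, []).append(o)
    profiles = [
        codon_mod.profile(c.id, [orfs_mod.orf_nt(c, o)
                                 for o in orfs_by_contig.get(c.id, [])])
        for c in genomes
    ]
    cluster_result = None
    dist_lookup: dict[tuple[str, str], float] = {}
    if sum(p.usable for p in profiles) >= 2:
        ids, dm = codon_mod.distance_matrix(profiles)
        cluster_result = codon_mod.cluster(ids, dm, height=config.cluster_height)
        index = {g: i for i, g in enumerate(ids)}
        for vp in vp_contigs:
            for lv in lv_big:
                if vp.id in index and lv.id in index:
                    dist_lookup[(vp.id, lv.id)] = float(dm[index[vp.id], index[lv.id]])
        if write_outputs:
            codon_mod.write_profiles_tsv(profiles, outdir / "codon_profiles.tsv")
            codon_mod.write_matrix_tsv(ids, dm, outdir / "codon_distance.tsv")
            with open(outdir / "codon_tree.nwk", "w") as fh:
                fh.write(codon_mod.to_newick(cluster_result) + "\n")
    logger.info("codon: %d usable profiles", sum(p.usable for p in profiles))

    # ----- stage: association ---------------------------------------------
    vp_prot = [(o.contig_id, o.id, o.protein)
               for c in vp_contigs for o in orfs_by_contig.get(c.id, [])]
    lv_prot = [(o.contig_id, o.id, o.protein)
               for c in lv_big for o in orfs_by_contig.get(c.id, [])]
    links = assoc_mod.shared_proteins(
        vp_prot, lv_prot, max_e=config.assoc_max_e,
        min_cov=config.assoc_min_cov, min_id=config.assoc_min_id)
    clinks = []
    if cluster_result is not None:
        clinks = assoc_mod.codon_links(
            cluster_result, [c.id for c in vp_contigs], [c.id for c in lv_big],
            dist_lookup)
    candidates = assoc_mod.pair_candidates(links + clinks)
    logger.info("association: %d shared-protein links, %d codon links, %d pairs",
                len(links), len(clinks), len(candidates))
    if write_outputs:
        assoc_mod.write_candidates_tsv(candidates, outdir / "association.tsv")

    # ----- stage: site tallies --------------------------------------------
    entries = [(c.site, "virophage") for c in vp_contigs] + \
              [(c.site, "large_virus") for c in lv_contigs]
    distribution = summarize_distribution(entries)

    # ----- report ---------------------------------------------------------
    strata = virophage_strata(vp_candidates, config.vp_long_length)
    report = {
        "n_contigs": len(contigs),
        "virophage": {
            **strata,
            "complete": {"circular": n_circ, "linear": n_lin,
                         "total": n_circ + n_lin},
        },
        "large_virus": {
            "profile": len(prof_ids),
            "pairwise": len(pair_ids),
            "union_report": union_report,
            "candidates": len(lv_ids),
            "length_bins": stratify([len(by_id[i]) for i in lv_ids],
                                    config.length_bin_edges),
        },
        "defense": {
            "spacer_hits": len(hits),
            "hits_with_flank_repeats": sum(1 for h in hits if h.flank_repeats),
        },
        "association": {
            "shared_protein_links": len(links),
            "codon_links": len(clinks),
            "pairs": [
                {"virophage": c.virophage_id, "large_virus": c.large_virus_id,
                 "support": c.support_count, "rank": c.rank}
                for c in candidates
            ],
        },
        "distribution": distribution,
    }
    assert report["virophage"]["ge3_markers"] + report["virophage"]["eq2_markers"] \
        == report["virophage"]["candidates"], "marker strata must sum to total"
    if write_outputs:
        io_mod.write_json(report, outdir / "report.json")
    if return_details:
        details = {
            "contigs": contigs,
            "truths": truths,
            "orfs": orfs,
            "vp_results": vp_results,
            "lv_profile": lv_profile,
            "lv_pairwise": lv_pairwise,
            "topology_calls": calls,
            "spacer_hits": hits,
            "profiles": profiles,
            "cluster_result": cluster_result,
            "codon_distances": dist_lookup,
            "links": links,
            "codon_links": clinks,
            "candidates": candidates,
        }
        return report, details
    return report
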