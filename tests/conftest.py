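"""Shared fixtures: a session-scoped default benchmark run plus small helpers."""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cvvscan.pipeline import RunConfig, run
from cvvscan.synthetic import (
    GeneratorConfig,
    _back_translate,
    _codon_preference,
    _mutate_protein,
    _random_nt,
)

settings.register_profile(
    "suite", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

DEFAULT_SEED = 42


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full pipeline run on the default benchmark virome (fixed seed)."""
    outdir = tmp_path_factory.mktemp("default_run")
    cfg = RunConfig(generator=GeneratorConfig(seed=DEFAULT_SEED), outdir=str(outdir))
    report, details = run(cfg, return_details=True)
    return {"config": cfg, "outdir": outdir, "report": report, **details}


@pytest.fixture(scope="session")
def truth_by_id(default_run):
    return {t.contig_id: t for t in default_run["truths"]}


def build_gene_contig(rng: np.random.Generator, proteins, pad_to: int,
                      gc: float = 0.45) -> str:
    """A contig carrying the given proteins as guarded CDS blocks, padded."""
    pref = _codon_preference(rng)
    parts = []
    for prot in proteins:
        parts.append(_random_nt(rng, 60, gc))
        parts.append("TAA" + _back_translate(rng, prot, pref))
    seq = "".join(parts)
    if len(seq) < pad_to:
        seq += _random_nt(rng, pad_to - len(seq), gc)
    return seq


@pytest.fixture
def gene_contig_builder():
    return build_gene_contig


@pytest.fixture
def mutate_protein():
    return _mutate_protein
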