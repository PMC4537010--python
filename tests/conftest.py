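from __future__ import annotations

import pytest

from icvseq.annotate import AnnotatedRead
from icvseq.germline import default_alleles
from icvseq.pipeline import PipelineConfig, run_pipeline
from icvseq.simulate import SimConfig, simulate_repertoire


@pytest.fixture(scope="session")
def alleles():
    return default_alleles()


def make_annotated(
    cdr3: str,
    replicate: str = "A",
    v_projection: str = "ACGT",
    allele: str = "IGHVS1-1*01",
    start: int = 0,
    read_id: str = "r",
    mutations=(),
) -> AnnotatedRead:
    return AnnotatedRead(
        read_id=read_id,
        replicate=replicate,
        allele=allele,
        aln_start_germ=start,
        aln_end_germ=start + len(v_projection),
        mutations=list(mutations),
        homology_pct=100.0,
        cdr3_nt=cdr3,
        cdr3_aa=None,
        v_projection=v_projection,
    )


def binom_interval(n: int, p: float, conf: float = 0.99) -> tuple[int, int]:
    from scipy.stats import binom

    lo, hi = binom.interval(conf, n, p)
    return int(lo), int(hi)


@pytest.fixture(scope="session")
def mm_run(tmp_path_factory):
    """MM-like dataset (dominant clone 0.8, 1e4 pairs) run through the
    full pipeline; shared across tests for speed."""
    base = tmp_path_factory.mktemp("mm")
    config = SimConfig(seed=11, total_read_pairs=10_000)
    a1, a2, b1, b2, truth = simulate_repertoire(config, base / "sim")
    pconfig = PipelineConfig(
        sample_id="mm_synth",
        repA_r1=str(a1),
        repA_r2=str(a2),
        repB_r1=str(b1),
        repB_r2=str(b2),
    )
    result = run_pipeline(pconfig, base / "run")
    return config, truth, result, base / "run"


@pytest.fixture(scope="session")
def error_free_run(tmp_path_factory):
    """Zero-error dataset: every read reconstructs a ground-truth amplicon."""
    base = tmp_path_factory.mktemp("clean")
    config = SimConfig(
        seed=23,
        total_read_pairs=3_000,
        seq_error_rate=0.0,
        pcr_error_rate=0.0,
        n_background_clones=10,
    )
    a1, a2, b1, b2, truth = simulate_repertoire(config, base / "sim")
    pconfig = PipelineConfig(
        sample_id="clean_synth",
        repA_r1=str(a1),
        repA_r2=str(a2),
        repB_r1=str(b1),
        repB_r2=str(b2),
        min_count_each_replicate=0,
        min_freq_each_replicate=0.0,
    )
    result = run_pipeline(pconfig, base / "run")
    return config, truth, result, base / "run"


@pytest.fixture(scope="session")
def npc_run(tmp_path_factory):
    """Polyclonal (normal-PC-like) dataset: no clone above the 5% cut-off."""
    base = tmp_path_factory.mktemp("npc")
    config = SimConfig(
        seed=31,
        total_read_pairs=6_000,
        dominant_clone_fraction=0.0,
        n_background_clones=80,
        background_abundance_shape=0.3,
    )
    a1, a2, b1, b2, truth = simulate_repertoire(config, base / "sim")
    pconfig = PipelineConfig(
        sample_id="npc_synth",
        repA_r1=str(a1),
        repA_r2=str(a2),
        repB_r1=str(b1),
        repB_r2=str(b2),
    )
    result = run_pipeline(pconfig, base / "run")
    return config, truth, result, base / "run"
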