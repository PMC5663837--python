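import pytest

from circkit.pipeline import RunConfig, run_pipeline
from circkit.synthetic import SimConfig, fixture_minimal, simulate_cohort


@pytest.fixture(scope="session")
def minimal():
    return fixture_minimal()


@pytest.fixture(scope="session")
def small_cfg():
    # a scaled-down cohort so every stage runs in seconds
    return SimConfig(
        n_cells=6,
        n_circ=40,
        n_genes_extra=20,
        n_mirnas=12,
        snp_rate_per_gene=0.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, small_cfg):
    outdir = tmp_path_factory.mktemp("cohort")
    gt = simulate_cohort(small_cfg, outdir)
    return outdir, gt


@pytest.fixture(scope="session")
def pipeline_run(small_cohort, tmp_path_factory):
    outdir, gt = small_cohort
    run_out = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        data_dir=str(outdir), out_dir=str(run_out), gsea_n_perm=200, seed=11
    )
    summary = run_pipeline(cfg)
    return cfg, summary, run_out, gt
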