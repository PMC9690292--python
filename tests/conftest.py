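import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def sim_run(tmp_path_factory):
    """One default-configuration synthetic bundle plus its pipeline run,
    shared across tests (seed fixed)."""
    from Bio import SeqIO

    from rgacnv import io
    from rgacnv.pipeline import run_pipeline
    from rgacnv.simulate import default_paper_like_config, simulate

    out = tmp_path_factory.mktemp("bundle")
    cfg = default_paper_like_config(seed=11)
    bundle, truth = simulate(cfg, out)
    reference = {
        r.id: str(r.seq) for r in SeqIO.parse(str(bundle.reference_fasta), "fasta")
    }
    result = run_pipeline(
        bundle.call_files,
        bundle.genes_gff3,
        bundle.domains_tsv,
        gaps=io.read_bed_gaps(bundle.gaps_bed),
        marker_rows=io.read_marker_table(bundle.markers_tsv),
        reference=reference,
        genotypes_path=bundle.genotypes_tsv,
    )
    return cfg, bundle, truth, result
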