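import pytest

from neoforge.pipeline import RunConfig, run
from neoforge.synthetic import SyntheticConfig, generate_reference, implant_variants


@pytest.fixture(scope="session")
def study():
    """One fully generated toy study (50 variants, implanted binder)."""
    config = SyntheticConfig(seed=7)
    bundle = generate_reference(config)
    somatic, rna, truth = implant_variants(bundle, config)
    return {
        "config": config,
        "bundle": bundle,
        "somatic": somatic,
        "rna": rna,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """A complete orchestrated run on the default synthetic study."""
    outdir = tmp_path_factory.mktemp("run_seed7")
    return run(RunConfig(outdir=outdir, seed=7, synthetic=SyntheticConfig()))


@pytest.fixture(scope="session")
def toy_gene():
    """Single-exon plus-strand toy: CDS ATG CTG GAA TAA at chrT:5-16."""
    from neoforge.consequence import TranscriptModel

    genome = {"chrT": "GGGG" + "ATGCTGGAATAA" + "GGGG"}
    transcript = TranscriptModel("toy_t1", "toy_g1", "chrT", "+", [(5, 16)])
    return genome, transcript
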