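import pandas as pd
import pytest

from circmir import RunConfig, generate_fixture, run_pipeline


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    """The designed synthetic dataset (seed 42), generated once per session."""
    return generate_fixture(tmp_path_factory.mktemp("fixture"), seed=42)


@pytest.fixture(scope="session")
def fixture_run(fixture, tmp_path_factory):
    """One full pipeline run on the synthetic dataset: (report, DataFrame)."""
    out = tmp_path_factory.mktemp("run") / "out.csv"
    config = RunConfig(
        input_bed=fixture.circ_bed,
        genome_fasta=fixture.genome_fa,
        gtf=fixture.gtf,
        mirna_fasta=fixture.mirna_fa,
        validated_bed=fixture.validated_bed,
        ago_bed=fixture.ago_bed,
        circbase_bed=fixture.circbase_bed,
        output_csv=out,
    )
    report = run_pipeline(config)
    frame = pd.read_csv(out, keep_default_na=False)
    return report, frame, out
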