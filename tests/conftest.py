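import pytest

from pmfvar import datasets, io_formats, pipeline


@pytest.fixture(scope="session")
def reference_table():
    return datasets.load_reference_table()


@pytest.fixture(scope="session")
def reference_inputs(tmp_path_factory):
    """The published 22-variant summary re-expressed as pipeline inputs."""
    outdir = tmp_path_factory.mktemp("reference")
    paths = datasets.reference_input_files(outdir)
    records = io_formats.read_variant_table(paths["variants"])
    panels = io_formats.read_frequency_panel(paths["frequencies"], datasets.SOURCE_ORDER)
    return {"paths": paths, "records": records, "panels": panels}


@pytest.fixture(scope="session")
def reference_summary(reference_inputs, tmp_path_factory):
    """Full pipeline run on the reference cohort summary."""
    out = tmp_path_factory.mktemp("reference_run")
    cfg = pipeline.PipelineConfig(
        variants=str(reference_inputs["paths"]["variants"]),
        frequencies=str(reference_inputs["paths"]["frequencies"]),
        out_dir=str(out),
        n_cases=datasets.N_CASES,
    )
    summary = pipeline.run_all(cfg)
    return {"summary": summary, "out": out}
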