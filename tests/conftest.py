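import pytest

from dndcrispr import io, pipeline


@pytest.fixture(scope="session")
def synthetic_run(tmp_path_factory):
    """One full pipeline run on the default synthetic study (seed 1)."""
    out = tmp_path_factory.mktemp("synthetic_run")
    cfg = io.PipelineConfig(simulate={}, seed=1, out_dir=str(out))
    return pipeline.run_pipeline(cfg)


def make_reference(seqs):
    """Callable (chrom, start, end) -> sequence over a dict of strings."""
    def ref(chrom, start, end):
        return seqs[chrom][max(start, 0):end]
    return ref
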