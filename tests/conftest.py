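import io

import pytest
from hypothesis import HealthCheck, settings

from seedspan.aligner_core import AlignParams
from seedspan.genome_index import build_index
from seedspan.parallel_exec import run_parallel
from seedspan.seq_io import SequenceRecord, parse_psl
from seedspan.synthetic_data import SynthConfig, gen_genome, gen_transcripts, ont_corpus

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def std_config():
    """Standard synthetic corpus configuration (all generator defaults)."""
    return SynthConfig()


@pytest.fixture(scope="session")
def std_genome(std_config):
    return gen_genome(std_config)


@pytest.fixture(scope="session")
def std_corpus(std_genome, std_config):
    """(reads, truths) of the clean spliced-transcript corpus."""
    pairs = gen_transcripts(std_genome, std_config)
    reads = [
        SequenceRecord(r.name, r.description, r.residues, i)
        for i, (r, _) in enumerate(pairs)
    ]
    truths = [t for _, t in pairs]
    return reads, truths


@pytest.fixture(scope="session")
def std_params():
    return AlignParams()


@pytest.fixture(scope="session")
def std_index(std_genome, std_params):
    p = std_params
    return build_index(std_genome, p.tile_size, p.step_size, p.overused_cutoff)


@pytest.fixture(scope="session")
def std_serial_output(std_corpus, std_genome, std_params, std_index):
    """Headerless serial PSL text for the clean corpus (the reference all
    parallel configurations must reproduce byte for byte)."""
    reads, _ = std_corpus
    buf = io.StringIO()
    run_parallel(reads, std_genome, std_params, workers=1, out_sink=buf,
                 index=std_index)
    return buf.getvalue()


@pytest.fixture(scope="session")
def ont_config():
    """Nanopore-like corpus: 12% total error, fragment lengths around
    mean 1868 / median 1787 bases."""
    return SynthConfig(error_rates=(0.06, 0.03, 0.03), read_length_stats=(1868, 1787))


@pytest.fixture(scope="session")
def ont_reads(std_genome, ont_config):
    return ont_corpus(std_genome, ont_config)


@pytest.fixture(scope="session")
def std_psl_records(std_serial_output):
    return parse_psl(std_serial_output)
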