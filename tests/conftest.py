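import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper

from avissr.detect import DetectorParams
from avissr.synth import generate_genome, random_genome_spec


@pytest.fixture(scope="session")
def params():
    return DetectorParams()


@pytest.fixture(scope="session")
def planted_genome():
    """One 2 x 60 kb synthetic genome with 50 planted loci of all classes."""
    spec = random_genome_spec(rng_seed=11)
    return spec, generate_genome(spec)


@pytest.fixture(scope="session")
def planted_genome_dir(planted_genome, tmp_path_factory):
    spec, genome = planted_genome
    out = tmp_path_factory.mktemp("genome")
    genome.write(out)
    return out
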