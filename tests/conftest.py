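import numpy as np
import pytest

from sporescreen import annotation, pipeline, synth
from sporescreen.screen import ScreenConfig


@pytest.fixture(scope="session")
def small_screenset(tmp_path_factory):
    """A small synthetic 4-species screen set shared across test modules."""
    out = tmp_path_factory.mktemp("screenset")
    return synth.generate_screenset(
        n_structured=10, n_background=14, n_canonical=4, seed=42, out_dir=out
    )


@pytest.fixture(scope="session")
def small_catalog(small_screenset):
    return annotation.parse_genbank_ncrnas(str(small_screenset.genbank_path))


@pytest.fixture(scope="session")
def small_families(small_screenset, small_catalog):
    conserved, families = pipeline.build_families(
        small_catalog, small_screenset.maf_paths
    )
    return conserved, families


@pytest.fixture(scope="session")
def small_alignments(small_families, small_catalog):
    _, families = small_families
    return pipeline.build_alignments(families, small_catalog)


@pytest.fixture(scope="session")
def screen_cfg():
    return ScreenConfig(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rna(rng, length):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, length))
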