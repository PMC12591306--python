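import numpy as np
import pytest

from chclone.config import PipelineConfig
from chclone.records import VariantRecord
from chclone.simulate import simulate_cds_panel


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_panel():
    return simulate_cds_panel(n_genes=5, length_codons=60, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_variant(**kwargs):
    """A clean, filter-passing SNV with overridable fields."""
    defaults = dict(
        sample_id="S1",
        chrom="chr1",
        pos=500,
        ref="A",
        alt="G",
        variant_class="SNV",
        depth=2000,
        alt_count=40,
        vaf=0.02,
        strand_counts=(980, 980, 20, 20),
        orientation_counts=(20, 20),
        gene="DNMT3A",
        consequence="missense",
        popaf_exome=0.0001,
        popaf_genome=0.0001,
        cosmic_count=0,
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


@pytest.fixture
def variant_factory():
    return make_variant
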