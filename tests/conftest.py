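import sys
from pathlib import Path

import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from ploidyseq.annotation import Feature
from ploidyseq.counts import CountTable
from ploidyseq.simulate import (
    GenomeConfig,
    MotifPlantConfig,
    SimulationConfig,
)


@pytest.fixture
def small_config():
    """Test-scale simulation: same structure, reduced depth and gene count."""
    return SimulationConfig(
        seed=7,
        n_genes=400,
        depth_per_sample=100_000,
        freq_log_sd=1.0,
        n_de=20,
        fold_range=(0.25, 4.0),
        genome=GenomeConfig(gene_length=(300, 600),
                            intergenic_gap=(150, 900)),
        motif_plant=MotifPlantConfig(plant_fraction=0.8,
                                     background_rate=0.05),
    )


@pytest.fixture
def toy_pair():
    """Hand-built haploid/tetraploid pair with one obvious DE gene."""
    hap = CountTable(
        sample_id="hapA", ploidy="1n",
        counts={"gene_flat": 100.0, "gene_down": 400.0, "gene_low": 5.0},
        library_total=1_000_000,
    )
    tet = CountTable(
        sample_id="tetA", ploidy="4n",
        counts={"gene_flat": 100.0, "gene_down": 100.0, "gene_low": 5.0},
        library_total=1_000_000,
    )
    return hap, tet


@pytest.fixture
def toy_annotation():
    """Plus- and minus-strand genes with controlled upstream geometry."""
    return [
        Feature("up_feat", "chr1", 8000, 8800, "+"),
        Feature("plus_near", "chr1", 10000, 11000, "+"),
        Feature("minus_gene", "chr1", 13000, 14000, "-"),
        Feature("far_gene", "chr1", 25000, 26000, "+"),
    ]
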