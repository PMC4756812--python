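import numpy as np
import pytest

from allelome.pseudogenome import HaplotypeGenome, SnpRecord
from allelome.synthetic_data import SimConfig, SimDataset, simulate_dataset


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    return SimConfig(
        n_chromosomes=2,
        chrom_length=12_000,
        n_peaks_per_category=2,
        reads_per_peak_per_line=80,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SimDataset:
    """One shared small simulated dataset (10 peaks, 2 chromosomes)."""
    return simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_dataset() -> SimDataset:
    """Error-free, duplicate-free dataset for exact-contract checks."""
    cfg = SimConfig(
        n_chromosomes=2,
        chrom_length=12_000,
        n_peaks_per_category=2,
        reads_per_peak_per_line=60,
        error_rate=0.0,
        duplicate_fraction=0.0,
        seed=5,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def toy_genomes():
    """Tiny two-haplotype pair differing at one SNP (chr1:26 A/G)."""
    b6_seq = "ACGTACGTACGTACGTACGTACGTAACGTACGTACGTACGTACGTACGTACGTACGTACG"
    jf1_seq = b6_seq[:25] + "G" + b6_seq[26:]
    b6 = HaplotypeGenome("B6", {"chr1": b6_seq})
    jf1 = HaplotypeGenome("JF1", {"chr1": jf1_seq})
    snp = SnpRecord("chr1", 26, "A", "G")
    return b6, jf1, snp
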