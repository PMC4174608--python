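import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from ssfilter.synthetic_data import SimConfig, simulate_assembly, simulate_pairs


@pytest.fixture
def tiny_fasta(tmp_path):
    p = tmp_path / "tiny.fasta"
    p.write_text(">comp1_c0_seq1\nACGT\n>comp1_c0_seq2\nACGTACGT\n>geneX\nAACCGGTT\n")
    return p


@pytest.fixture(scope="session")
def leaky_dataset(tmp_path_factory):
    """A small simulated dataset with twins, contamination, and SNPs."""
    d = tmp_path_factory.mktemp("leaky")
    cfg = SimConfig(
        seed=7,
        n_components=12,
        isoforms_per_component=(1, 3),
        transcript_len=(600, 1200),
        leak_prob=0.1,
        twin_fraction=0.5,
        contamination_fraction=0.3,
        pairs_per_transcript=(150, 250),
        snp_sites_per_kb=1.0,
        error_rate=0.002,
    )
    transcripts, truth = simulate_assembly(cfg)
    sam = d / "pairs.sam"
    simulate_pairs(cfg, transcripts, truth, sam)
    return cfg, transcripts, truth, sam
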