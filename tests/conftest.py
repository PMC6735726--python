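import numpy as np
import pytest

from duplexsc.bamio import PairedRead, seq_to_array
from duplexsc.simulator import (
    SimConfig,
    simulate_library,
    write_toy_panel,
    write_toy_reference,
)


@pytest.fixture(scope="session")
def toy_reference(tmp_path_factory):
    path = tmp_path_factory.mktemp("ref") / "toy.fa"
    return write_toy_reference(str(path))


@pytest.fixture(scope="session")
def toy_panel(toy_reference, tmp_path_factory):
    path = tmp_path_factory.mktemp("panel") / "panel.bed"
    return write_toy_panel(str(path), toy_reference)


@pytest.fixture(scope="session")
def small_panel(toy_reference, tmp_path_factory):
    """A 2 kb single-interval panel, small enough for brute-force oracles."""
    path = tmp_path_factory.mktemp("panel") / "small.bed"
    with open(path, "w") as fh:
        fh.write("toy1\t1500\t3500\n")
    return str(path)


@pytest.fixture(scope="session")
def sim_factory(toy_reference, toy_panel, tmp_path_factory):
    """Factory producing simulated libraries under unique directories."""

    def make(name, panel=None, write_fastq=False, **kwargs):
        cfg = SimConfig(
            reference=toy_reference, panel=panel or toy_panel, **kwargs
        )
        out = tmp_path_factory.mktemp(f"sim_{name}")
        return simulate_library(cfg, str(out), write_fastq=write_fastq), cfg

    return make


def make_paired_read(
    qname="t1|ACGT",
    barcode="ACGT",
    contig="toy1",
    pos1=1001,
    pos2=1101,
    length=100,
    seq1=None,
    seq2=None,
    qual=37,
    reverse1=False,
):
    """Hand-built PairedRead for unit tests (no BAM round trip)."""
    seq1 = seq1 or "A" * length
    seq2 = seq2 or "C" * length
    return PairedRead(
        qname=qname,
        barcode=barcode,
        contig1=contig,
        pos1=pos1,
        cigar1=f"{len(seq1)}M",
        reverse1=reverse1,
        seq1=seq_to_array(seq1),
        qual1=np.full(len(seq1), qual, dtype=np.uint8),
        contig2=contig,
        pos2=pos2,
        cigar2=f"{len(seq2)}M",
        reverse2=not reverse1,
        seq2=seq_to_array(seq2),
        qual2=np.full(len(seq2), qual, dtype=np.uint8),
    )
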