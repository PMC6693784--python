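"""Shared fixtures: tiny hand-built genomes and a reusable simulated dataset."""

from __future__ import annotations

import textwrap
from pathlib import Path

import pysam
import pytest

from orgedit.simulate import SimulationConfig, simulate_genome


def write_fasta(path: Path, seqs: dict[str, str]) -> Path:
    with path.open("w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, 70)) + "\n")
    return path


def write_gff(path: Path, rows: list[tuple]) -> Path:
    """rows: (seqid, start, end, strand, gene_id) CDS features."""
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for i, (seqid, start, end, strand, gene_id) in enumerate(rows):
            fh.write(
                f"{seqid}\ttest\tCDS\t{start}\t{end}\t.\t{strand}\t0\t"
                f"ID={gene_id}.cds{i};Parent={gene_id}\n"
            )
    return path


def write_sam(path: Path, ref_name: str, ref_len: int, reads: list[tuple]) -> Path:
    """reads: (name, start_1based, seq, qual_string)."""
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for name, start, seq, qual in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.reference_id = 0
            a.reference_start = start - 1
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_sequence = seq
            a.query_qualities = pysam.qualitystring_to_array(qual)
            out.write(a)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fully deterministic simulated dataset shared across tests."""
    config = SimulationConfig(n_genes=6, n_sites=60, depth_mean=500, seed=11)
    return simulate_genome(config)


@pytest.fixture()
def two_gene_fixture(tmp_path):
    """1 kb contig with one plus- and one minus-strand single-exon gene.

    Plus gene: CDS 101..160 (60 nt).  Minus gene: CDS 301..360 (60 nt).
    """
    import numpy as np

    rng = np.random.default_rng(42)
    contig = "".join(rng.choice(list("ACGT"), size=1000))
    fasta = write_fasta(tmp_path / "genome.fasta", {"chr": contig})
    gff = write_gff(
        tmp_path / "genes.gff3",
        [("chr", 101, 160, "+", "gplus"), ("chr", 301, 360, "-", "gminus")],
    )
    return fasta, gff, contig
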