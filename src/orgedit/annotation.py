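"""Organelle genome annotation: gene models, CDS extraction and coordinate maps.

Plant mitochondrial protein-coding genes live on either strand of a circular
genome and may be spliced.  All downstream editing analysis works in *CDS
coordinates*: 1-based nucleotide positions within the spliced coding sequence
read 5'->3' in transcript orientation, so that a site named ``nad7-77`` is the
77th nucleotide of the nad7 CDS regardless of which genomic strand the gene
occupies.  This module owns the (bijective) map between genomic and CDS
coordinates and the codon arithmetic built on top of it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import yaml
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import CoordinateError, ValidationError

_VALID_BASES = set("ACGTN")


@dataclass(frozen=True)
class GeneModel:
    """A transcript's CDS geometry on the organelle genome.

    ``cds_segments`` are 1-based closed genomic intervals ordered 5'->3' in
    transcript orientation: ascending genomic coordinates on the plus strand,
    descending on the minus strand.
    """

    gene_id: str
    seqid: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]
    category: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if not self.cds_segments:
            raise ValidationError(f"{self.gene_id}: no CDS segments")
        for start, end in self.cds_segments:
            if start < 1 or end < start:
                raise ValidationError(f"{self.gene_id}: bad CDS segment [{start}, {end}]")
        starts = [s for s, _ in self.cds_segments]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValidationError(
                f"{self.gene_id}: CDS segments not ordered 5'->3' in transcript orientation"
            )
        spans = sorted(self.cds_segments)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValidationError(f"{self.gene_id}: overlapping CDS segments")
        if self.cds_length % 3 != 0:
            # Organellar annotations can be ragged; do not hard-fail.
            warnings.warn(
                f"{self.gene_id}: CDS length {self.cds_length} is not a multiple of 3",
                stacklevel=2,
            )

    @property
    def cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_segments)


@dataclass(frozen=True)
class CodonRef:
    """Location of a CDS nucleotide within its codon.

    Satisfies ``3 * (codon_index - 1) + codon_offset == cds_pos`` for the
    position it was built from; ``codon_nt`` is the codon in CDS orientation.
    """

    codon_index: int
    codon_offset: int
    codon_nt: str


def default_gene_categories() -> dict[str, str]:
    """Functional category for each of the 35 maize mitochondrial genes.

    Shipped as an editable YAML asset; used to group per-site classifications
    into the standard complex-level summary rows.
    """
    from importlib.resources import files

    text = files("orgedit.data").joinpath("maize_mito_genes.yaml").read_text()
    raw = yaml.safe_load(text)
    return {gene: category for category, genes in raw["categories"].items() for gene in genes}


def default_category_order() -> list[str]:
    from importlib.resources import files

    text = files("orgedit.data").joinpath("maize_mito_genes.yaml").read_text()
    return list(yaml.safe_load(text)["categories"])


def load_genome(genome_fasta: str | Path) -> dict[str, str]:
    """Read a genome FASTA into an uppercase ``{seqid: sequence}`` dict."""
    genome = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    if not genome:
        raise ValidationError(f"no sequences in {genome_fasta}")
    return genome


def load_gene_models(
    genome_fasta: str | Path,
    gff_path: str | Path,
    category_map: Mapping[str, str] | None = None,
) -> tuple[dict[str, GeneModel], dict[str, str]]:
    """Load genome FASTA + GFF3 gene models.

    CDS features are grouped by their ``Parent`` attribute (falling back to
    ``gene_id`` / ``ID``).  Every CDS must lie within its contig; a violation
    raises :class:`ValidationError` naming the offending feature.  When
    ``category_map`` is None the shipped maize mitochondrial defaults are used.
    """
    genome = load_genome(genome_fasta)
    if category_map is None:
        category_map = default_gene_categories()

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    grouped: dict[str, dict] = {}
    for feat in db.features_of_type("CDS"):
        for key in ("Parent", "gene_id", "ID"):
            if key in feat.attributes:
                gene_id = feat.attributes[key][0]
                break
        else:
            raise ValidationError(f"CDS feature at {feat.seqid}:{feat.start} has no Parent/ID")
        if feat.seqid not in genome:
            raise ValidationError(f"{gene_id}: CDS on unknown sequence {feat.seqid!r}")
        contig_len = len(genome[feat.seqid])
        if feat.end > contig_len or feat.start < 1:
            raise ValidationError(
                f"{gene_id}: CDS [{feat.start}, {feat.end}] outside {feat.seqid} "
                f"bounds (length {contig_len})"
            )
        entry = grouped.setdefault(
            gene_id, {"seqid": feat.seqid, "strand": feat.strand, "segments": []}
        )
        if entry["seqid"] != feat.seqid or entry["strand"] != feat.strand:
            raise ValidationError(f"{gene_id}: CDS segments disagree on contig or strand")
        entry["segments"].append((feat.start, feat.end))

    models: dict[str, GeneModel] = {}
    for gene_id, entry in grouped.items():
        segments = sorted(entry["segments"], reverse=entry["strand"] == "-")
        models[gene_id] = GeneModel(
            gene_id=gene_id,
            seqid=entry["seqid"],
            strand=entry["strand"],
            cds_segments=tuple(segments),
            category=category_map.get(gene_id),
        )
    if not models:
        raise ValidationError(f"no CDS features found in {gff_path}")
    return models, genome


def extract_cds(gene: GeneModel, genome: Mapping[str, str] | str) -> str:
    """Spliced CDS sequence in transcript (5'->3') orientation, uppercase."""
    contig = genome if isinstance(genome, str) else genome[gene.seqid]
    parts = []
    for start, end in gene.cds_segments:
        if end > len(contig):
            raise ValidationError(f"{gene.gene_id}: segment [{start}, {end}] beyond contig end")
        seg = contig[start - 1 : end].upper()
        if gene.strand == "-":
            seg = str(Seq(seg).reverse_complement())
        parts.append(seg)
    cds = "".join(parts)
    bad = set(cds) - _VALID_BASES
    if bad:
        raise ValidationError(f"{gene.gene_id}: non-nucleotide characters {sorted(bad)}")
    return cds


def cds_position_to_codon(cds_pos: int, cds_seq: str) -> CodonRef:
    """Map a 1-based CDS nucleotide position to its codon.

    ``codon_index = ceil(cds_pos / 3)`` gives the 1-based residue number, so
    e.g. CDS position 77 lies at offset 2 of codon 26.
    """
    if not 1 <= cds_pos <= len(cds_seq):
        raise CoordinateError(f"cds_pos {cds_pos} outside CDS of length {len(cds_seq)}")
    codon_index = (cds_pos + 2) // 3
    codon_offset = (cds_pos - 1) % 3 + 1
    codon_nt = cds_seq[3 * (codon_index - 1) : 3 * codon_index]
    return CodonRef(codon_index=codon_index, codon_offset=codon_offset, codon_nt=codon_nt)


def genomic_to_cds(gene: GeneModel, genomic_pos: int) -> int:
    """1-based genomic position -> 1-based CDS position (transcript orientation)."""
    offset = 0
    for start, end in gene.cds_segments:
        if start <= genomic_pos <= end:
            if gene.strand == "+":
                return offset + (genomic_pos - start + 1)
            return offset + (end - genomic_pos + 1)
        offset += end - start + 1
    raise CoordinateError(f"{gene.gene_id}: genomic position {genomic_pos} not in CDS")


def cds_to_genomic(gene: GeneModel, cds_pos: int) -> int:
    """Inverse of :func:`genomic_to_cds` on valid positions."""
    if cds_pos < 1:
        raise CoordinateError(f"cds_pos must be >= 1, got {cds_pos}")
    offset = 0
    for start, end in gene.cds_segments:
        seg_len = end - start + 1
        if cds_pos <= offset + seg_len:
            within = cds_pos - offset
            if gene.strand == "+":
                return start + within - 1
            return end - within + 1
        offset += seg_len
    raise CoordinateError(f"{gene.gene_id}: cds_pos {cds_pos} beyond CDS length {offset}")


def candidate_c_positions(gene: GeneModel, genome: Mapping[str, str] | str) -> Iterable[int]:
    """CDS positions whose reference base is C (the only editable positions)."""
    cds = extract_cds(gene, genome)
    return [i + 1 for i, base in enumerate(cds) if base == "C"]
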