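"""Synthetic amplicon-sequencing data with known editing truth.

Generates fixture organelle genomes, gene models, per-site editing truth
tables and per-library read counts (or SAM reads) with the statistical
structure the amplicon editing analysis assumes: two wild-type and two mutant
libraries, ~35 genes, hundreds of C sites whose wild-type extents follow the
empirical editotype mixture (a point mass at 1.0 plus components for the
99-100 / 90-99 / 50-89 / <50 % bins), planted effect classes
abolished / decreased / increased / unaffected, binomial read sampling at
configurable coverage, and a small symmetric base-error rate.

Observed edited reads are n_T ~ Binomial(d, p) with
p = e*(1-eps) + (1-e)*eps, where e is the library's true extent and eps the
base-error rate; other-base reads are Binomial(d, eps/2); the three cells are
drawn jointly as one multinomial so depth is conserved exactly.  Sites are
edited independently within a read (no editing linkage).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio.Seq import Seq

from .annotation import GeneModel, cds_to_genomic, default_gene_categories
from .errors import ConfigError, ValidationError

#: library ids of the emulated 2 WT + 2 mutant design
DEFAULT_LIBRARIES = ("WT-1", "WT-2", "mut-1", "mut-2")

TRUTH_COLUMNS = ["gene", "position", "wt_extent", "mut_extent", "label"]


def default_genotype_map(libraries: Sequence[str] = DEFAULT_LIBRARIES) -> dict[str, str]:
    return {lib: ("wt" if lib.startswith("WT") else "mutant") for lib in libraries}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulator.

    Defaults emulate the characterised dataset: 35 genes, 493 sites, WT-extent
    bin masses 12/72/170/154/85 (within-bin distribution uniform), effect-class
    counts 5/76/22/390, effects at least threshold+margin = 20 points beyond
    the +/-10-point rule, mean per-site depth 2000, base error 0.1%.
    """

    n_genes: int = 35
    n_sites: int = 493
    cds_length_range: tuple[int, int] = (300, 1500)
    gene_names: tuple[str, ...] | None = None
    cds_lengths: Mapping[str, int] | None = None
    wt_bin_masses: tuple[int, int, int, int, int] = (12, 72, 170, 154, 85)
    label_counts: tuple[int, int, int, int] = (5, 76, 22, 390)  # abol/decr/incr/unaff
    effect_min: float = 0.20      # delta_threshold (0.10) + margin (0.10)
    effect_max: float = 0.60
    decreased_min_residual: float = 0.05
    abolished_min_wt: float = 0.15
    depth_mean: float = 2000.0
    base_error_rate: float = 0.001
    read_length: int = 150
    libraries: tuple[str, ...] = DEFAULT_LIBRARIES
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_sites < 1:
            raise ConfigError("n_genes and n_sites must be positive")
        if sum(self.label_counts) < 1:
            raise ConfigError("label_counts must not be all zero")
        if not 0.0 <= self.base_error_rate < 0.5:
            raise ConfigError("base_error_rate must lie in [0, 0.5)")
        if not 0 < self.effect_min <= self.effect_max <= 1:
            raise ConfigError("need 0 < effect_min <= effect_max <= 1")
        if len(self.libraries) != 4:
            raise ConfigError("the emulated design uses exactly 4 libraries (2 WT + 2 mutant)")


@dataclass(frozen=True)
class SimulatedDataset:
    config: SimulationConfig
    genome: dict[str, str]
    gene_models: dict[str, GeneModel]
    cds_seqs: dict[str, str]
    truth: pd.DataFrame


def _scaled_counts(weights: Sequence[int], total: int) -> list[int]:
    """Scale integer weights to sum to ``total`` by largest remainder."""
    weight_sum = sum(weights)
    raw = [w * total / weight_sum for w in weights]
    counts = [int(x) for x in raw]
    remainders = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in remainders[: total - sum(counts)]:
        counts[i] += 1
    return counts


_BIN_EDGES = ((1.0, 1.0), (0.99, 1.0), (0.90, 0.99), (0.50, 0.90), (0.0, 0.50))


def sample_wt_extents(n: int, masses: Sequence[int], rng: np.random.Generator) -> np.ndarray:
    """Draw WT extents from the editotype mixture: per-bin mass, uniform within."""
    counts = _scaled_counts(masses, n)
    values = []
    for (lo, hi), count in zip(_BIN_EDGES, counts):
        if lo == hi:
            values.append(np.full(count, lo))
        else:
            # right-open bins; nextafter keeps draws strictly below the edge
            values.append(rng.uniform(lo, np.nextafter(hi, lo), size=count))
    out = np.concatenate(values)
    rng.shuffle(out)
    return out


def assign_effects(
    wt_extents: np.ndarray, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Assign effect labels and mutant extents consistent with the rule.

    Feasibility constraints follow from the classification rule itself:
    abolished sites need enough WT editing for all four deltas to clear the
    threshold; decreased sites additionally keep a residual mutant extent so
    they are never mistaken for abolished; increased sites need headroom
    below 1.0.
    """
    n = len(wt_extents)
    counts = _scaled_counts(config.label_counts, n)
    feasible = {
        "abolished": wt_extents >= config.abolished_min_wt,
        "decreased": wt_extents >= config.effect_min + config.decreased_min_residual,
        "increased": wt_extents <= 1.0 - config.effect_min,
        "unaffected": np.ones(n, dtype=bool),
    }
    labels = np.array([""] * n, dtype=object)
    unassigned = np.ones(n, dtype=bool)
    for label, count in zip(("abolished", "decreased", "increased", "unaffected"), counts):
        pool = np.flatnonzero(unassigned & feasible[label])
        if len(pool) < count:
            raise ConfigError(
                f"only {len(pool)} sites feasible for label {label!r}, need {count}; "
                "adjust the WT extent mixture or effect sizes"
            )
        chosen = rng.choice(pool, size=count, replace=False)
        labels[chosen] = label
        unassigned[chosen] = False

    mut = wt_extents.copy()
    for i, label in enumerate(labels):
        wt = wt_extents[i]
        if label == "abolished":
            mut[i] = 0.0
        elif label == "decreased":
            hi = min(config.effect_max, wt - config.decreased_min_residual)
            delta = config.effect_min if hi <= config.effect_min else rng.uniform(config.effect_min, hi)
            mut[i] = wt - delta
        elif label == "increased":
            hi = min(config.effect_max, 1.0 - wt)
            delta = config.effect_min if hi <= config.effect_min else rng.uniform(config.effect_min, hi)
            mut[i] = wt + delta
    return labels, mut


def _gene_names(config: SimulationConfig) -> list[str]:
    if config.gene_names is not None:
        if len(config.gene_names) != config.n_genes:
            raise ConfigError("gene_names length must equal n_genes")
        return list(config.gene_names)
    maize = list(default_gene_categories())
    if config.n_genes <= len(maize):
        return maize[: config.n_genes]
    return maize + [f"gene{i:03d}" for i in range(config.n_genes - len(maize))]


def _random_cds(length: int, rng: np.random.Generator) -> str:
    body = rng.choice(list("ACGT"), size=length - 6)
    return "ATG" + "".join(body) + "TAA"


def simulate_genome(config: SimulationConfig) -> SimulatedDataset:
    """Build a fixture genome with planted editing sites and its truth table.

    Genes alternate strands (so any 2+ gene genome exercises the minus-strand
    path), roughly every fifth gene is split into two CDS segments, every
    planted site's CDS base is C, and sites keep >= 17 nt of upstream CDS so
    PPR windows stay extractable.  Byte-identical rerun under the same seed.
    """
    rng = np.random.default_rng(config.seed)
    names = _gene_names(config)
    lo, hi = config.cds_length_range
    lengths = {}
    for name in names:
        if config.cds_lengths and name in config.cds_lengths:
            length = int(config.cds_lengths[name])
        else:
            length = int(rng.integers(lo, hi + 1))
        length -= length % 3
        if length < 60:
            raise ConfigError(f"CDS length {length} for {name} too short (< 60)")
        lengths[name] = length

    # distribute sites over genes proportional to CDS length
    site_counts = _scaled_counts([lengths[n] for n in names], config.n_sites)

    cds_seqs: dict[str, str] = {}
    site_positions: dict[str, np.ndarray] = {}
    for name, n_sites in zip(names, site_counts):
        length = lengths[name]
        cds = list(_random_cds(length, rng))
        eligible = np.arange(18, length - 3)  # keep start codon and stop intact
        if n_sites > len(eligible):
            raise ConfigError(f"{name}: cannot plant {n_sites} sites in CDS of length {length}")
        positions = np.sort(rng.choice(eligible, size=n_sites, replace=False))
        for pos in positions:
            cds[pos - 1] = "C"
        cds_seqs[name] = "".join(cds)
        site_positions[name] = positions

    # assemble the contig: spacer, gene, spacer, gene, ...
    contig_parts: list[str] = []
    cursor = 0
    gene_models: dict[str, GeneModel] = {}

    def emit(seq: str) -> tuple[int, int]:
        nonlocal cursor
        contig_parts.append(seq)
        start = cursor + 1
        cursor += len(seq)
        return start, cursor

    for i, name in enumerate(names):
        emit("".join(rng.choice(list("ACGT"), size=100)))  # intergenic spacer
        strand = "+" if i % 2 == 0 else "-"
        cds = cds_seqs[name]
        split = i % 5 == 4 and len(cds) >= 120
        if split:
            cut = (len(cds) // 2 // 3) * 3  # codon-boundary cut near the middle
            pieces = [cds[:cut], cds[cut:]]
        else:
            pieces = [cds]
        intron = "".join(rng.choice(list("ACGT"), size=60))
        if strand == "+":
            spans = []
            for j, piece in enumerate(pieces):
                if j:
                    emit(intron)
                spans.append(emit(piece))
            segments = tuple(spans)
        else:
            spans = []
            for j, piece in enumerate(reversed(pieces)):
                if j:
                    emit(intron)
                spans.append(emit(str(Seq(piece).reverse_complement())))
            segments = tuple(reversed(spans))  # transcript order: descending genomic
        gene_models[name] = GeneModel(
            gene_id=name,
            seqid="mito",
            strand=strand,
            cds_segments=segments,
            category=default_gene_categories().get(name),
        )
    emit("".join(rng.choice(list("ACGT"), size=100)))
    genome = {"mito": "".join(contig_parts)}

    # truth table
    all_sites = [(name, int(pos)) for name in names for pos in site_positions[name]]
    wt = sample_wt_extents(len(all_sites), config.wt_bin_masses, rng)
    labels, mut = assign_effects(wt, config, rng)
    truth = pd.DataFrame(
        {
            "gene": [g for g, _ in all_sites],
            "position": [p for _, p in all_sites],
            "wt_extent": wt,
            "mut_extent": mut,
            "label": labels,
        }
    ).sort_values(["gene", "position"], ignore_index=True)
    return SimulatedDataset(
        config=config, genome=genome, gene_models=gene_models, cds_seqs=cds_seqs, truth=truth
    )


def simulate_counts(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw per-library site counts from the binomial observation model."""
    if rng is None:
        rng = np.random.default_rng(None if config.seed is None else config.seed + 1)
    eps = config.base_error_rate
    genotypes = default_genotype_map(config.libraries)
    rows = []
    for record in truth.itertuples(index=False):
        for lib in config.libraries:
            e = record.wt_extent if genotypes[lib] == "wt" else record.mut_extent
            d = int(rng.poisson(config.depth_mean))
            p_t = e * (1 - eps) + (1 - e) * eps
            p_other = eps / 2
            if d > 0:
                n_t, n_other, n_c = rng.multinomial(d, [p_t, p_other, 1.0 - p_t - p_other])
            else:
                n_t = n_other = n_c = 0
            rows.append((record.gene, record.position, lib, int(n_c), int(n_t), int(n_other)))
    return pd.DataFrame(rows, columns=["gene", "position", "library", "n_C", "n_T", "n_other"])


def simulate_reads(
    dataset: SimulatedDataset,
    out_dir: str | Path,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, Path], pd.DataFrame]:
    """Write per-library SAM files of amplicon reads tiling each gene.

    Per-read edit status is drawn independently per overlapped site at the
    library's true extent; minus-strand sites appear as genomic G->A in the
    reads.  Returns the SAM paths and the simulate-time per-site tally, which
    ``tally_site_counts`` on the SAM output must reproduce exactly.
    """
    config = dataset.config
    if rng is None:
        if config.seed is None:
            raise ConfigError("a seed is required to persist simulated reads")
        rng = np.random.default_rng(config.seed + 2)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contig = dataset.genome["mito"]
    read_len = config.read_length
    genotypes = default_genotype_map(config.libraries)

    # genomic coordinates of planted sites: (gpos 1-based) -> (gene, cds_pos, strand, wt, mut)
    site_info: dict[int, tuple[str, int, str, float, float]] = {}
    for record in dataset.truth.itertuples(index=False):
        gene = dataset.gene_models[record.gene]
        gpos = cds_to_genomic(gene, record.position)
        site_info[gpos] = (record.gene, record.position, gene.strand,
                           record.wt_extent, record.mut_extent)

    paths: dict[str, Path] = {}
    tally: dict[tuple[str, int, str], list[int]] = {}
    for lib in config.libraries:
        for _, (g, p, _, _, _) in site_info.items():
            tally[(g, p, lib)] = [0, 0]  # [n_C, n_T]

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "mito", "LN": len(contig)}]}
    for lib in config.libraries:
        is_wt = genotypes[lib] == "wt"
        path = out_dir / f"{lib}.sam"
        paths[lib] = path
        records = []
        serial = 0
        for gene in dataset.gene_models.values():
            gstart = min(s for s, _ in gene.cds_segments)
            gend = max(e for _, e in gene.cds_segments)
            span = gend - gstart + 1
            n_reads = int(round(config.depth_mean * span / read_len))
            lo = max(1, gstart - read_len + 1)
            hi = min(len(contig) - read_len + 1, gend)
            starts = np.sort(rng.integers(lo, hi + 1, size=n_reads))
            for start in starts:
                seq = list(contig[start - 1 : start + read_len - 1])
                for offset in range(read_len):
                    gpos = int(start) + offset
                    info = site_info.get(gpos)
                    if info is None:
                        continue
                    sgene, spos, strand, wt_e, mut_e = info
                    e = wt_e if is_wt else mut_e
                    edited = rng.random() < e
                    if edited:
                        seq[offset] = "T" if strand == "+" else "A"
                    tally[(sgene, spos, lib)][1 if edited else 0] += 1
                serial += 1
                records.append((int(start), f"{lib}.{serial}", "".join(seq)))
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for start, name, seq in records:
                a = pysam.AlignedSegment(out.header)
                a.query_name = name
                a.reference_id = 0
                a.reference_start = start - 1
                a.mapping_quality = 60
                a.cigarstring = f"{read_len}M"
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
                out.write(a)

    oracle = pd.DataFrame(
        [(g, p, lib, c, t, 0) for (g, p, lib), (c, t) in tally.items()],
        columns=["gene", "position", "library", "n_C", "n_T", "n_other"],
    ).sort_values(["gene", "position", "library"], ignore_index=True)
    return paths, oracle


def write_fixtures(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Persist FASTA, GFF3 and truth TSV (refuses without a seed)."""
    if dataset.config.seed is None:
        raise ConfigError("a seed is required to persist simulated fixtures")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta = out_dir / "genome.fasta"
    with fasta.open("w") as fh:
        for seqid, seq in dataset.genome.items():
            fh.write(f">{seqid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    gff = out_dir / "genes.gff3"
    with gff.open("w") as fh:
        fh.write("##gff-version 3\n")
        for gene in dataset.gene_models.values():
            phase = 0
            for j, (start, end) in enumerate(gene.cds_segments):
                fh.write(
                    "\t".join(
                        [gene.seqid, "orgedit-sim", "CDS", str(start), str(end), ".",
                         gene.strand, str(phase),
                         f"ID={gene.gene_id}.cds{j + 1};Parent={gene.gene_id}"]
                    )
                    + "\n"
                )
                phase = (3 - ((end - start + 1 - phase) % 3)) % 3
    truth_path = out_dir / "truth.tsv"
    dataset.truth.to_csv(truth_path, sep="\t", index=False, float_format="%.6g")
    return {"fasta": fasta, "gff": gff, "truth": truth_path}
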