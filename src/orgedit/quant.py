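"""Per-site, per-library tallies of edited/unedited reads and editing extent.

C-to-U editing is observed in cDNA sequencing as C->T at the edited position
(in CDS orientation; genomic G->A for minus-strand genes).  The editing
*extent* of a site in a library is ``n_T / (n_T + n_C)`` — reads carrying any
other base are tracked but excluded from the denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotation import GeneModel, cds_to_genomic, extract_cds
from .errors import ConfigError, ValidationError

#: Canonical column order of a site-counts table.
COUNT_COLUMNS = ["gene", "position", "library", "n_C", "n_T", "n_other"]

#: Extent bins reported for the wild-type editotype, high to low.
EXTENT_BIN_LABELS = ["100%", "99-100%", "90-99%", "50-89%", "<50%"]


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds for calling a position an editing site from WT libraries.

    min_depth: minimum pooled WT depth (n_C + n_T + n_other).
    min_extent_any_wt: extent floor that at least one WT library must reach.
    max_other_fraction: ceiling on the pooled non-C/non-T read fraction,
        guarding against misalignment and genomic SNVs.
    """

    min_depth: int = 50
    min_extent_any_wt: float = 0.05
    max_other_fraction: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_extent_any_wt", "max_other_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")


def editing_extent(n_C: int, n_T: int) -> float:
    """T/(T+C); NaN (not 0) when no informative reads cover the site."""
    if n_C < 0 or n_T < 0:
        raise ValidationError(f"negative counts: n_C={n_C}, n_T={n_T}")
    total = n_C + n_T
    if total == 0:
        return math.nan
    return n_T / total


def add_extent_column(counts: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of a counts table with an ``extent`` column appended."""
    out = counts.copy()
    informative = out["n_C"] + out["n_T"]
    with np.errstate(invalid="ignore"):
        out["extent"] = np.where(informative > 0, out["n_T"] / informative, np.nan)
    return out


def read_count_table(tsv_path: str | Path) -> pd.DataFrame:
    """Read a per-site read-count TSV.

    Expected tab-separated columns ``gene  position  library  n_C  n_T``
    (optional ``n_other``, default 0); '#' starts a comment line.
    """
    df = pd.read_csv(tsv_path, sep="\t", comment="#", dtype={"gene": str, "library": str})
    required = {"gene", "position", "library", "n_C", "n_T"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{tsv_path}: missing columns {sorted(missing)}")
    if "n_other" not in df.columns:
        df["n_other"] = 0
    df = df[COUNT_COLUMNS].copy()
    for col in ("position", "n_C", "n_T", "n_other"):
        values = pd.to_numeric(df[col], errors="raise")
        if (values < 0).any() or not (values == values.astype(int)).all():
            bad = df.loc[(values < 0) | (values != values.astype(int))].iloc[0]
            raise ValidationError(
                f"{tsv_path}: column {col} must be a non-negative integer "
                f"(offending row: {bad['gene']}-{bad['position']}/{bad['library']})"
            )
        df[col] = values.astype(int)
    dup = df.duplicated(subset=["gene", "position", "library"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise ValidationError(
            f"{tsv_path}: duplicate rows for site {first['gene']}-{first['position']} "
            f"in library {first['library']}"
        )
    return df.sort_values(["gene", "position", "library"], ignore_index=True)


def write_extent_table(counts: pd.DataFrame, path: str | Path) -> None:
    """Write the per-site extent TSV (gene, position, library, n_C, n_T, extent)."""
    out = add_extent_column(counts)
    out = out.sort_values(["gene", "position", "library"])
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _candidate_map(
    gene_models: Mapping[str, GeneModel], genome: Mapping[str, str]
) -> dict[tuple[str, int], tuple[str, int, str]]:
    """(seqid, genomic_pos 1-based) -> (gene, cds_pos, strand) for every CDS C."""
    candidates: dict[tuple[str, int], tuple[str, int, str]] = {}
    for gene in gene_models.values():
        cds = extract_cds(gene, genome)
        for i, base in enumerate(cds):
            if base == "C":
                gpos = cds_to_genomic(gene, i + 1)
                candidates[(gene.seqid, gpos)] = (gene.gene_id, i + 1, gene.strand)
    return candidates


def tally_site_counts(
    alignments: Mapping[str, str | Path],
    gene_models: Mapping[str, GeneModel],
    genome: Mapping[str, str],
    min_base_quality: int = 20,
) -> pd.DataFrame:
    """Tally C/T/other read support at every CDS-orientation C position.

    ``alignments`` maps library id -> SAM/BAM path.  Counts are strand
    corrected: on minus-strand genes the genomic pileup bases G/A are tallied
    as CDS-orientation C (unedited) / T (edited).  Bases below
    ``min_base_quality`` are excluded.  Duplicate reads are counted — these are
    amplicon libraries, where deduplication would distort extents.
    """
    candidates = _candidate_map(gene_models, genome)
    complement = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    rows = []
    for library, path in alignments.items():
        tallies = {key: [0, 0, 0] for key in candidates}  # [n_C, n_T, n_other]
        n_mapped = 0
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for ref in af.references:
                if ref not in genome:
                    raise ValidationError(
                        f"{path}: alignment reference {ref!r} absent from genome FASTA"
                    )
                if af.get_reference_length(ref) != len(genome[ref]):
                    raise ValidationError(
                        f"{path}: reference {ref!r} length mismatch with genome FASTA"
                    )
            for read in af.fetch(until_eof=True):
                if read.is_unmapped or read.is_secondary or read.is_supplementary:
                    continue
                n_mapped += 1
                seq = read.query_sequence
                quals = read.query_qualities
                ref_name = read.reference_name
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    key = (ref_name, rpos + 1)
                    site = candidates.get(key)
                    if site is None:
                        continue
                    if quals is not None and quals[qpos] < min_base_quality:
                        continue
                    base = seq[qpos].upper()
                    _, _, strand = site
                    cds_base = base if strand == "+" else complement.get(base, "N")
                    if cds_base == "C":
                        tallies[key][0] += 1
                    elif cds_base == "T":
                        tallies[key][1] += 1
                    else:
                        tallies[key][2] += 1
        if n_mapped == 0:
            warnings.warn(f"library {library!r}: no mapped reads in {path}", stacklevel=2)
        for key, (n_c, n_t, n_other) in tallies.items():
            gene, cds_pos, _ = candidates[key]
            rows.append((gene, cds_pos, library, n_c, n_t, n_other))
    df = pd.DataFrame(rows, columns=COUNT_COLUMNS)
    return df.sort_values(["gene", "position", "library"], ignore_index=True)


def pooled_extents(counts: pd.DataFrame, library_ids: Sequence[str]) -> pd.DataFrame:
    """Pooled extent per site over the given libraries.

    Pooling sums counts before dividing — (sum n_T)/(sum n_T + sum n_C) —
    rather than averaging per-library extents, so deeper libraries weigh more.
    Returns columns gene, position, n_C, n_T, n_other, extent.
    """
    sub = counts[counts["library"].isin(library_ids)]
    pooled = (
        sub.groupby(["gene", "position"], as_index=False)[["n_C", "n_T", "n_other"]]
        .sum()
        .sort_values(["gene", "position"], ignore_index=True)
    )
    return add_extent_column(pooled)


def discover_sites(
    counts: pd.DataFrame,
    wt_library_ids: Sequence[str],
    params: DetectionParams = DetectionParams(),
    cds_seqs: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Call editing sites from wild-type libraries.

    A site is called when pooled WT depth >= min_depth, at least one WT library
    reaches the extent floor, and the pooled other-base fraction stays below
    the ceiling.  When ``cds_seqs`` is provided, positions whose CDS reference
    base is not C are rejected.  Rows ordered by (gene, position).
    """
    if not wt_library_ids:
        raise ConfigError("discover_sites requires at least one WT library id")
    pooled = pooled_extents(counts, wt_library_ids)
    per_lib = add_extent_column(counts[counts["library"].isin(wt_library_ids)])
    max_lib_extent = (
        per_lib.groupby(["gene", "position"])["extent"].max().rename("max_wt_extent")
    )
    pooled = pooled.join(max_lib_extent, on=["gene", "position"])
    depth = pooled["n_C"] + pooled["n_T"] + pooled["n_other"]
    with np.errstate(invalid="ignore", divide="ignore"):
        other_frac = np.where(depth > 0, pooled["n_other"] / depth, 0.0)
    keep = (
        (depth >= params.min_depth)
        & (pooled["max_wt_extent"].fillna(0.0) >= params.min_extent_any_wt)
        & (other_frac <= params.max_other_fraction)
    )
    if cds_seqs is not None:
        ref_is_c = [
            gene in cds_seqs
            and pos <= len(cds_seqs[gene])
            and cds_seqs[gene][pos - 1] == "C"
            for gene, pos in zip(pooled["gene"], pooled["position"])
        ]
        keep &= np.asarray(ref_is_c)
    sites = pooled.loc[keep, ["gene", "position", "extent"]].rename(
        columns={"extent": "wt_extent"}
    )
    return sites.sort_values(["gene", "position"], ignore_index=True)


def bin_extent_distribution(extents: Iterable[float]) -> dict[str, int]:
    """Bin pooled-WT extents into {=100%, [99,100), [90,99), [50,90), [0,50)}.

    The label scheme is closed-open at every internal edge and "100%" means
    exactly 1.0; the five counts always sum to the number of sites.
    """
    bins = dict.fromkeys(EXTENT_BIN_LABELS, 0)
    for e in extents:
        if not 0.0 <= e <= 1.0:
            raise ValidationError(f"extent {e} outside [0, 1]")
        if e == 1.0:
            bins["100%"] += 1
        elif e >= 0.99:
            bins["99-100%"] += 1
        elif e >= 0.90:
            bins["90-99%"] += 1
        elif e >= 0.50:
            bins["50-89%"] += 1
        else:
            bins["<50%"] += 1
    return bins
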