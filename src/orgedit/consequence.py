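"""Codon- and protein-level consequences of editing vs non-editing.

Each edited C changes its codon from the genomic form (C kept) to the edited
form (C->T).  A codon can carry several editing sites; the full outcome table
enumerates every combination of per-site edit statuses — 2^k outcomes for k
sites — so that e.g. a CCA codon with sites at offsets 1 and 2 yields
Pro (none), Ser (first only), Leu (second only) and Leu (both).

Translation uses the standard genetic code (NCBI table 1), which plant
mitochondria use; the table id is configurable for portability.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .annotation import cds_position_to_codon
from .errors import CoordinateError, ValidationError

#: primary-class priority when several recoding flags apply
CLASS_PRIORITY = ("stop_gain", "stop_loss", "start_gain", "missense", "silent")


@dataclass(frozen=True)
class CodonEffect:
    gene_id: str
    codon_index: int
    sites_in_codon: tuple[tuple[int, int], ...]  # (cds_pos, codon_offset), ascending
    outcomes: Mapping[tuple[int, ...], tuple[str, str]]  # edit-status bits -> (codon, aa)
    recoding_class: str
    flags: frozenset[str]


def translate_codon(codon: str, table: int = 1) -> str:
    return str(Seq(codon).translate(table=table))


def _recoding_flags(
    aa_unedited: str, aa_edited: str, codon_edited: str, codon_index: int
) -> frozenset[str]:
    flags = set()
    if aa_edited == "*" and aa_unedited != "*":
        flags.add("stop_gain")
    if aa_unedited == "*" and aa_edited != "*":
        flags.add("stop_loss")
    if codon_index == 1 and codon_edited == "ATG" and aa_unedited != "M":
        flags.add("start_gain")
    if aa_unedited != aa_edited:
        flags.add("missense")
    if not flags:
        flags.add("silent")
    return frozenset(flags)


def primary_class(flags: frozenset[str]) -> str:
    for cls in CLASS_PRIORITY:
        if cls in flags:
            return cls
    raise ValidationError(f"unrecognised recoding flags {sorted(flags)}")


def codon_effect(
    cds_seq: str,
    codon_index: int,
    sites: Sequence[int],
    gene_id: str = "",
    table: int = 1,
) -> CodonEffect:
    """Enumerate all 2^k edit-status outcomes of a codon with k sites.

    ``sites`` are 1-based CDS positions, all lying inside the stated codon and
    all with reference base C.  Outcome keys are bit tuples, bit i belonging to
    site i in ascending CDS position (1 = edited).
    """
    if not sites:
        raise ValidationError("codon_effect requires at least one site")
    sites = sorted(sites)
    start = 3 * (codon_index - 1)  # 0-based
    codon = cds_seq[start : start + 3].upper()
    if len(codon) != 3:
        raise CoordinateError(f"codon {codon_index} beyond CDS of length {len(cds_seq)}")
    offsets = []
    for pos in sites:
        ref = cds_position_to_codon(pos, cds_seq)
        if ref.codon_index != codon_index:
            raise ValidationError(
                f"site {gene_id}-{pos} lies in codon {ref.codon_index}, not {codon_index}"
            )
        if cds_seq[pos - 1].upper() != "C":
            raise ValidationError(
                f"site {gene_id}-{pos}: reference base {cds_seq[pos - 1]!r} is not C"
            )
        offsets.append(ref.codon_offset)

    outcomes = {}
    for bits in product((0, 1), repeat=len(sites)):
        nt = list(codon)
        for bit, offset in zip(bits, offsets):
            if bit:
                nt[offset - 1] = "T"
        variant = "".join(nt)
        outcomes[bits] = (variant, translate_codon(variant, table))

    aa_unedited = outcomes[(0,) * len(sites)][1]
    codon_edited, aa_edited = outcomes[(1,) * len(sites)]
    flags = _recoding_flags(aa_unedited, aa_edited, codon_edited, codon_index)
    return CodonEffect(
        gene_id=gene_id,
        codon_index=codon_index,
        sites_in_codon=tuple(zip(sites, offsets)),
        outcomes=outcomes,
        recoding_class=primary_class(flags),
        flags=flags,
    )


def annotate_sites(
    sites: Iterable[tuple[str, int]],
    cds_seqs: Mapping[str, str],
    table: int = 1,
) -> pd.DataFrame:
    """Per-site consequence table.

    One row per (gene, cds_pos): codon index/offset, unedited and fully-edited
    codon and amino acid, and the primary recoding class.  "Edited" means all
    sites sharing the codon edited; partial combinations live in the
    :class:`CodonEffect` detail, obtainable via :func:`codon_effect`.
    """
    site_list = sorted(set(sites))
    by_codon: dict[tuple[str, int], list[int]] = {}
    for gene, pos in site_list:
        if gene not in cds_seqs:
            raise ValidationError(f"no CDS sequence for gene {gene!r}")
        if pos > len(cds_seqs[gene]) or pos < 1:
            raise CoordinateError(
                f"site {gene}-{pos} beyond CDS length {len(cds_seqs[gene])}"
            )
        ref = cds_position_to_codon(pos, cds_seqs[gene])
        by_codon.setdefault((gene, ref.codon_index), []).append(pos)

    effects = {
        key: codon_effect(cds_seqs[key[0]], key[1], positions, gene_id=key[0], table=table)
        for key, positions in by_codon.items()
    }
    rows = []
    for gene, pos in site_list:
        ref = cds_position_to_codon(pos, cds_seqs[gene])
        eff = effects[(gene, ref.codon_index)]
        k = len(eff.sites_in_codon)
        codon_un, aa_un = eff.outcomes[(0,) * k]
        codon_ed, aa_ed = eff.outcomes[(1,) * k]
        rows.append(
            (gene, pos, ref.codon_index, ref.codon_offset,
             codon_un, codon_ed, aa_un, aa_ed, eff.recoding_class)
        )
    return pd.DataFrame(
        rows,
        columns=["gene", "position", "codon_index", "codon_offset",
                 "codon_unedited", "codon_edited", "aa_unedited", "aa_edited", "class"],
    )


def write_consequences(consequences: pd.DataFrame, path: str | Path) -> None:
    consequences.sort_values(["gene", "position"]).to_csv(path, sep="\t", index=False)
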