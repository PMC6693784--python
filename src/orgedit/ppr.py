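"""PPR combinatorial-code matching against upstream windows of editing sites.

PLS-class PPR editing factors bind the RNA immediately upstream of the target
C, one array motif per nucleotide.  Nucleotide preference of a motif is read
from the combinatorial code: the residue at position 6 of that motif together
with the residue at position 1' of the *next* motif.  For an array of k
nucleotide-binding motifs (P/L/S variants; E1/E2/DYW are excluded) the array
spans window positions -(k+3)..-4 relative to the edited C (position 0), the
C-terminal-most motif pairing with -4.  An 11-motif array therefore covers
-14..-4.

Scoring is deliberately simple and fully config-exposed: a window position
scores 1 when its nucleotide is the top-weight prediction of the motif's
(aa6, aa1') pair, 0.5 when it is a lower-weight prediction, 0 otherwise;
positions whose pair is absent from the code table make no prediction and are
dropped from the denominator.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .errors import CoordinateError, ValidationError

AA_LETTERS = set("ACDEFGHIKLMNPQRSTVWY")
TERMINAL_TYPES = {"E1", "E2", "DYW"}
MOTIF_TYPES = {"P", "L", "S", "P1", "P2", "L1", "L2", "S1", "S2"} | TERMINAL_TYPES

MATCH, PARTIAL, MISMATCH, NO_PREDICTION = "match", "partial", "mismatch", "no_prediction"
_LABEL_CHAR = {MATCH: "M", PARTIAL: "p", MISMATCH: "x", NO_PREDICTION: "."}


@dataclass(frozen=True)
class PPRMotif:
    """One repeat of the array, N->C indexed from 1.

    ``aa1prime`` is the position-1' residue of the *following* motif — the
    partner residue of this motif's code pair — and may be absent for the
    last motif of the array.
    """

    index: int
    motif_type: str
    aa6: str | None
    aa1prime: str | None

    def __post_init__(self) -> None:
        if self.motif_type not in MOTIF_TYPES:
            raise ValidationError(f"motif {self.index}: unknown type {self.motif_type!r}")
        for name in ("aa6", "aa1prime"):
            aa = getattr(self, name)
            if aa is not None and aa not in AA_LETTERS:
                raise ValidationError(f"motif {self.index}: invalid residue {aa!r} for {name}")


@dataclass(frozen=True)
class PPRProtein:
    protein_id: str
    motifs: tuple[PPRMotif, ...]

    @property
    def array_motifs(self) -> tuple[PPRMotif, ...]:
        """The nucleotide-binding subset: every motif except E1/E2/DYW."""
        return tuple(m for m in self.motifs if m.motif_type not in TERMINAL_TYPES)


@dataclass(frozen=True)
class SiteMatch:
    site_id: tuple[str, int]
    window: str
    labels: tuple[str, ...]
    score: float

    @property
    def label_string(self) -> str:
        """Compact per-position label string (M = match, p = partial, x = mismatch, . = no prediction)."""
        return "".join(_LABEL_CHAR[l] for l in self.labels)


class CodeTable:
    """(aa6, aa1') -> ranked nucleotide preferences with weights in (0, 1].

    Weights per pair must sum to <= 1; U is normalised to T (cDNA alphabet).
    Unknown pairs predict nothing.
    """

    def __init__(self, table: Mapping[tuple[str, str], Mapping[str, float]]):
        self._table: dict[tuple[str, str], dict[str, float]] = {}
        for pair, prefs in table.items():
            clean = {}
            for nt, w in prefs.items():
                nt = nt.upper().replace("U", "T")
                if nt not in set("ACGT"):
                    raise ValidationError(f"code table {pair}: invalid nucleotide {nt!r}")
                if not 0.0 < w <= 1.0:
                    raise ValidationError(f"code table {pair}: weight {w} outside (0, 1]")
                clean[nt] = w
            if sum(clean.values()) > 1.0 + 1e-9:
                raise ValidationError(f"code table {pair}: weights sum above 1")
            self._table[tuple(pair)] = clean

    def preferences(self, aa6: str | None, aa1prime: str | None) -> dict[str, float]:
        if aa6 is None or aa1prime is None:
            return {}
        return self._table.get((aa6, aa1prime), {})

    def top(self, aa6: str | None, aa1prime: str | None) -> str | None:
        prefs = self.preferences(aa6, aa1prime)
        if not prefs:
            return None
        # deterministic tie-break: highest weight, then alphabetical nucleotide
        return min(prefs, key=lambda nt: (-prefs[nt], nt))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CodeTable":
        raw = yaml.safe_load(Path(path).read_text())
        return cls._from_mapping(raw["code"])

    @classmethod
    def default(cls) -> "CodeTable":
        """The shipped code table transcribed from the published (6, 1') code."""
        from importlib.resources import files

        raw = yaml.safe_load(files("orgedit.data").joinpath("ppr_code.yaml").read_text())
        return cls._from_mapping(raw["code"])

    @classmethod
    def _from_mapping(cls, raw: Mapping[str, Mapping[str, float]]) -> "CodeTable":
        table = {}
        for key, prefs in raw.items():
            aa6, aa1p = key.split("/")
            table[(aa6, aa1p)] = dict(prefs)
        return cls(table)


def load_ppr(motif_table_path: str | Path, protein_id: str | None = None) -> PPRProtein:
    """Load a motif table TSV with columns ``index  type  aa6  aa1prime``.

    '-' or empty marks an absent residue.  Motif boundaries and residues are
    inputs (taken from published motif definitions), never computed here.
    """
    path = Path(motif_table_path)
    motifs = []
    with path.open() as fh:
        reader = csv.DictReader(
            (line for line in fh if not line.startswith("#")), delimiter="\t"
        )
        for row in reader:
            aa6 = (row.get("aa6") or "").strip() or None
            aa1p = (row.get("aa1prime") or "").strip() or None
            motifs.append(
                PPRMotif(
                    index=int(row["index"]),
                    motif_type=row["type"].strip(),
                    aa6=None if aa6 == "-" else aa6,
                    aa1prime=None if aa1p == "-" else aa1p,
                )
            )
    if not motifs:
        raise ValidationError(f"{path}: empty motif table")
    motifs.sort(key=lambda m: m.index)
    protein = PPRProtein(protein_id=protein_id or path.stem, motifs=tuple(motifs))
    array = protein.array_motifs
    if array and array[-1].aa1prime is None:
        warnings.warn(
            f"{protein.protein_id}: last array motif has no aa1' partner; "
            "its position will make no prediction",
            stacklevel=2,
        )
    return protein


def extract_window(seq: str, site_pos: int, array_length: int = 11) -> str:
    """The 5'->3' upstream window -(k+3)..-4 for a site at 1-based ``site_pos``.

    Position -4 is the 3'-most nucleotide of the window; -1..-3 are skipped.
    For the standard 11-motif array this is the -14..-4 window.
    """
    if array_length < 1:
        raise ValidationError("array_length must be >= 1")
    start = site_pos - (array_length + 3)  # 1-based
    if start < 1:
        raise CoordinateError(
            f"site at position {site_pos} has fewer than {array_length + 3} nt upstream"
        )
    return seq[start - 1 : site_pos - 4].upper()


def score_alignment(
    ppr: PPRProtein,
    window: str,
    code: CodeTable,
    motif_type_mask: Iterable[str] | None = None,
    site_id: tuple[str, int] = ("", 0),
    partial_weight: float = 0.5,
) -> SiteMatch:
    """Align the motif array against an upstream window and score it.

    Motif i (N->C, i = 1..k) is paired with window position -(4 + k - i),
    i.e. window character i-1.  ``motif_type_mask`` optionally restricts
    prediction to the listed motif types (some published codes exclude L
    motifs); masked positions count as no_prediction.
    """
    array = ppr.array_motifs
    if len(window) != len(array):
        raise ValidationError(
            f"window length {len(window)} != array motif count {len(array)}"
        )
    mask = set(motif_type_mask) if motif_type_mask is not None else None
    labels = []
    points = 0.0
    predicted = 0
    for motif, nt in zip(array, window.upper()):
        if mask is not None and motif.motif_type not in mask:
            labels.append(NO_PREDICTION)
            continue
        prefs = code.preferences(motif.aa6, motif.aa1prime)
        if not prefs:
            labels.append(NO_PREDICTION)
            continue
        predicted += 1
        if nt == code.top(motif.aa6, motif.aa1prime):
            labels.append(MATCH)
            points += 1.0
        elif nt in prefs:
            labels.append(PARTIAL)
            points += partial_weight
        else:
            labels.append(MISMATCH)
    score = points / predicted if predicted else 0.0
    return SiteMatch(site_id=site_id, window=window, labels=tuple(labels), score=score)


def rank_candidate_sites(
    ppr: PPRProtein,
    site_windows: Iterable[tuple[tuple[str, int], str]],
    code: CodeTable,
    motif_type_mask: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score all candidate sites and sort by descending score, ties by (gene, position)."""
    matches = [
        score_alignment(ppr, window, code, motif_type_mask, site_id=site_id)
        for site_id, window in site_windows
    ]
    df = pd.DataFrame(
        [
            (m.site_id[0], m.site_id[1], m.window, m.label_string, m.score)
            for m in matches
        ],
        columns=["gene", "position", "window", "labels", "score"],
    )
    return df.sort_values(
        ["score", "gene", "position"], ascending=[False, True, True], ignore_index=True
    )
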