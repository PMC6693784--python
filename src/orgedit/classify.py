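"""Differential editing classification between mutant and wild-type libraries.

The design is 2 WT + 2 mutant amplicon libraries.  A site is *decreased*
(resp. *increased*) when the extent difference, in percentage points, is
<= -10 (resp. >= +10) for **all four** pairwise library comparisons
(mut1-wt1, mut1-wt2, mut2-wt1, mut2-wt2).  *Abolished* additionally requires
no detectable editing in the pooled mutant libraries.  The rule is a
deterministic threshold, not a statistical test; an optional per-pair Fisher
exact test is available for annotation but never alters the label.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError
from .quant import add_extent_column, editing_extent

LABELS = ("abolished", "decreased", "increased", "unaffected")
NOT_EVALUABLE = "not_evaluable"

#: classification table column order
CLASS_COLUMNS = [
    "gene", "position",
    "wt1_extent", "wt2_extent", "mut1_extent", "mut2_extent",
    "d11", "d12", "d21", "d22", "label",
]


@dataclass(frozen=True)
class ClassificationParams:
    """Thresholds of the differential rule.

    delta_threshold: percentage points every pairwise comparison must exceed.
    abolished_max_mutant_T: pooled mutant edited-read ceiling for abolition.
    abolished_max_mutant_extent: alternative abolition criterion tolerating
        rare error reads at high depth (0.005 = 0.5% pooled mutant extent).
    min_informative_depth: per-library n_C + n_T floor below which a site is
        not evaluable rather than classified from noise.
    """

    delta_threshold: float = 10.0
    abolished_max_mutant_T: int = 0
    abolished_max_mutant_extent: float = 0.005
    min_informative_depth: int = 20

    def __post_init__(self) -> None:
        if self.delta_threshold <= 0:
            raise ValidationError("delta_threshold must be positive")
        if not 0.0 <= self.abolished_max_mutant_extent <= 1.0:
            raise ValidationError("abolished_max_mutant_extent must lie in [0, 1]")


@dataclass(frozen=True)
class SiteClassification:
    gene_id: str
    cds_pos: int
    deltas: tuple[float, float, float, float] | None
    label: str


def pairwise_deltas(
    mut_extents: Sequence[float], wt_extents: Sequence[float]
) -> tuple[float, float, float, float]:
    """All four mutant-minus-WT extent differences in percentage points.

    Order is fixed: (m1-w1, m1-w2, m2-w1, m2-w2).
    """
    if len(mut_extents) != 2 or len(wt_extents) != 2:
        raise ConfigError("pairwise_deltas expects exactly 2 mutant and 2 WT extents")
    for e in (*mut_extents, *wt_extents):
        if e != e:  # NaN
            raise ValidationError("NA extent: site is not evaluable, no deltas defined")
    return tuple(100.0 * (m - w) for m in mut_extents for w in wt_extents)  # type: ignore[return-value]


def classify_site(
    wt_counts: Sequence[tuple[int, int]],
    mut_counts: Sequence[tuple[int, int]],
    params: ClassificationParams = ClassificationParams(),
    gene_id: str = "",
    cds_pos: int = 0,
) -> SiteClassification:
    """Label one site from (n_C, n_T) pairs of 2 WT and 2 mutant libraries."""
    if len(wt_counts) != 2 or len(mut_counts) != 2:
        raise ConfigError("classify_site expects exactly 2 WT and 2 mutant libraries")
    depths = [c + t for c, t in (*wt_counts, *mut_counts)]
    if any(d < params.min_informative_depth for d in depths):
        return SiteClassification(gene_id, cds_pos, None, NOT_EVALUABLE)
    wt_extents = [editing_extent(c, t) for c, t in wt_counts]
    mut_extents = [editing_extent(c, t) for c, t in mut_counts]
    deltas = pairwise_deltas(mut_extents, wt_extents)
    # tolerance keeps counts landing exactly on the threshold (e.g. 40% vs
    # 50%) inside the rule despite float rounding of the extent ratios
    t = params.delta_threshold - 1e-9
    if all(d <= -t for d in deltas):
        pooled_t = sum(nt for _, nt in mut_counts)
        pooled_c = sum(nc for nc, _ in mut_counts)
        pooled_extent = editing_extent(pooled_c, pooled_t)
        if pooled_t <= params.abolished_max_mutant_T or (
            pooled_extent == pooled_extent
            and pooled_extent <= params.abolished_max_mutant_extent
        ):
            label = "abolished"
        else:
            label = "decreased"
    elif all(d >= t for d in deltas):
        label = "increased"
    else:
        label = "unaffected"
    return SiteClassification(gene_id, cds_pos, deltas, label)


def fisher_pairwise(
    wt_counts: Sequence[tuple[int, int]], mut_counts: Sequence[tuple[int, int]]
) -> tuple[float, float, float, float]:
    """Fisher exact p-value per library pair (annotation only, never the label)."""
    ps = []
    for mc, mt in mut_counts:
        for wc, wt in wt_counts:
            ps.append(stats.fisher_exact([[mt, mc], [wt, wc]])[1])
    return tuple(ps)  # type: ignore[return-value]


def classify_table(
    counts: pd.DataFrame,
    genotype_map: Mapping[str, str],
    params: ClassificationParams = ClassificationParams(),
) -> pd.DataFrame:
    """Classify every site of a counts table.

    ``genotype_map`` maps library id -> 'wt' or 'mutant' and must contain
    exactly two of each.  Library pairing is by sorted library id, so labels
    are invariant under swapping the two WT (or two mutant) libraries.
    """
    wt_libs = sorted(k for k, v in genotype_map.items() if v == "wt")
    mut_libs = sorted(k for k, v in genotype_map.items() if v == "mutant")
    if len(wt_libs) != 2 or len(mut_libs) != 2:
        raise ConfigError(
            f"need exactly 2 WT and 2 mutant libraries, got {len(wt_libs)} WT "
            f"and {len(mut_libs)} mutant"
        )
    unknown = set(counts["library"]) - set(genotype_map)
    if unknown:
        raise ConfigError(f"libraries without genotype: {sorted(unknown)}")

    wide = add_extent_column(counts).pivot_table(
        index=["gene", "position"],
        columns="library",
        values=["n_C", "n_T", "extent"],
        aggfunc="first",
    )
    rows = []
    for (gene, pos), row in wide.iterrows():
        wt_ct = [
            (int(row.get(("n_C", lib), 0) or 0), int(row.get(("n_T", lib), 0) or 0))
            for lib in wt_libs
        ]
        mut_ct = [
            (int(row.get(("n_C", lib), 0) or 0), int(row.get(("n_T", lib), 0) or 0))
            for lib in mut_libs
        ]
        result = classify_site(wt_ct, mut_ct, params, gene_id=gene, cds_pos=pos)
        extents = [editing_extent(c, t) for c, t in (*wt_ct, *mut_ct)]
        deltas = result.deltas or (float("nan"),) * 4
        rows.append((gene, pos, *extents, *deltas, result.label))
    out = pd.DataFrame(rows, columns=CLASS_COLUMNS)
    return out.sort_values(["gene", "position"], ignore_index=True)


def summarize_classification(
    classified: pd.DataFrame,
    gene_categories: Mapping[str, str],
    category_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Category-by-label summary with a Total row.

    not_evaluable sites are excluded from the table (they are listed
    separately by the pipeline); genes without a category are reported under
    'uncategorized', never dropped.
    """
    evaluable = classified[classified["label"].isin(LABELS)]
    cats = evaluable["gene"].map(lambda g: gene_categories.get(g, "uncategorized"))
    table = (
        pd.crosstab(cats, evaluable["label"])
        .reindex(columns=list(LABELS), fill_value=0)
        .astype(int)
    )
    if category_order is None:
        category_order = sorted(table.index)
    order = [c for c in category_order if c in table.index]
    order += [c for c in table.index if c not in order]
    table = table.reindex(order, fill_value=0)
    table["total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "category"
    return table


def overlap_sites(run_a: pd.DataFrame, run_b: pd.DataFrame) -> pd.DataFrame:
    """Affected sites (abolished or decreased) shared by two classification runs.

    Both runs must cover the same site universe; the asymmetric difference is
    reported otherwise.  Extents from both runs are attached (suffixes _a/_b).
    """
    key = ["gene", "position"]
    universe_a = set(map(tuple, run_a[key].itertuples(index=False)))
    universe_b = set(map(tuple, run_b[key].itertuples(index=False)))
    if universe_a != universe_b:
        asym = sorted(universe_a ^ universe_b)
        raise ValidationError(f"site universes differ; asymmetric sites: {asym[:20]}")
    affected = {"abolished", "decreased"}
    a = run_a[run_a["label"].isin(affected)]
    b = run_b[run_b["label"].isin(affected)]
    merged = a.merge(b, on=key, suffixes=("_a", "_b"))
    return merged.sort_values(key, ignore_index=True)


def write_classification(classified: pd.DataFrame, path: str | Path) -> None:
    classified.sort_values(["gene", "position"]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
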