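"""End-to-end orchestration: tally -> extents -> classify -> consequences -> summary.

A run is described by a config mapping (usually loaded from YAML):

.. code-block:: yaml

    genome: genome.fasta
    gff: genes.gff3
    libraries:            # either SAM/BAM per library ...
      WT-1:  {genotype: wt,     alignments: wt1.sam}
      WT-2:  {genotype: wt,     alignments: wt2.sam}
      mut-1: {genotype: mutant, alignments: mut1.sam}
      mut-2: {genotype: mutant, alignments: mut2.sam}
    counts: counts.tsv    # ... or one pre-tallied counts TSV
    params:
      detection: {min_depth: 50}
      classification: {delta_threshold: 10}

Outputs are deterministic: every table is sorted by (gene, position) and a
manifest records input hashes, parameters and package version, so a rerun
with identical inputs is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .annotation import default_category_order, default_gene_categories, extract_cds, load_gene_models
from .classify import (
    ClassificationParams,
    classify_table,
    summarize_classification,
    write_classification,
)
from .consequence import annotate_sites, write_consequences
from .errors import ConfigError
from .quant import DetectionParams, read_count_table, tally_site_counts, write_extent_table


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def load_run_config(path: str | Path) -> dict[str, Any]:
    config = yaml.safe_load(Path(path).read_text())
    if not isinstance(config, dict):
        raise ConfigError(f"{path}: run config must be a mapping")
    return config


def _genotype_map(config: Mapping[str, Any]) -> dict[str, str]:
    libraries = config.get("libraries")
    if not libraries:
        raise ConfigError("config must define 'libraries' with genotypes")
    gmap = {}
    for lib, entry in libraries.items():
        genotype = entry.get("genotype") if isinstance(entry, Mapping) else entry
        if genotype not in {"wt", "mutant"}:
            raise ConfigError(f"library {lib!r}: genotype must be 'wt' or 'mutant'")
        gmap[lib] = genotype
    n_wt = sum(1 for g in gmap.values() if g == "wt")
    if n_wt != 2 or len(gmap) - n_wt != 2:
        raise ConfigError("the paper-mode classification needs exactly 2 WT + 2 mutant libraries")
    return gmap


def run_pipeline(config: Mapping[str, Any], out_dir: str | Path) -> dict[str, Any]:
    """Run all stages and write the result bundle under ``out_dir``.

    Returns the in-memory results: counts, classification, consequences,
    summary and the manifest dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    genotype_map = _genotype_map(config)  # validate config before any compute
    params_cfg = config.get("params", {})
    det = DetectionParams(**params_cfg.get("detection", {}))
    cls = ClassificationParams(**params_cfg.get("classification", {}))

    input_hashes: dict[str, str] = {}
    gene_models = None
    cds_seqs: dict[str, str] | None = None
    categories = default_gene_categories()
    if config.get("genome") and config.get("gff"):
        gene_models, genome = load_gene_models(config["genome"], config["gff"])
        cds_seqs = {g: extract_cds(m, genome) for g, m in gene_models.items()}
        input_hashes["genome"] = _sha256(config["genome"])
        input_hashes["gff"] = _sha256(config["gff"])
        categories = {g: m.category or "uncategorized" for g, m in gene_models.items()}

    if config.get("counts"):
        counts = read_count_table(config["counts"])
        input_hashes["counts"] = _sha256(config["counts"])
    else:
        if gene_models is None:
            raise ConfigError("alignment input requires 'genome' and 'gff'")
        alignments = {}
        for lib, entry in config["libraries"].items():
            if not isinstance(entry, Mapping) or "alignments" not in entry:
                raise ConfigError(f"library {lib!r}: no 'alignments' path and no 'counts' table")
            alignments[lib] = entry["alignments"]
            input_hashes[f"alignments/{lib}"] = _sha256(entry["alignments"])
        counts = tally_site_counts(
            alignments, gene_models, genome,
            min_base_quality=params_cfg.get("min_base_quality", 20),
        )

    write_extent_table(counts, out_dir / "extents.tsv")
    classified = classify_table(counts, genotype_map, cls)
    write_classification(classified, out_dir / "classification.tsv")

    consequences = None
    if cds_seqs is not None:
        sites = [(r.gene, int(r.position)) for r in classified.itertuples(index=False)
                 if r.gene in cds_seqs]
        consequences = annotate_sites(sites, cds_seqs)
        write_consequences(consequences, out_dir / "consequences.tsv")

    summary = summarize_classification(classified, categories, default_category_order())
    summary.to_csv(out_dir / "summary.tsv", sep="\t")
    (out_dir / "summary.json").write_text(
        json.dumps({str(k): v for k, v in summary.to_dict(orient="index").items()},
                   indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "table1.txt").write_text(report_table1(summary))

    manifest = {
        "version": __version__,
        "inputs": dict(sorted(input_hashes.items())),
        "parameters": {
            "detection": asdict(det),
            "classification": asdict(cls),
            "genotypes": dict(sorted(genotype_map.items())),
        },
        "outputs": {
            name: _sha256(out_dir / name)
            for name in sorted(p.name for p in out_dir.iterdir() if p.name != "manifest.json")
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "counts": counts,
        "classification": classified,
        "consequences": consequences,
        "summary": summary,
        "manifest": manifest,
    }


def report_table1(summary: pd.DataFrame) -> str:
    """Human-readable category-by-label table, Total row last."""
    header = ["category", *map(str, summary.columns)]
    body = [[str(idx), *(str(int(v)) for v in row)] for idx, row in summary.iterrows()]
    widths = [max(len(row[i]) for row in [header, *body]) for i in range(len(header))]
    lines = ["  ".join(h.ljust(w) for h, w in zip(header, widths))]
    for row in body:
        lines.append(
            "  ".join(
                cell.ljust(w) if i == 0 else cell.rjust(w)
                for i, (cell, w) in enumerate(zip(row, widths))
            )
        )
    return "\n".join(lines) + "\n"
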