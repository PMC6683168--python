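"""End-to-end analysis orchestration.

score -> select high/low expression groups -> DEP screen -> element
content comparison (O with C control) -> chromosome localization ->
gene-set over-representation, with per-stage TSV outputs, a JSON summary
and a provenance log (config hash, seed, versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import GroupComparisonResult, compare_groups
from .dep import screen_deps
from .elements import element_content_many
from .enrich import enrichment_table, hypergeom_enrich, localize
from .io import (
    ProteinRecord,
    StainingObservation,
    read_expression_table,
    read_fasta,
    read_gene_chromosomes,
    read_gene_chromosomes_gff3,
    read_gmt,
)
from .scoring import ScoreMapping, average_scores, build_expression_matrix, select_group

logger = logging.getLogger("stoichioprot")


@dataclass
class RunConfig:
    """Serializable configuration of one pipeline run."""

    fasta: str = ""
    expression: str = ""
    annotation: str = ""  # TSV (gene<TAB>chromosome) or GFF3 (by suffix)
    gene_sets: str = ""  # GMT; optional, empty disables enrichment
    outdir: str = "results"
    case_prefix: str = "case"
    control_prefix: str = "control"
    top_fractions: tuple[float, ...] = (0.03, 0.05)
    threshold_high: float = 12.0
    threshold_low: float = 0.1
    alpha: float = 0.05
    max_q: float = 0.01
    lfc: float = 1.0
    pseudocount: float = 0.1
    element: str = "O"
    control_element: str = "C"
    seed: int = 0
    score_mapping_yaml: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _comparison_rows(results: list[GroupComparisonResult], comparison: str) -> list[dict]:
    return [
        {
            "comparison": comparison,
            "element": r.element,
            "group_a": r.group_a,
            "group_b": r.group_b,
            "n_a": r.n_a,
            "n_b": r.n_b,
            "mean_a": r.mean_a,
            "mean_b": r.mean_b,
            "percent_difference": r.percent_difference,
            "u_statistic": r.u_statistic,
            "p_value": r.p_value,
        }
        for r in results
    ]


def run_all(
    config: RunConfig,
    records: list[ProteinRecord] | None = None,
    observations: list[StainingObservation] | None = None,
    annotation: dict[str, str] | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    write_outputs: bool = True,
) -> dict:
    """Execute every stage and return the run report.

    Inputs may be passed in-memory (the synthetic generator's objects) or
    read from the paths in ``config``.  Any stage failure raises
    :class:`StageError` naming the stage.
    """
    outdir = Path(config.outdir)
    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    # ---- load ----
    try:
        if records is None:
            records = read_fasta(config.fasta)
        if observations is None:
            observations = read_expression_table(config.expression)
        if annotation is None and config.annotation:
            if config.annotation.endswith((".gff", ".gff3")):
                annotation = read_gene_chromosomes_gff3(config.annotation)
            else:
                annotation = read_gene_chromosomes(config.annotation)
        if gene_sets is None and config.gene_sets:
            gene_sets = read_gmt(config.gene_sets)
    except Exception as exc:  # noqa: BLE001 - stage context is the contract
        raise StageError("load", str(exc)) from exc

    mapping = (
        ScoreMapping.from_yaml(config.score_mapping_yaml)
        if config.score_mapping_yaml
        else ScoreMapping()
    )

    # ---- score ----
    try:
        matrix = build_expression_matrix(observations, mapping)
        samples = list(matrix.columns)
        case_samples = [s for s in samples if s.startswith(config.case_prefix)]
        control_samples = [s for s in samples if s.startswith(config.control_prefix)]
        if not case_samples or not control_samples:
            raise ValueError(
                f"could not split samples into case/control with prefixes "
                f"{config.case_prefix!r}/{config.control_prefix!r}"
            )
        case_means = average_scores(matrix, case_samples)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    # ---- element profiles ----
    try:
        by_id = {r.protein_id: r for r in records}
        scored_ids = [pid for pid in case_means.index if pid in by_id]
        elements = [config.element]
        if config.control_element and config.control_element != config.element:
            elements.append(config.control_element)
        contents: dict[str, dict[str, float]] = {pid: {} for pid in by_id}
        all_ids = list(by_id)
        for elem in elements:
            vals = element_content_many((by_id[p].sequence for p in all_ids), elem)
            for pid, v in zip(all_ids, vals):
                contents[pid][elem] = float(v)
    except Exception as exc:
        raise StageError("element_content", str(exc)) from exc

    # ---- select high/low groups & compare ----
    comparison_rows: list[dict] = []
    try:
        selections = {}
        for f in config.top_fractions:
            selections[f"top_{f:g}"] = select_group(case_means, "top_fraction", f)
            selections[f"bottom_{f:g}"] = select_group(case_means, "bottom_fraction", f)
        selections["threshold_high"] = select_group(
            case_means, "threshold_high", config.threshold_high
        )
        selections["threshold_low"] = select_group(
            case_means, "threshold_low", config.threshold_low
        )
        for f in config.top_fractions:
            high = selections[f"top_{f:g}"].members & set(contents)
            low = selections[f"bottom_{f:g}"].members & set(contents) - high
            res = compare_groups(
                contents, high, low, config.element,
                label_a="high", label_b="low",
                control_element=config.control_element,
            )
            comparison_rows += _comparison_rows(res, f"high_vs_low_top{f:g}")
        high_t = selections["threshold_high"].members & set(contents)
        low_t = (selections["threshold_low"].members & set(contents)) - high_t
        if high_t and low_t:
            res = compare_groups(
                contents, high_t, low_t, config.element,
                label_a="high", label_b="low",
                control_element=config.control_element,
            )
            comparison_rows += _comparison_rows(res, "high_vs_low_threshold")
    except Exception as exc:
        raise StageError("select_compare", str(exc)) from exc

    # ---- DEP screen ----
    try:
        dep_table = screen_deps(
            matrix,
            case_samples,
            control_samples,
            alpha=config.alpha,
            max_q=config.max_q,
            lfc=config.lfc,
            pseudocount=config.pseudocount,
        )
        up_ids = set(dep_table.index[dep_table["call"] == "up"])
        down_ids = set(dep_table.index[dep_table["call"] == "down"])
        if up_ids and down_ids:
            res = compare_groups(
                contents, up_ids, down_ids, config.element,
                label_a="up", label_b="down",
                control_element=config.control_element,
            )
            comparison_rows += _comparison_rows(res, "up_vs_down")
    except Exception as exc:
        raise StageError("dep_screen", str(exc)) from exc

    # ---- localization ----
    chrom_table = None
    if annotation:
        try:
            genes_by_dir = {
                "up": {by_id[p].gene_symbol for p in up_ids if by_id[p].gene_symbol},
                "down": {by_id[p].gene_symbol for p in down_ids if by_id[p].gene_symbol},
            }
            chrom_table = localize(genes_by_dir, annotation)
        except Exception as exc:
            raise StageError("localize", str(exc)) from exc

    # ---- enrichment ----
    enrich_tables = {}
    if gene_sets:
        try:
            universe = {
                by_id[p].gene_symbol for p in scored_ids if by_id[p].gene_symbol
            }
            for direction, ids in (("up", up_ids), ("down", down_ids)):
                genes = {by_id[p].gene_symbol for p in ids if by_id[p].gene_symbol}
                if genes:
                    enrich_tables[direction] = hypergeom_enrich(
                        genes, gene_sets, universe
                    )
        except Exception as exc:
            raise StageError("enrich", str(exc)) from exc

    # ---- report ----
    comparisons = pd.DataFrame(comparison_rows)
    report = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_proteins": len(records),
        "n_scored": int(len(case_means)),
        "n_case_samples": len(case_samples),
        "n_control_samples": len(control_samples),
        "n_up": len(up_ids),
        "n_down": len(down_ids),
        "n_dep": len(up_ids) + len(down_ids),
        "comparisons": comparison_rows,
        "mean_content_all": {
            elem: float(pd.Series({p: contents[p][elem] for p in scored_ids}).mean())
            for elem in elements
        },
    }
    if chrom_table is not None:
        report["chromosome_counts"] = {
            c: {d: int(chrom_table.loc[c, d]) for d in chrom_table.columns}
            for c in chrom_table.index
        }
    if enrich_tables:
        report["top_enrichment"] = {
            d: {
                "set_name": res[0].set_name,
                "p_value": res[0].p_value,
                "q_value": res[0].q_value,
            }
            for d, res in enrich_tables.items()
            if res
        }

    if write_outputs:
        matrix.to_csv(outdir / "scores.tsv", sep="\t")
        case_means.rename("mean_score").to_csv(outdir / "case_means.tsv", sep="\t")
        dep_table.to_csv(outdir / "dep.tsv", sep="\t")
        comparisons.to_csv(outdir / "comparisons.tsv", sep="\t", index=False)
        if chrom_table is not None:
            chrom_table.to_csv(outdir / "chromosome_counts.tsv", sep="\t")
        for direction, res in enrich_tables.items():
            enrichment_table(res).to_csv(
                outdir / f"enrichment_{direction}.tsv", sep="\t", index=False
            )
        with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        with open(outdir / "run.log", "w", encoding="utf-8") as fh:
            fh.write(
                f"stoichioprot {__version__}\npython {sys.version.split()[0]}\n"
                f"seed {config.seed}\nconfig_hash {config.config_hash()}\n"
            )
            fh.write(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return report
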