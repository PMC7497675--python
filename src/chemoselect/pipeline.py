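"""End-to-end orchestration: filter -> subtract -> classify -> aggregate
-> enrich -> score -> validate, from a flat configuration.

Every stage writes its outputs before the next starts, logs its
input/output counts, and contributes to a machine-readable summary, so
the whole accounting (burden table, selection totals, recurrent-gene
list, priority table, validation results) can be reconstructed from a
run directory.  Reruns with identical config and inputs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import os
from dataclasses import dataclass, field

import yaml

from . import (
    enrichment,
    gene_recurrence,
    germline_subtraction,
    outcome_validation,
    prioritization,
    synthetic_data,
    therapy_selection,
    variant_io,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "STAGES"]

logger = logging.getLogger("chemoselect")

STAGES = (
    "simulate",
    "filter",
    "somatic",
    "classify",
    "aggregate",
    "enrich",
    "prioritize",
    "validate",
)


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults are the study's values."""

    input_dir: str = ""
    out_dir: str = "chemoselect_run"
    simulate: bool = False
    min_depth: int = 5
    max_depth: int = 800
    min_qual: float = 30.0
    subtraction_mode: str = "pooled"  # or "matched"
    maf_delta_threshold: float = 0.05
    min_patients: int = 2
    sift_cutoff: float = 0.05
    priority_threshold: int = 5
    enrichment_top_n: int = 3
    pathway_q_max: float = 0.05  # top sets must also be significant to grant the bonus
    fdr_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subtraction_mode not in ("matched", "pooled"):
            raise ValueError("subtraction_mode must be matched or pooled")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineResult:
    """In-memory handles to every stage's outputs."""

    config: PipelineConfig
    summary: dict = field(default_factory=dict)
    burden: object = None
    selection: object = None
    list_c: object = None
    bidirectional: object = None
    enrichment_results: dict = field(default_factory=dict)
    ranked: list = field(default_factory=list)
    top_candidates: list = field(default_factory=list)
    validation: list = field(default_factory=list)


def _discover_patients(input_dir: str) -> list[str]:
    pids = sorted(
        os.path.basename(p)[: -len("_normal.vcf")]
        for p in glob.glob(os.path.join(input_dir, "*_normal.vcf"))
    )
    if not pids:
        raise FileNotFoundError(f"no *_normal.vcf files found in {input_dir}")
    for pid in pids:
        for tp in ("pre", "post"):
            path = os.path.join(input_dir, f"{pid}_{tp}.vcf")
            if not os.path.exists(path):
                raise FileNotFoundError(f"patient {pid} is missing {path}")
    return pids


def run_pipeline(
    config: PipelineConfig, stop_after: str = "validate"
) -> PipelineResult:
    """Execute the pipeline stages in order, stopping after ``stop_after``."""
    if stop_after not in STAGES:
        raise ValueError(f"unknown stage {stop_after!r}")
    stop_idx = STAGES.index(stop_after)
    os.makedirs(config.out_dir, exist_ok=True)
    result = PipelineResult(config=config)
    summary: dict = {"stages": {}}
    result.summary = summary

    def done(stage: str) -> bool:
        return STAGES.index(stage) > stop_idx

    # --- simulate -----------------------------------------------------
    input_dir = config.input_dir
    if config.simulate:
        try:
            input_dir = os.path.join(config.out_dir, "simulated")
            cfg = synthetic_data.SyntheticCohortConfig(seed=config.seed)
            truth = synthetic_data.generate_cohort(cfg, input_dir)
            summary["stages"]["simulate"] = {
                "n_patients": cfg.n_patients,
                "n_drivers": len(truth.drivers),
            }
            logger.info("simulate: %d patients -> %s", cfg.n_patients, input_dir)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("simulate", str(exc)) from exc
    if done("simulate"):
        _write_summary(summary, config.out_dir)
        return result

    # --- read + filter ------------------------------------------------
    try:
        pids = _discover_patients(input_dir)
        raw: dict[str, dict[str, variant_io.SampleProfile]] = {}
        filtered: dict[str, dict[str, variant_io.SampleProfile]] = {}
        counts = {}
        for pid in pids:
            raw[pid], filtered[pid] = {}, {}
            for tp in ("normal", "pre", "post"):
                prof = variant_io.read_vcf(
                    os.path.join(input_dir, f"{pid}_{tp}.vcf"), f"{pid}:{tp}",
                    "normal" if tp == "normal" else tp,
                )
                filt = variant_io.filter_calls(
                    prof, config.min_depth, config.max_depth, config.min_qual
                )
                raw[pid][tp], filtered[pid][tp] = prof, filt
                counts[f"{pid}:{tp}"] = {"raw": len(prof), "filtered": len(filt)}
                logger.info("filter %s:%s %d -> %d", pid, tp, len(prof), len(filt))
        summary["stages"]["filter"] = counts
        variant_io.write_profile_tsv(
            (filtered[p][t] for p in pids for t in ("normal", "pre", "post")),
            os.path.join(config.out_dir, "filtered_calls.tsv"),
        )
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("filter", str(exc)) from exc
    if done("filter"):
        _write_summary(summary, config.out_dir)
        return result

    # --- germline subtraction ------------------------------------------
    try:
        pooled = germline_subtraction.build_pooled_normal(
            [filtered[p]["normal"] for p in pids]
        )
        matched_somatic, pooled_somatic = {}, {}
        active: dict[str, dict[str, variant_io.SampleProfile]] = {p: {} for p in pids}
        for pid in pids:
            matched = germline_subtraction.matched_germline(filtered[pid]["normal"])
            for tp in ("pre", "post"):
                label = f"{pid}:{tp}"
                m = germline_subtraction.subtract_germline(filtered[pid][tp], matched)
                q = germline_subtraction.subtract_germline(filtered[pid][tp], pooled)
                matched_somatic[label], pooled_somatic[label] = m, q
                active[pid][tp] = q if config.subtraction_mode == "pooled" else m
                logger.info(
                    "somatic %s matched=%d pooled=%d", label, len(m), len(q)
                )
        table = germline_subtraction.burden_table(matched_somatic, pooled_somatic)
        result.burden = germline_subtraction.summarize_burden(table)
        summary["stages"]["somatic"] = {
            "mean_burden": result.burden.mean_burden,
            "min_burden": result.burden.min_burden,
            "max_burden": result.burden.max_burden,
            "mean_pct_change": result.burden.mean_pct_change,
        }
        table.to_csv(os.path.join(config.out_dir, "burden_table.tsv"), sep="\t")
        variant_io.write_profile_tsv(
            (active[p][t] for p in pids for t in ("pre", "post")),
            os.path.join(config.out_dir, "somatic_calls.tsv"),
            subtraction_mode=config.subtraction_mode,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("somatic", str(exc)) from exc
    if done("somatic"):
        _write_summary(summary, config.out_dir)
        return result

    # --- selection classification --------------------------------------
    try:
        gene_map = variant_io.read_gene_map(os.path.join(input_dir, "gene_map.tsv"))
        selection = therapy_selection.build_selection_lists(
            active, config.maf_delta_threshold
        )
        result.selection = selection
        totals = selection.pooled_totals()
        summary["stages"]["classify"] = totals
        logger.info("classify: %s", totals)
        therapy_selection.write_selection_tsv(
            selection, gene_map, os.path.join(config.out_dir, "selection_lists.tsv")
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("classify", str(exc)) from exc
    if done("classify"):
        _write_summary(summary, config.out_dir)
        return result

    # --- gene recurrence ------------------------------------------------
    try:
        recs, unmapped = gene_recurrence.aggregate_by_gene(selection, gene_map)
        list_c = gene_recurrence.build_list_C(recs, config.min_patients)
        bidir = gene_recurrence.report_bidirectional(recs, list_c)
        result.list_c, result.bidirectional = list_c, bidir
        summary["stages"]["aggregate"] = {
            "gene_direction_records": len(recs),
            "unmapped_variants": len(unmapped),
            "list_c_entries": len(list_c.entries),
            "list_c_distinct_genes": list_c.distinct_genes,
            "dual_direction_genes": sorted(list_c.dual_direction_genes),
            "bidirectional_genes": len(bidir.bidirectional),
            "same_patient_conflicts": len(bidir.same_patient),
            "breakdown": {
                d: {str(k): v for k, v in sorted(list_c.breakdown[d].items())}
                for d in ("A", "B")
            },
        }
        logger.info(
            "aggregate: %d entries, %d distinct genes",
            len(list_c.entries), list_c.distinct_genes,
        )
        gene_recurrence.write_list_c_tsv(
            list_c, os.path.join(config.out_dir, "list_c.tsv")
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("aggregate", str(exc)) from exc
    if done("aggregate"):
        _write_summary(summary, config.out_dir)
        return result

    # --- enrichment -------------------------------------------------------
    try:
        universe = {g for genes in gene_map.values() for g in genes}
        collection = enrichment.read_gmt(
            os.path.join(input_dir, "pathways.gmt"), universe=universe
        )
        queries = {
            "A": _genes_of(selection.pooled("A"), gene_map),
            "B": _genes_of(selection.pooled("B"), gene_map),
            "C": list_c.genes(),
        }
        top_pathway_genes: dict[str, str] = {}
        enr_summary = {}
        for name, query in queries.items():
            if not query:
                enr_summary[name] = None
                continue
            results, _top = enrichment.enrich(
                query, collection, config.enrichment_top_n
            )
            result.enrichment_results[name] = results
            members = {s.set_id: s.members for s in collection.sets}
            descr = {s.set_id: s.description or s.set_id for s in collection.sets}
            for r in results[: config.enrichment_top_n]:
                if r.q >= config.pathway_q_max:
                    continue
                for g in members[r.set_id]:
                    top_pathway_genes.setdefault(g, descr[r.set_id])
            enr_summary[name] = {
                "n_query": len(query),
                "top_sets": [r.set_id for r in results[: config.enrichment_top_n]],
            }
            enrichment.write_enrichment_tsv(
                results, os.path.join(config.out_dir, f"enrichment_{name}.tsv")
            )
        summary["stages"]["enrich"] = enr_summary
        result.summary["top_pathway_genes"] = sorted(top_pathway_genes)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("enrich", str(exc)) from exc
    if done("enrich"):
        _write_summary(summary, config.out_dir)
        return result

    # --- prioritization ---------------------------------------------------
    try:
        annotations = prioritization.read_annotations(
            os.path.join(input_dir, "annotations.tsv")
        )
        ranked, top = prioritization.score_candidates(
            list_c, annotations, top_pathway_genes, config.priority_threshold
        )
        result.ranked, result.top_candidates = ranked, top
        frac_c, n_unann = prioritization.damaging_fraction(
            [v for e in list_c.entries for v in e.variants], annotations
        )
        summary["stages"]["prioritize"] = {
            "ranked_entries": len(ranked),
            "top_candidates": [
                {"gene": r.gene, "direction": r.direction, "score": r.score}
                for r in top
            ],
            "damaging_fraction_list_c": round(frac_c, 4),
            "unannotated_list_c_variants": n_unann,
        }
        logger.info("prioritize: %d candidates at score >= %d",
                    len(top), config.priority_threshold)
        prioritization.write_priority_tsv(
            ranked, os.path.join(config.out_dir, "priority_table.tsv")
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("prioritize", str(exc)) from exc
    if done("prioritize"):
        _write_summary(summary, config.out_dir)
        return result

    # --- outcome validation -----------------------------------------------
    try:
        cohort_path = os.path.join(input_dir, "survival_cohort.tsv")
        if os.path.exists(cohort_path):
            cohort = outcome_validation.read_cohort(cohort_path)
            genes = sorted({r.gene for r in top}) or sorted(cohort.genes)
            validation = outcome_validation.validate_genes(
                cohort, genes, config.fdr_threshold
            )
            result.validation = validation
            summary["stages"]["validate"] = {
                "n_tested": len(validation),
                "significant": sorted(r.gene for r in validation if r.significant),
            }
            with open(
                os.path.join(config.out_dir, "outcome_validation.tsv"), "w"
            ) as fh:
                fh.write("gene\tauc\tcutpoint\tmw_p\tlogrank_p\tq\tsignificant\n")
                for r in validation:
                    fh.write(
                        f"{r.gene}\t{r.auc:.4f}\t{r.cutpoint:.4f}\t{r.mw_p:.4g}\t"
                        f"{r.logrank_p:.4g}\t{r.q:.4g}\t{int(r.significant)}\n"
                    )
        else:
            summary["stages"]["validate"] = None
            logger.info("validate: no survival cohort found, skipped")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("validate", str(exc)) from exc
    _write_summary(summary, config.out_dir)
    return result


def _genes_of(pairs, gene_map) -> set:
    genes: set = set()
    for p in pairs:
        genes |= set(variant_io.genes_for(p.key, gene_map))
    return genes


def _write_summary(summary: dict, out_dir: str) -> None:
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
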