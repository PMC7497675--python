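"""Damaging-prediction ingest and additive candidate scoring.

A variant counts as damaging when SIFT scores it below 0.05 or PolyPhen2
calls it possibly/probably damaging (either tool suffices).  Each
recurrent (gene, direction) entry receives the additive priority score

    score = n_patients + n_damaging + (1 if in a top enriched pathway)

where n_damaging counts damaging variants among the gene's selected
variants (it can exceed n_patients when one patient carries several
variants in the gene).  Entries scoring at or above the threshold
(default 5) form the highest-priority candidate list.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

from .gene_recurrence import ListC
from .therapy_selection import SomaticPair
from .variant_io import VariantKey, normalize_variant

__all__ = [
    "POLYPHEN_CATEGORIES",
    "DamagingAnnotation",
    "PriorityRecord",
    "is_damaging",
    "read_annotations",
    "damaging_fraction",
    "score_candidates",
    "write_priority_tsv",
    "DEFAULT_SIFT_CUTOFF",
    "DEFAULT_PRIORITY_THRESHOLD",
]

DEFAULT_SIFT_CUTOFF = 0.05
DEFAULT_PRIORITY_THRESHOLD = 5

POLYPHEN_CATEGORIES = ("benign", "possibly_damaging", "probably_damaging")
_DAMAGING_POLYPHEN = {"possibly_damaging", "probably_damaging"}


def is_damaging(
    sift_score: float | None,
    polyphen_call: str | None,
    sift_cutoff: float = DEFAULT_SIFT_CUTOFF,
    count_possibly: bool = True,
) -> bool:
    """Either-tool damaging rule: SIFT < cutoff (strict) or PolyPhen2 damaging."""
    if sift_score is not None and not 0.0 <= sift_score <= 1.0:
        raise ValueError(f"SIFT score {sift_score} outside [0, 1]")
    if polyphen_call is not None and polyphen_call not in POLYPHEN_CATEGORIES:
        raise ValueError(f"unknown PolyPhen2 category {polyphen_call!r}")
    by_sift = sift_score is not None and sift_score < sift_cutoff
    damaging_cats = (
        _DAMAGING_POLYPHEN if count_possibly else {"probably_damaging"}
    )
    by_polyphen = polyphen_call in damaging_cats
    return by_sift or by_polyphen


@dataclass(frozen=True)
class DamagingAnnotation:
    key: VariantKey
    sift_score: float | None
    polyphen_call: str | None

    @property
    def damaging(self) -> bool:
        return is_damaging(self.sift_score, self.polyphen_call)


def read_annotations(path: str) -> dict[VariantKey, DamagingAnnotation]:
    """Read a damaging-prediction TSV (chrom, pos, ref, alt, sift_score, polyphen_call)."""
    table: dict[VariantKey, DamagingAnnotation] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "sift_score", "polyphen_call"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"annotation table must have columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                key = normalize_variant(
                    row["chrom"], int(row["pos"]), row["ref"], row["alt"]
                )
                sift = row["sift_score"].strip()
                poly = row["polyphen_call"].strip()
                ann = DamagingAnnotation(
                    key,
                    float(sift) if sift else None,
                    poly if poly else None,
                )
                ann.damaging  # validate ranges/categories eagerly
            except (ValueError, KeyError) as exc:
                raise ValueError(f"malformed annotation row {rownum}: {exc}") from exc
            table[key] = ann
    return table


def damaging_fraction(
    variants: Iterable[SomaticPair],
    annotations: Mapping[VariantKey, DamagingAnnotation],
) -> tuple[float, int]:
    """Fraction damaging among annotated variants, plus the unannotated count.

    Distinct variant keys are evaluated once each.
    """
    keys = {v.key for v in variants}
    annotated = [annotations[k] for k in keys if k in annotations]
    n_unannotated = len(keys) - len(annotated)
    if not annotated:
        return 0.0, n_unannotated
    frac = sum(a.damaging for a in annotated) / len(annotated)
    return frac, n_unannotated


@dataclass(frozen=True)
class PriorityRecord:
    """One ranked candidate row: gene, direction, evidence counts, score."""

    gene: str
    direction: str  # A = selected against, B = selected for
    n_patients: int
    n_damaging: int
    pathway_flag: bool
    pathway_name: str
    score: int

    def __post_init__(self) -> None:
        expected = self.n_patients + self.n_damaging + (1 if self.pathway_flag else 0)
        if self.score != expected:
            raise ValueError(
                f"score {self.score} != n_patients + n_damaging + pathway "
                f"({expected}) for {self.gene}"
            )


def score_candidates(
    list_c: ListC,
    annotations: Mapping[VariantKey, DamagingAnnotation],
    top_pathway_genes: Mapping[str, str] | Iterable[str] = (),
    threshold: int = DEFAULT_PRIORITY_THRESHOLD,
) -> tuple[list[PriorityRecord], list[PriorityRecord]]:
    """Score and rank every recurrent entry; return (all ranked, >= threshold).

    ``top_pathway_genes`` maps gene symbols in a top enriched pathway to
    the pathway's name (a plain set of symbols is accepted; the name is
    then blank).  Ordering: score desc, n_patients desc, n_damaging
    desc, pathway flag first, gene symbol ascending.
    """
    if isinstance(top_pathway_genes, Mapping):
        pathway_of = dict(top_pathway_genes)
    else:
        pathway_of = {g: "" for g in top_pathway_genes}
    pathway_of = {g.upper(): name for g, name in pathway_of.items()}
    records = []
    for e in list_c.entries:
        keys = {v.key for v in e.variants}
        n_damaging = sum(
            1 for k in keys if k in annotations and annotations[k].damaging
        )
        flag = e.gene.upper() in pathway_of
        records.append(
            PriorityRecord(
                gene=e.gene,
                direction=e.direction,
                n_patients=e.n_patients,
                n_damaging=n_damaging,
                pathway_flag=flag,
                pathway_name=pathway_of.get(e.gene.upper(), "") if flag else "",
                score=e.n_patients + n_damaging + (1 if flag else 0),
            )
        )
    ranked = sorted(
        records,
        key=lambda r: (-r.score, -r.n_patients, -r.n_damaging, not r.pathway_flag, r.gene),
    )
    top = [r for r in ranked if r.score >= threshold]
    return ranked, top


def write_priority_tsv(records: list[PriorityRecord], path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["gene", "direction", "n_patients", "n_damaging", "pathway", "score"]
        )
        for r in records:
            pathway = f"Y; {r.pathway_name}" if r.pathway_flag else "N"
            w.writerow(
                [r.gene, r.direction, r.n_patients, r.n_damaging, pathway, r.score]
            )
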