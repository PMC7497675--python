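"""Cross-patient gene recurrence of direction-consistent selected variants.

Selected variants (groups A and B) are aggregated to (gene, direction)
units.  A gene enters the recurrent candidate list ("list C") for a
direction when variants of that direction occur in at least
``min_patients`` different patients — recurrence counts patients, not
variants.  A gene may recur in both directions and then contributes two
entries but one distinct gene; such dual-direction entries are flagged,
since simultaneous gain- and loss-of-function selection on one gene is
biologically unlikely.  Genes with variants in both directions that lack
single-direction recurrence are reported and excluded from
prioritization.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field

from .therapy_selection import SelectionLists, SomaticPair
from .variant_io import GeneMap, genes_for

__all__ = [
    "GeneRecurrence",
    "ListC",
    "BidirectionalReport",
    "aggregate_by_gene",
    "build_list_C",
    "report_bidirectional",
    "write_list_c_tsv",
]

DEFAULT_MIN_PATIENTS = 2


@dataclass
class GeneRecurrence:
    """Support for one (gene, direction): patients and variants."""

    gene: str
    direction: str  # "A" or "B"
    patients: frozenset
    variants: tuple  # supporting SomaticPairs

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_variants(self) -> int:
        return len(self.variants)


def aggregate_by_gene(
    lists: SelectionLists, gene_map: GeneMap
) -> tuple[list[GeneRecurrence], list[SomaticPair]]:
    """Group selected variants by (gene, direction).

    A variant mapping to several genes supports each of them; variants
    with no gene annotation are returned separately, not dropped.
    """
    support: dict[tuple[str, str], list[SomaticPair]] = {}
    unmapped: list[SomaticPair] = []
    for direction in ("A", "B"):
        for pair in lists.pooled(direction):
            genes = genes_for(pair.key, gene_map)
            if not genes:
                unmapped.append(pair)
                continue
            for gene in genes:
                support.setdefault((gene, direction), []).append(pair)
    recs = [
        GeneRecurrence(
            gene,
            direction,
            frozenset(p.patient_id for p in pairs),
            tuple(pairs),
        )
        for (gene, direction), pairs in sorted(support.items())
    ]
    return recs, unmapped


@dataclass
class ListC:
    """Recurrent (gene, direction) entries and the distinct-gene count."""

    entries: list[GeneRecurrence]
    min_patients: int
    distinct_genes: int
    dual_direction_genes: frozenset
    breakdown: dict  # direction -> {n_patients: n_genes}

    def entry(self, gene: str, direction: str) -> GeneRecurrence | None:
        for e in self.entries:
            if e.gene == gene and e.direction == direction:
                return e
        return None

    def genes(self) -> set[str]:
        return {e.gene for e in self.entries}


def build_list_C(
    recs: list[GeneRecurrence], min_patients: int = DEFAULT_MIN_PATIENTS
) -> ListC:
    """Keep (gene, direction) records recurrent in >= min_patients patients."""
    if min_patients < 2:
        raise ValueError("min_patients must be >= 2")
    entries = [r for r in recs if r.n_patients >= min_patients]
    genes = [e.gene for e in entries]
    dual = frozenset(g for g, n in Counter(genes).items() if n > 1)
    breakdown: dict[str, dict[int, int]] = {"A": {}, "B": {}}
    for e in entries:
        d = breakdown[e.direction]
        d[e.n_patients] = d.get(e.n_patients, 0) + 1
    return ListC(entries, min_patients, len(set(genes)), dual, breakdown)


@dataclass
class BidirectionalReport:
    """Genes carrying selected variants in both directions."""

    bidirectional: frozenset  # >=1 A variant and >=1 B variant anywhere
    same_patient: frozenset  # both directions within one patient
    in_list_c: frozenset  # bidirectional genes that still made list C
    excluded: frozenset = field(default_factory=frozenset)  # no single-direction recurrence


def report_bidirectional(
    recs: list[GeneRecurrence], list_c: ListC
) -> BidirectionalReport:
    """Identify both-direction genes and the same-patient conflict subset."""
    by_gene: dict[str, dict[str, GeneRecurrence]] = {}
    for r in recs:
        by_gene.setdefault(r.gene, {})[r.direction] = r
    bidirectional = {g for g, d in by_gene.items() if len(d) == 2}
    same_patient = {
        g
        for g in bidirectional
        if by_gene[g]["A"].patients & by_gene[g]["B"].patients
    }
    c_genes = list_c.genes()
    return BidirectionalReport(
        bidirectional=frozenset(bidirectional),
        same_patient=frozenset(same_patient),
        in_list_c=frozenset(bidirectional & c_genes),
        excluded=frozenset(bidirectional - c_genes),
    )


def write_list_c_tsv(list_c: ListC, path: str) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "direction", "n_patients", "n_variants", "patients"])
        for e in list_c.entries:
            w.writerow(
                [e.gene, e.direction, e.n_patients, e.n_variants,
                 ";".join(sorted(e.patients))]
            )
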