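"""Pairing somatic variants across timepoints and classifying selection.

Within each patient, every somatic variant seen in the pre- or
post-therapy tumour is paired across the two timepoints and assigned to:

* group A — unique to the pre-therapy sample, or with mutant allele
  frequency (MAF) reduced by more than the threshold: lost or reduced in
  prevalence through therapy (candidate sensitivity mediators);
* group B — unique to the post-therapy sample, or with MAF increased by
  more than the threshold: selected for by therapy (candidate resistance
  mediators);
* none — detected at both timepoints with |delta| at or below threshold.

"Unique" means present-and-passing-filters at one timepoint and
absent-or-filtered at the other.  The threshold is an absolute MAF
difference (default 0.05, i.e. changes > 5 percentage points), strict.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .variant_io import GeneMap, SampleProfile, VariantCall, VariantKey, genes_for

__all__ = [
    "SomaticPair",
    "SelectionLists",
    "compute_maf",
    "classify_pair",
    "build_selection_lists",
    "count_groups",
    "write_selection_tsv",
    "DEFAULT_MAF_DELTA",
]

DEFAULT_MAF_DELTA = 0.05


def compute_maf(call: VariantCall) -> float:
    """Mutant allele frequency: alt-supporting reads / total reads."""
    if call.depth == 0:
        raise ValueError(
            f"depth 0 at {call.key.chrom}:{call.key.pos}; MAF undefined"
        )
    return call.alt_depth / call.depth


@dataclass(frozen=True)
class SomaticPair:
    """A somatic variant's matched pre/post state within one patient."""

    key: VariantKey
    patient_id: str
    maf_pre: float | None
    maf_post: float | None
    group: str  # "A", "B" or "none"

    @property
    def present_pre(self) -> bool:
        return self.maf_pre is not None

    @property
    def present_post(self) -> bool:
        return self.maf_post is not None

    @property
    def delta(self) -> float | None:
        if self.maf_pre is None or self.maf_post is None:
            return None
        return self.maf_post - self.maf_pre


def classify_pair(
    pre: VariantCall | None,
    post: VariantCall | None,
    threshold: float = DEFAULT_MAF_DELTA,
    patient_id: str | None = None,
) -> SomaticPair:
    """Classify one somatic variant's selection group within a patient."""
    if pre is None and post is None:
        raise ValueError("at least one of pre/post must be present")
    if pre is not None and post is not None and pre.key != post.key:
        raise ValueError(f"key mismatch: {pre.key} vs {post.key}")
    key = (pre or post).key
    pid = patient_id if patient_id is not None else (pre or post).sample_id
    maf_pre = compute_maf(pre) if pre is not None else None
    maf_post = compute_maf(post) if post is not None else None
    if post is None:
        group = "A"
    elif pre is None:
        group = "B"
    else:
        delta = maf_post - maf_pre
        if delta < -threshold:
            group = "A"
        elif delta > threshold:
            group = "B"
        else:
            group = "none"
    return SomaticPair(key, pid, maf_pre, maf_post, group)


@dataclass
class SelectionLists:
    """Per-patient A/B/none classification plus pooled totals."""

    per_patient: dict[str, dict[str, list[SomaticPair]]] = field(default_factory=dict)
    threshold: float = DEFAULT_MAF_DELTA

    def patient_list(self, patient_id: str, group: str) -> list[SomaticPair]:
        return self.per_patient.get(patient_id, {}).get(group, [])

    def pooled(self, group: str) -> list[SomaticPair]:
        out: list[SomaticPair] = []
        for groups in self.per_patient.values():
            out.extend(groups.get(group, []))
        return out

    def pooled_totals(self) -> dict[str, int]:
        return {g: len(self.pooled(g)) for g in ("A", "B", "none")}

    def all_pairs(self) -> list[SomaticPair]:
        return self.pooled("A") + self.pooled("B") + self.pooled("none")


def build_selection_lists(
    cohort: dict[str, dict[str, SampleProfile]],
    threshold: float = DEFAULT_MAF_DELTA,
) -> SelectionLists:
    """Classify every somatic variant of every patient exactly once.

    ``cohort`` maps patient id to ``{"pre": profile, "post": profile}`` of
    somatic calls (already germline-subtracted and filtered).
    """
    lists = SelectionLists(threshold=threshold)
    for patient_id in sorted(cohort):
        profiles = cohort[patient_id]
        if "pre" not in profiles or "post" not in profiles:
            raise ValueError(f"patient {patient_id} is missing a timepoint")
        pre_p, post_p = profiles["pre"], profiles["post"]
        groups: dict[str, list[SomaticPair]] = {"A": [], "B": [], "none": []}
        for key in sorted(pre_p.keys | post_p.keys):
            pair = classify_pair(
                pre_p.calls.get(key), post_p.calls.get(key), threshold, patient_id
            )
            groups[pair.group].append(pair)
        lists.per_patient[patient_id] = groups
    return lists


def count_groups(rows) -> dict[str, int]:
    """Tally selection-group labels from an iterable of row mappings.

    Accepts any iterable of mappings with a ``group`` entry — e.g. rows
    of a published per-variant supplementary table — and returns counts
    per group, so list totals can be checked against external tables.
    """
    counts: dict[str, int] = {}
    for row in rows:
        g = str(row["group"]).strip()
        counts[g] = counts.get(g, 0) + 1
    return counts


def write_selection_tsv(lists: SelectionLists, gene_map: GeneMap, path: str) -> None:
    """Per-variant table: patient, locus, gene(s), MAFs, delta, group."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["patient", "chrom", "pos", "ref", "alt", "genes",
             "maf_pre", "maf_post", "delta", "group"]
        )
        for patient_id in sorted(lists.per_patient):
            for group in ("A", "B", "none"):
                for p in lists.per_patient[patient_id][group]:
                    w.writerow(
                        [p.patient_id, p.key.chrom, p.key.pos, p.key.ref, p.key.alt,
                         ";".join(sorted(genes_for(p.key, gene_map))),
                         _fmt(p.maf_pre), _fmt(p.maf_post), _fmt(p.delta), p.group]
                    )


def _fmt(x: float | None) -> str:
    return "" if x is None else f"{x:.6g}"
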