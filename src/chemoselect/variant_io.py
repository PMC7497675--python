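"""Reading, normalising and quality-filtering per-sample variant calls.

Each patient contributes three single-sample VCFs (normal tissue, tumour
before therapy, tumour after therapy).  Calls are keyed by the exact
(chrom, pos, ref, alt) tuple after multi-allelic splitting and parsimony
trimming, so that the same event called slightly differently in two files
compares equal across samples — the whole downstream analysis rests on
exact variant identity between timepoints and between tumour and normal.

Quality filtering applies the study's hard thresholds: total read depth
within [5, 800] inclusive and Phred-scaled quality >= 30.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping

import pysam

__all__ = [
    "VariantKey",
    "VariantClass",
    "VariantCall",
    "SampleProfile",
    "GeneMap",
    "normalize_variant",
    "read_vcf",
    "filter_calls",
    "read_gene_map",
    "DEFAULT_MIN_DEPTH",
    "DEFAULT_MAX_DEPTH",
    "DEFAULT_MIN_QUAL",
]

DEFAULT_MIN_DEPTH = 5
DEFAULT_MAX_DEPTH = 800
DEFAULT_MIN_QUAL = 30.0

_TIMEPOINTS = ("normal", "pre", "post")


class VariantClass(str, Enum):
    """SNV / insertion / deletion, decided by ref/alt lengths."""

    SNV = "SNV"
    INS = "Ins"
    DEL = "Del"


@dataclass(frozen=True, order=True)
class VariantKey:
    """Exact variant identity: 1-based position, uppercase ACGT alleles."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> VariantClass:
        if len(self.ref) == len(self.alt) == 1:
            return VariantClass.SNV
        return VariantClass.INS if len(self.alt) > len(self.ref) else VariantClass.DEL


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantKey:
    """Parsimony-trim an allele pair and return its canonical key.

    Shared suffix bases are stripped first, then shared prefix bases
    (advancing ``pos``), keeping at least one base in each allele.  This
    canonicalises padded indel representations without needing the
    reference sequence.
    """
    ref, alt = ref.upper(), alt.upper()
    # strip common suffix
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # strip common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantKey(chrom, pos, ref, alt)


@dataclass(frozen=True)
class VariantCall:
    """One observed variant in one sample, with read-depth evidence.

    ``qual`` is the Phred-scaled call quality; ``None`` encodes a missing
    QUAL ('.'), which the quality filter removes.
    """

    key: VariantKey
    sample_id: str
    depth: int
    alt_depth: int
    qual: float | None

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.alt_depth > self.depth:
            raise ValueError(
                f"alt_depth {self.alt_depth} > depth {self.depth} at "
                f"{self.key.chrom}:{self.key.pos}"
            )
        if self.qual is not None and self.qual < 0:
            raise ValueError("qual must be >= 0")

    @property
    def vclass(self) -> VariantClass:
        return self.key.vclass


@dataclass
class SampleProfile:
    """All calls of one sample, uniquely keyed by variant."""

    patient_id: str
    timepoint: str
    calls: dict[VariantKey, VariantCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.timepoint not in _TIMEPOINTS:
            raise ValueError(
                f"timepoint must be one of {_TIMEPOINTS}, got {self.timepoint!r}"
            )

    def __len__(self) -> int:
        return len(self.calls)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.calls

    @property
    def keys(self) -> set[VariantKey]:
        return set(self.calls)

    def add(self, call: VariantCall) -> None:
        """Insert a call; on a duplicate key the higher-QUAL record wins."""
        prev = self.calls.get(call.key)
        if prev is None or _qual_rank(call.qual) > _qual_rank(prev.qual):
            self.calls[call.key] = call

    def class_counts(self) -> dict[str, int]:
        """Counts per variant class plus the total, Table-1 style."""
        out = {"SNV": 0, "Ins": 0, "Del": 0}
        for call in self.calls.values():
            out[call.vclass.value] += 1
        out["All"] = len(self.calls)
        return out


def _qual_rank(q: float | None) -> float:
    return -1.0 if q is None else q


class VCFFormatError(ValueError):
    """Raised when a VCF record lacks the fields this pipeline requires."""


def read_vcf(path: str, sample_id: str, timepoint: str) -> SampleProfile:
    """Read a single-sample VCF into a :class:`SampleProfile`.

    Multi-allelic records are split into one call per alternate allele,
    taking depth from the sample's DP and alt support from the matching
    component of AD.  Records whose alt is symbolic (e.g. ``<DEL>``) or
    ``*`` are skipped.  Duplicate keys collapse to the highest-QUAL call.
    """
    patient_id, _, tp = sample_id.rpartition(":")
    profile = SampleProfile(patient_id or sample_id, timepoint)
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            fmt = rec.samples[0] if len(rec.samples) else None
            for i, alt in enumerate(rec.alts):
                if not _is_simple_allele(rec.ref) or not _is_simple_allele(alt):
                    continue
                key = normalize_variant(rec.chrom, rec.pos, rec.ref, alt)
                depth, ad = _extract_depths(rec, fmt, i)
                if depth is None or ad is None:
                    raise VCFFormatError(
                        f"missing DP/AD at {rec.chrom}:{rec.pos} in {path}"
                    )
                qual = float(rec.qual) if rec.qual is not None else None
                profile.add(
                    VariantCall(key, sample_id, depth, min(ad, depth), qual)
                )
    return profile


def _is_simple_allele(a: str | None) -> bool:
    return bool(a) and all(c in "ACGTacgt" for c in a)


def _extract_depths(rec, fmt, alt_index: int) -> tuple[int | None, int | None]:
    depth = None
    ad = None
    if fmt is not None:
        dp = fmt.get("DP")
        if dp is not None:
            depth = int(dp)
        advals = fmt.get("AD")
        if advals is not None and len(advals) > alt_index + 1:
            v = advals[alt_index + 1]
            if v is not None:
                ad = int(v)
    if depth is None and "DP" in rec.info:
        depth = int(rec.info["DP"])
    return depth, ad


def filter_calls(
    profile: SampleProfile,
    min_depth: int = DEFAULT_MIN_DEPTH,
    max_depth: int = DEFAULT_MAX_DEPTH,
    min_qual: float = DEFAULT_MIN_QUAL,
) -> SampleProfile:
    """Apply the depth/quality hard filter.

    Retains exactly the calls with ``min_depth <= depth <= max_depth`` and
    ``qual >= min_qual``; missing QUAL fails the quality test.  Idempotent.
    """
    if min_depth <= 0 or max_depth <= 0 or min_qual <= 0:
        raise ValueError("thresholds must be positive")
    if min_depth > max_depth:
        raise ValueError("min_depth > max_depth")
    kept = {
        k: c
        for k, c in profile.calls.items()
        if min_depth <= c.depth <= max_depth
        and c.qual is not None
        and c.qual >= min_qual
    }
    return replace(profile, calls=kept)


GeneMap = Mapping[VariantKey, frozenset]


def read_gene_map(path: str) -> dict[VariantKey, frozenset]:
    """Read a variant-to-gene TSV (chrom, pos, ref, alt, gene).

    A variant may map to several genes; repeated (variant, gene) rows are
    deduplicated.  Malformed rows raise with their row number.
    """
    mapping: dict[VariantKey, set] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"chrom", "pos", "ref", "alt", "gene"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"gene map must have columns {sorted(required)}")
        for rownum, row in enumerate(reader, start=2):
            try:
                key = normalize_variant(
                    row["chrom"], int(row["pos"]), row["ref"], row["alt"]
                )
                gene = row["gene"].strip()
                if not gene:
                    raise ValueError("empty gene symbol")
            except (ValueError, KeyError, TypeError) as exc:
                raise ValueError(f"malformed gene map row {rownum}: {exc}") from exc
            mapping.setdefault(key, set()).add(gene)
    return {k: frozenset(v) for k, v in mapping.items()}


def genes_for(key: VariantKey, gene_map: GeneMap) -> frozenset:
    """Gene symbols a variant maps to (empty if unannotated)."""
    return gene_map.get(key, frozenset())


def write_profile_tsv(
    profiles: Iterable[SampleProfile], path: str, subtraction_mode: str = ""
) -> None:
    """Write call profiles as a flat TSV (one row per call)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(
            ["patient", "timepoint", "chrom", "pos", "ref", "alt", "vclass",
             "depth", "alt_depth", "qual", "subtraction_mode"]
        )
        for p in profiles:
            for k in sorted(p.calls):
                c = p.calls[k]
                w.writerow(
                    [p.patient_id, p.timepoint, k.chrom, k.pos, k.ref, k.alt,
                     c.vclass.value, c.depth, c.alt_depth,
                     "" if c.qual is None else c.qual, subtraction_mode]
                )
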