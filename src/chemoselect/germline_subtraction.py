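"""Somatic definition by germline subtraction, matched or pooled.

A somatic variant is a tumour call whose key is absent from the germline
set.  The matched mode subtracts only the same patient's normal; the
pooled mode subtracts the union of every patient's normal variants,
which effectively pools normal read depths and drives the probability of
missing a heterozygous germline variant — (1/2)^depth under fair allele
sampling — towards zero.  The burden summary reproduces the matched
vs pooled accounting (per-sample counts by variant class, cohort mean
and range, and the mean percent change from switching modes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .variant_io import SampleProfile, VariantKey

__all__ = [
    "GermlineSet",
    "BurdenSummary",
    "build_pooled_normal",
    "matched_germline",
    "subtract_germline",
    "het_miss_probability",
    "expected_missed_germline",
    "summarize_burden",
    "burden_table",
]

_CLASS_COLS = ("SNV", "Ins", "Del", "All")


@dataclass(frozen=True)
class GermlineSet:
    """A set of germline variant keys with provenance."""

    source: str  # "matched" or "pooled"
    keys: frozenset
    contributing_samples: tuple

    def __post_init__(self) -> None:
        if self.source not in ("matched", "pooled"):
            raise ValueError(f"source must be matched|pooled, got {self.source!r}")

    def __len__(self) -> int:
        return len(self.keys)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self.keys


def matched_germline(normal: SampleProfile) -> GermlineSet:
    """Germline set from one patient's own (filtered) normal sample."""
    return GermlineSet(
        "matched", frozenset(normal.calls), (f"{normal.patient_id}:normal",)
    )


def build_pooled_normal(normals: list[SampleProfile]) -> GermlineSet:
    """Union of all normals' variant keys (the pooled-normal germline)."""
    if not normals:
        raise ValueError("need at least one normal profile to pool")
    keys: set = set()
    for n in normals:
        keys |= n.keys
    return GermlineSet(
        "pooled",
        frozenset(keys),
        tuple(f"{n.patient_id}:normal" for n in normals),
    )


def subtract_germline(tumour: SampleProfile, germline: GermlineSet) -> SampleProfile:
    """Retain exactly the tumour calls absent from the germline set."""
    kept = {k: c for k, c in tumour.calls.items() if k not in germline.keys}
    return replace(tumour, calls=kept)


def het_miss_probability(depth: int) -> float:
    """P(all reads at a heterozygous site show the reference allele).

    Equal allele sampling gives (1/2)^depth; at the cohort's lowest median
    normal depth of 15 this is ~3.05e-5, i.e. ~0.003% of heterozygous
    germline variants mis-called homozygous reference.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return 0.5 ** depth


def expected_missed_germline(depth: int, n_germline: int) -> float:
    """Expected germline variants missed at a given depth.

    Worst-case model: all ``n_germline`` sites heterozygous, each missed
    independently with probability (1/2)^depth.
    """
    if n_germline < 0:
        raise ValueError("n_germline must be >= 0")
    return n_germline * het_miss_probability(depth)


@dataclass
class BurdenSummary:
    """Matched vs pooled somatic burden accounting.

    ``per_sample`` is indexed by sample label with a two-level column
    index (mode in {matched, pooled} x class in {SNV, Ins, Del, All}).
    Means and the percent-change row are rounded half away from zero, the
    convention used for the published figures.
    """

    per_sample: pd.DataFrame
    mean_burden: dict = field(default_factory=dict)
    min_burden: dict = field(default_factory=dict)
    max_burden: dict = field(default_factory=dict)
    mean_pct_change: dict = field(default_factory=dict)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_burden(per_sample: pd.DataFrame) -> BurdenSummary:
    """Summarise per-sample somatic counts under both subtraction modes.

    ``per_sample`` must carry columns ``(mode, cls)`` for mode in
    {matched, pooled} and cls in {SNV, Ins, Del, All} (a MultiIndex), one
    row per tumour sample.  Samples with a matched count of zero in a
    class are excluded from that class's percent-change mean, with a
    warning.
    """
    for mode in ("matched", "pooled"):
        for cls in _CLASS_COLS:
            if (mode, cls) not in per_sample.columns:
                raise ValueError(f"missing column {(mode, cls)}")
    mean_burden = {
        mode: _round_half_away(per_sample[(mode, "All")].mean())
        for mode in ("matched", "pooled")
    }
    min_burden = {
        mode: int(per_sample[(mode, "All")].min()) for mode in ("matched", "pooled")
    }
    max_burden = {
        mode: int(per_sample[(mode, "All")].max()) for mode in ("matched", "pooled")
    }
    mean_pct = {}
    for cls in _CLASS_COLS:
        matched = per_sample[("matched", cls)]
        pooled = per_sample[("pooled", cls)]
        ok = matched > 0
        if not ok.all():
            warnings.warn(
                f"{(~ok).sum()} sample(s) with matched {cls} count 0 excluded "
                "from the percent-change mean",
                stacklevel=2,
            )
        pct = 100.0 * (pooled[ok] - matched[ok]) / matched[ok]
        mean_pct[cls] = _round_half_away(pct.mean()) if ok.any() else 0
    return BurdenSummary(per_sample, mean_burden, min_burden, max_burden, mean_pct)


def burden_table(
    matched_somatic: dict[str, SampleProfile],
    pooled_somatic: dict[str, SampleProfile],
) -> pd.DataFrame:
    """Build the per-sample count frame summarize_burden consumes.

    Both dicts map a sample label (e.g. ``"1: pre-NAC"``) to that tumour
    sample's somatic profile under the corresponding subtraction mode.
    """
    if set(matched_somatic) != set(pooled_somatic):
        raise ValueError("matched and pooled somatic sets cover different samples")
    cols = pd.MultiIndex.from_product([("matched", "pooled"), _CLASS_COLS])
    rows = {}
    for label in matched_somatic:
        m = matched_somatic[label].class_counts()
        p = pooled_somatic[label].class_counts()
        rows[label] = [m[c] for c in _CLASS_COLS] + [p[c] for c in _CLASS_COLS]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols).sort_index()
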