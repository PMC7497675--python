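"""Shared fixtures: hand-built variant objects and one small simulated cohort."""

from __future__ import annotations

import pytest

from chemoselect import (
    SampleProfile,
    SyntheticCohortConfig,
    VariantCall,
    VariantKey,
    generate_cohort,
)


def make_key(pos: int = 100, chrom: str = "1", ref: str = "A", alt: str = "T") -> VariantKey:
    return VariantKey(chrom, pos, ref, alt)


def make_call(
    pos: int = 100,
    depth: int = 30,
    alt_depth: int = 10,
    qual: float | None = 60.0,
    sample_id: str = "P1:pre",
    chrom: str = "1",
    ref: str = "A",
    alt: str = "T",
) -> VariantCall:
    return VariantCall(make_key(pos, chrom, ref, alt), sample_id, depth, alt_depth, qual)


def make_profile(calls, patient_id: str = "P1", timepoint: str = "pre") -> SampleProfile:
    p = SampleProfile(patient_id, timepoint)
    for c in calls:
        p.add(c)
    return p


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A compact synthetic cohort on disk with its planted truth."""
    outdir = tmp_path_factory.mktemp("cohort")
    cfg = SyntheticCohortConfig(
        n_genes=400, n_het=150, n_hom=50, n_passenger=60, seed=11
    )
    truth = generate_cohort(cfg, str(outdir))
    return cfg, str(outdir), truth
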