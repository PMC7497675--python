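"""Damaging predictions and the additive priority score (published table shape)."""

import pytest

from chemoselect import damaging_fraction, is_damaging, read_annotations, score_candidates
from chemoselect.gene_recurrence import GeneRecurrence, ListC, build_list_C
from chemoselect.prioritization import DamagingAnnotation, PriorityRecord
from chemoselect.therapy_selection import SomaticPair
from chemoselect.variant_io import VariantKey


class TestIsDamaging:
    @pytest.mark.parametrize(
        ("sift", "polyphen", "expected"),
        [
            (0.03, "benign", True),  # SIFT alone
            (0.50, "probably_damaging", True),  # PolyPhen2 alone
            (0.50, "possibly_damaging", True),  # possibly counts by default
            (0.50, "benign", False),
            (0.05, "benign", False),  # strict "below 0.05"
            (None, None, False),
            (0.01, None, True),
        ],
    )
    def test_either_tool_rule(self, sift, polyphen, expected):
        assert is_damaging(sift, polyphen) is expected

    def test_possibly_damaging_configurable(self):
        assert is_damaging(0.5, "possibly_damaging", count_possibly=False) is False

    def test_out_of_range_sift_rejected(self):
        with pytest.raises(ValueError):
            is_damaging(1.2, None)


def key(pos):
    return VariantKey("1", pos, "A", "T")


def pair(pos, patient="P1", group="A"):
    return SomaticPair(key(pos), patient, 0.4, None, group)


def ann(pos, sift=None, polyphen=None):
    return DamagingAnnotation(key(pos), sift, polyphen)


class TestDamagingFraction:
    def test_all_and_none(self):
        variants = [pair(i) for i in range(1, 4)]
        all_dam = {key(i): ann(i, sift=0.01) for i in range(1, 4)}
        none_dam = {key(i): ann(i, sift=0.9, polyphen="benign") for i in range(1, 4)}
        assert damaging_fraction(variants, all_dam) == (1.0, 0)
        assert damaging_fraction(variants, none_dam) == (0.0, 0)

    def test_partial_annotation_counted_separately(self):
        variants = [pair(i) for i in range(1, 13)]  # 12 variants, 10 annotated
        annotations = {key(i): ann(i, sift=0.01 if i <= 7 else 0.9) for i in range(1, 11)}
        frac, unannotated = damaging_fraction(variants, annotations)
        assert frac == pytest.approx(0.7)
        assert unannotated == 2


def entry(gene, direction, patients, n_extra_variants=0, start_pos=1):
    """Recurrence entry with one variant per patient plus optional extras."""
    pairs = [
        pair(start_pos + i, patient=p, group=direction)
        for i, p in enumerate(patients)
    ]
    pairs += [
        pair(start_pos + len(patients) + j, patient=patients[0], group=direction)
        for j in range(n_extra_variants)
    ]
    return GeneRecurrence(gene, direction, frozenset(patients), tuple(pairs))


def list_c_of(entries):
    return build_list_C(entries)


class TestScoreCandidates:
    def test_published_style_rows(self):
        entries = [
            entry("TCHH_LIKE", "A", ["P1", "P2", "P3"], start_pos=100),
            entry("COL6A3_LIKE", "A", ["P4", "P5"], start_pos=200),
            entry("DMBT1_LIKE", "A", ["P1", "P2", "P3", "P4"], start_pos=300),
            entry("DULL", "A", ["P5", "P6"], start_pos=400),
        ]
        annotations = {}
        for pos in (100, 101, 102):  # 3 tumours, 3 damaging
            annotations[key(pos)] = ann(pos, sift=0.01)
        for pos in (200, 201):  # 2 tumours, 2 damaging
            annotations[key(pos)] = ann(pos, polyphen="probably_damaging")
        annotations[key(300)] = ann(300, sift=0.02)  # 4 tumours, 1 damaging
        ranked, top = score_candidates(
            list_c_of(entries), annotations, {"COL6A3_LIKE": "collagen proteins"}
        )
        scores = {r.gene: r.score for r in ranked}
        assert scores["TCHH_LIKE"] == 6  # 3 + 3 + 0
        assert scores["COL6A3_LIKE"] == 5  # 2 + 2 + 1
        assert scores["DMBT1_LIKE"] == 5  # 4 + 1 + 0
        assert scores["DULL"] == 2  # 2 + 0 + 0, excluded at threshold 5
        assert {r.gene for r in top} == {"TCHH_LIKE", "COL6A3_LIKE", "DMBT1_LIKE"}
        col = next(r for r in ranked if r.gene == "COL6A3_LIKE")
        assert col.pathway_flag and col.pathway_name == "collagen proteins"

    def test_damaging_counts_variants_not_patients(self):
        # one patient contributes two damaging variants: n_damaging exceeds n_patients
        entries = [entry("G", "A", ["P1", "P2"], n_extra_variants=1)]
        annotations = {key(i): ann(i, sift=0.0) for i in (1, 2, 3)}
        ranked, _ = score_candidates(list_c_of(entries), annotations, {})
        assert ranked[0].n_damaging == 3
        assert ranked[0].score == 5

    def test_ranking_is_permutation_invariant_and_deterministic(self):
        entries = [
            entry(f"G{i}", "A", ["P1", "P2"], start_pos=10 * i) for i in range(1, 8)
        ]
        annotations = {}
        ranked_fwd, _ = score_candidates(list_c_of(entries), annotations, {})
        ranked_rev, _ = score_candidates(list_c_of(entries[::-1]), annotations, {})
        assert [r.gene for r in ranked_fwd] == [r.gene for r in ranked_rev]
        # equal evidence -> alphabetical order
        assert [r.gene for r in ranked_fwd] == sorted(r.gene for r in ranked_fwd)

    def test_score_invariant_enforced(self):
        with pytest.raises(ValueError, match="score"):
            PriorityRecord("G", "A", 2, 2, False, "", 7)

    def test_every_threshold_candidate_recomputes(self, small_cohort):
        import chemoselect as cs

        cfg, outdir, _ = small_cohort
        res = cs.run_pipeline(
            cs.PipelineConfig(input_dir=outdir, out_dir=outdir + "/run_prio", seed=1),
            stop_after="prioritize",
        )
        for r in res.top_candidates:
            assert r.score == r.n_patients + r.n_damaging + (1 if r.pathway_flag else 0)
            assert r.score >= 5


class TestAnnotationIO:
    def test_round_trip_and_validation(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tsift_score\tpolyphen_call\n"
            "1\t100\tA\tT\t0.01\tbenign\n"
            "1\t200\tC\tG\t\tprobably_damaging\n"
            "2\t300\tG\tA\t0.9\t\n"
        )
        table = read_annotations(str(path))
        assert table[VariantKey("1", 100, "A", "T")].damaging
        assert table[VariantKey("1", 200, "C", "G")].damaging
        assert not table[VariantKey("2", 300, "G", "A")].damaging

    def test_bad_sift_reports_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "chrom\tpos\tref\talt\tsift_score\tpolyphen_call\n1\t100\tA\tT\t2.0\tbenign\n"
        )
        with pytest.raises(ValueError, match="row 2"):
            read_annotations(str(path))
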