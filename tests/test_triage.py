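"""Unit tests for paired subtraction, filters, classification, TMB, spectrum."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skinmut.triage import (
    FilterParams,
    apply_quality_filters,
    classify_loci,
    compare_group_location,
    compute_tmb,
    mutation_status_matrix,
    remove_germline_blacklist,
    restrict_to_target,
    substitution_spectrum,
    subtract_paired,
    tmb_summary,
    top_mutated_genes,
)
from conftest import make_call


class TestSubtractPaired:
    def test_removes_shared_locus(self):
        v1 = make_call(pos=100)
        v2 = make_call(pos=200)
        blood = [make_call(sample_id="B1", pos=200)]
        assert subtract_paired([v1, v2], blood) == [v1]

    def test_empty_tissue(self):
        assert subtract_paired([], [make_call(sample_id="B1")]) == []

    def test_allele_aware_same_position(self):
        # A>C and A>G at the same position are different loci
        tissue = [make_call(pos=50, ref="A", alt="C")]
        blood = [make_call(sample_id="B1", pos=50, ref="A", alt="G")]
        assert subtract_paired(tissue, blood) == tissue

    def test_brute_force_key_comparison(self):
        rng = np.random.default_rng(0)
        tissue = [
            make_call(pos=int(p), ref="A", alt="ACGT"[a])
            for p, a in zip(rng.integers(1, 50, 60), rng.integers(1, 4, 60))
        ]
        blood = [
            make_call(sample_id="B1", pos=int(p), ref="A", alt="ACGT"[a])
            for p, a in zip(rng.integers(1, 50, 30), rng.integers(1, 4, 30))
        ]
        expected = [
            t
            for t in tissue
            if not any(
                t.chrom == b.chrom and t.pos == b.pos and t.ref == b.ref
                and t.alt == b.alt
                for b in blood
            )
        ]
        assert subtract_paired(tissue, blood) == expected

    def test_pairing_mismatch_errors(self):
        tissue = [make_call(sample_id="S1"), make_call(sample_id="S2", pos=5)]
        with pytest.raises(ValueError, match="mix samples"):
            subtract_paired(tissue, [])
        with pytest.raises(ValueError, match="expected"):
            subtract_paired([make_call(sample_id="S1")], [], tissue_id="S9")


class TestQualityFilters:
    @pytest.mark.parametrize(
        "coverage,count,q,kept",
        [
            (9, 5, 80.0, False),  # below minimum coverage of 10
            (100, 2, 60.0, True),  # every threshold at its boundary
            (100, 1, 80.0, False),  # below minimum count of 2
            (100, 50, 59.9, False),  # below Q60
        ],
    )
    def test_thresholds_are_inclusive_minima(self, coverage, count, q, kept):
        call = make_call(coverage=coverage, count=count, q_score=q)
        result = apply_quality_filters([call], FilterParams())
        assert (call in result) is kept

    def test_frequency_threshold(self):
        low = make_call(coverage=1000, count=10)  # 1% < 2%
        boundary = make_call(coverage=1000, count=20)  # exactly 2%
        assert apply_quality_filters([low, boundary]) == [boundary]

    def test_missing_field_names_sample_and_locus(self):
        call = make_call(sample_id="T07", chrom="chr3", pos=777)
        call.q_score = None
        with pytest.raises(ValueError, match="q_score on T07 chr3:777"):
            apply_quality_filters([call])

    @given(
        min_q=st.floats(min_value=0, max_value=200),
        tighter=st.floats(min_value=0, max_value=50),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotonicity_in_min_q(self, min_q, tighter):
        rng = np.random.default_rng(7)
        calls = [
            make_call(pos=i, coverage=100, count=10, q_score=float(q))
            for i, q in enumerate(rng.uniform(0, 200, 40), start=1)
        ]
        loose = apply_quality_filters(calls, FilterParams(min_q=min_q))
        strict = apply_quality_filters(
            calls, FilterParams(min_q=min_q + tighter)
        )
        assert set(id(c) for c in strict) <= set(id(c) for c in loose)


class TestTargetRestriction:
    def test_coordinate_conversion(self):
        # BED chr9 97 100 covers 1-based positions 98..100
        bed = [("chr9", 97, 100)]
        inside = make_call(chrom="chr9", pos=98)
        assert restrict_to_target([inside], bed) == [inside]

    def test_boundary_outside(self):
        bed = [("chr9", 97, 100)]
        outside = make_call(chrom="chr9", pos=101)
        assert restrict_to_target([outside], bed) == []

    def test_unknown_chromosome_dropped_not_raised(self, caplog):
        bed = [("chr1", 0, 1000)]
        call = make_call(chrom="chrUn", pos=5)
        with caplog.at_level("WARNING"):
            assert restrict_to_target([call], bed) == []
        assert "chrUn" in caplog.text

    def test_agrees_with_brute_force_scan(self):
        rng = np.random.default_rng(3)
        bed = [
            ("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 5000, 30), rng.integers(1, 200, 30))
        ]
        calls = [
            make_call(chrom="chr1", pos=int(p))
            for p in rng.integers(1, 5500, 300)
        ]
        expected = [
            c for c in calls
            if any(s < c.pos <= e for _, s, e in bed)
        ]
        assert restrict_to_target(calls, bed) == expected


class TestBlacklist:
    def test_empty_blacklist_is_identity(self):
        calls = [make_call(pos=i) for i in range(1, 5)]
        assert remove_germline_blacklist(calls, frozenset()) == calls

    def test_set_oracle_on_random_calls(self):
        rng = np.random.default_rng(11)
        calls = [
            make_call(pos=int(p), alt="ACGT"[a] if "ACGT"[a] != "C" else "G")
            for p, a in zip(rng.integers(1, 400, 1000), rng.integers(0, 4, 1000))
        ]
        blacklist = frozenset(c.locus for c in calls[:100])
        kept = remove_germline_blacklist(calls, blacklist)
        assert kept == [c for c in calls if c.locus not in blacklist]


class TestClassifyLoci:
    def _callsets(self):
        t1 = [make_call(sample_id="T1", pos=1), make_call(sample_id="T1", pos=2)]
        t2 = [make_call(sample_id="T2", pos=1)]
        h1 = [make_call(sample_id="H1", pos=2), make_call(sample_id="H1", pos=3)]
        return {"T1": t1, "T2": t2}, {"H1": h1}

    def test_three_way_partition(self):
        tumors, healthy = self._callsets()
        result = classify_loci(tumors, healthy)
        by_pos = {l[1]: c for l, c in result.category.items()}
        assert by_pos == {1: "NMSC_ONLY", 2: "SHARED", 3: "HEALTHY_ONLY"}
        total = sum(len(result.loci_in(c)) for c in
                    ("NMSC_ONLY", "SHARED", "HEALTHY_ONLY"))
        assert total == len(result.category)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty cohort"):
            classify_loci({}, {})

    def test_random_partition_property(self):
        rng = np.random.default_rng(5)
        tumors = {
            f"T{i}": [make_call(sample_id=f"T{i}", pos=int(p))
                      for p in rng.integers(1, 60, 25)]
            for i in range(4)
        }
        healthy = {
            f"H{i}": [make_call(sample_id=f"H{i}", pos=int(p))
                      for p in rng.integers(1, 60, 25)]
            for i in range(3)
        }
        result = classify_loci(tumors, healthy)
        all_loci = {c.locus for calls in (*tumors.values(), *healthy.values())
                    for c in calls}
        assert set(result.category) == all_loci
        for locus, cat in result.category.items():
            in_t = any(locus in {c.locus for c in v} for v in tumors.values())
            in_h = any(locus in {c.locus for c in v} for v in healthy.values())
            expected = ("SHARED" if in_t and in_h
                        else "NMSC_ONLY" if in_t else "HEALTHY_ONLY")
            assert cat == expected


class TestMutationStatus:
    def test_synonymous_does_not_count(self):
        t = [make_call(sample_id="T1", gene="PTCH1", nonsynonymous=False)]
        triage = classify_loci({"T1": t}, {"H1": []})
        status = mutation_status_matrix(triage, ["PTCH1"])
        assert status.loc["T1", "PTCH1"] == 0

    def test_stop_gain_counts_as_nonsynonymous(self):
        t = [make_call(sample_id="T1", gene="PTCH1", aa_change="p.Gln184*")]
        triage = classify_loci({"T1": t}, {"H1": []})
        status = mutation_status_matrix(triage, ["PTCH1"])
        assert status.loc["T1", "PTCH1"] == 1

    def test_shared_locus_does_not_count(self):
        t = [make_call(sample_id="T1", gene="PTCH1", nonsynonymous=True)]
        h = [make_call(sample_id="H1", gene="PTCH1", nonsynonymous=True)]
        triage = classify_loci({"T1": t}, {"H1": h})
        status = mutation_status_matrix(triage, ["PTCH1"])
        assert status.loc["T1", "PTCH1"] == 0

    def test_sample_without_calls_is_all_zero(self):
        t = [make_call(sample_id="T1", gene="PTCH1", nonsynonymous=True)]
        triage = classify_loci({"T1": t, "T2": []}, {"H1": []})
        status = mutation_status_matrix(triage, ["PTCH1"])
        assert status.loc["T2"].sum() == 0
        assert status.loc["H1"].sum() == 0

    def test_unknown_gene_errors(self):
        t = [make_call(sample_id="T1", gene="PTCH1", nonsynonymous=True)]
        triage = classify_loci({"T1": t}, {"H1": []})
        with pytest.raises(KeyError, match="NOSUCH"):
            mutation_status_matrix(triage, ["NOSUCH"])


class TestTmb:
    def test_reported_group_medians(self):
        # median somatic counts per group over a 1.7 Mb panel
        assert tmb_summary({"a": 148}, {"a": "BCC"}).loc["BCC", "median_tmb"] == 87
        even = tmb_summary({"a": 180, "b": 181}, {"a": "SCC", "b": "SCC"})
        assert even.loc["SCC", "median_tmb"] == 106
        assert tmb_summary({"a": 140}, {"a": "healthy"}).loc[
            "healthy", "median_tmb"] == 82

    def test_zero_and_linearity(self):
        assert compute_tmb(0, 1.7) == 0
        assert compute_tmb(2 * 37, 1.7) == pytest.approx(2 * compute_tmb(37, 1.7))

    def test_invalid_panel(self):
        with pytest.raises(ValueError):
            compute_tmb(10, 0)


class TestSpectrum:
    def test_single_class(self):
        calls = {"S1": [make_call(pos=i, ref="C", alt="T") for i in range(1, 5)]}
        per_sample, _ = substitution_spectrum(calls)
        assert per_sample.loc["S1", "C>T"] == 100.0
        assert per_sample.loc["S1"].drop("C>T").sum() == 0.0

    def test_even_split(self):
        calls = {"S1": [
            make_call(pos=1, ref="C", alt="T"),
            make_call(pos=2, ref="C", alt="T"),
            make_call(pos=3, ref="G", alt="A"),
            make_call(pos=4, ref="G", alt="A"),
        ]}
        per_sample, _ = substitution_spectrum(calls)
        assert per_sample.loc["S1", "C>T"] == 50.0
        assert per_sample.loc["S1", "G>A"] == 50.0

    def test_indels_ignored_and_rows_sum_100(self):
        rng = np.random.default_rng(9)
        refs = np.array(list("ACGT"))[rng.integers(0, 4, 200)]
        calls = []
        for i, r in enumerate(refs, start=1):
            alt = "ACGT"[(("ACGT".index(r)) + int(rng.integers(1, 4))) % 4]
            calls.append(make_call(pos=i, ref=r, alt=alt))
        calls.append(make_call(pos=999, ref="A", alt="AT"))  # insertion
        per_sample, _ = substitution_spectrum({"S1": calls})
        assert per_sample.loc["S1"].sum() == pytest.approx(100.0)
        # brute-force tally over the SNVs only
        from collections import Counter
        tally = Counter(f"{c.ref}>{c.alt}" for c in calls if c.vtype == "SNV")
        for cls, n in tally.items():
            assert per_sample.loc["S1", cls] == pytest.approx(100 * n / 200)

    def test_zero_snv_sample_excluded(self):
        per_sample, _ = substitution_spectrum(
            {"S1": [make_call(ref="A", alt="AT")], "S2": [make_call()]}
        )
        assert list(per_sample.index) == ["S2"]


class TestKruskalWallis:
    def test_identical_groups_p_one(self):
        h, p = compare_group_location({"a": [1, 2, 3], "b": [1, 2, 3]})
        assert p == pytest.approx(1.0, abs=0.05)

    def test_all_identical_values_convention(self):
        h, p = compare_group_location({"a": [5, 5], "b": [5, 5]})
        assert (h, p) == (0.0, 1.0)

    def test_hand_computed_rank_statistic(self):
        # ranks 1..6, R1=6, R2=15: H = 12/42*(12+75) - 21 = 27/7
        h, p = compare_group_location({"a": [1, 2, 3], "b": [10, 11, 12]})
        assert h == pytest.approx(27 / 7, rel=1e-12)
        assert p == pytest.approx(0.0495, abs=2e-4)

    def test_order_invariance(self):
        a = {"x": [3, 1, 2], "y": [9, 7, 8]}
        b = {"x": [1, 2, 3], "y": [7, 8, 9]}
        assert compare_group_location(a) == compare_group_location(b)

    def test_too_few_groups(self):
        with pytest.raises(ValueError):
            compare_group_location({"only": [1, 2]})


class TestTopMutatedGenes:
    def test_percentage_arithmetic(self):
        tumors = {
            f"T{i}": [make_call(sample_id=f"T{i}", gene="PTCH1")]
            for i in range(13)
        }
        tumors.update({f"T{i}": [] for i in range(13, 26)})
        triage = classify_loci(tumors, {"H1": []})
        top = top_mutated_genes(triage, "NMSC_ONLY", 5)
        assert top == [("PTCH1", pytest.approx(50.0))]

    def test_k_larger_than_gene_count(self):
        tumors = {"T1": [make_call(sample_id="T1", gene="A"),
                         make_call(sample_id="T1", pos=2, gene="B")]}
        triage = classify_loci(tumors, {"H1": []})
        assert len(top_mutated_genes(triage, "NMSC_ONLY", 99)) == 2

    def test_ties_alphabetical_and_counting_oracle(self):
        rng = np.random.default_rng(21)
        genes = ["ALPHA", "BETA", "GAMMA"]
        tumors = {}
        incidence = {g: set() for g in genes}
        for i in range(10):
            sid = f"T{i}"
            calls = []
            for j, g in enumerate(genes):
                if rng.random() < 0.5:
                    calls.append(make_call(sample_id=sid, pos=1000 * i + j,
                                           gene=g))
                    incidence[g].add(sid)
            tumors[sid] = calls
        triage = classify_loci(tumors, {"H1": []})
        top = top_mutated_genes(triage, "NMSC_ONLY", 10)
        expected = sorted(
            ((g, 100.0 * len(s) / 10) for g, s in incidence.items() if s),
            key=lambda t: (-t[1], t[0]),
        )
        assert [(g, pytest.approx(p)) for g, p in expected] == top

    def test_empty_category(self):
        triage = classify_loci({"T1": [make_call(sample_id="T1", gene="A")]},
                               {"H1": []})
        assert top_mutated_genes(triage, "HEALTHY_ONLY", 3) == []
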