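"""Haplotype sorting, depth/coverage gates, masking, imputation, logit."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from asmbs.align import AlignedRead
from asmbs.haplo import (
    ALT,
    REF,
    HaploMethMatrix,
    apply_depth_filter,
    build_matrix,
    check_target_coverage,
    impute_missing,
    logit_transform,
    mask_cpg_snps,
    matrix_from_tsv,
    matrix_to_tsv,
    methylation_rates,
    split_by_allele,
    to_logit,
    usable_sorting_snp,
)
from asmbs.targets import SnpDef, TargetDef


def _target(snps=(), seq="ATTAGCAATTCGGCATTAACGAATTGGCAA"):
    return TargetDef(
        "T1", "cg0", "c", 1, len(seq), "+", seq.count("CG"),
        snps=list(snps), reference_seq=seq,
    )


def _ar(rid, sample, alleles=None, meth=None, gene="T1"):
    return AlignedRead(
        read_id=rid, sample=sample, gene_label=gene, cigar="5M",
        aligned_start=1, score=0.0, identity=1.0,
        methylation_calls=dict(meth or {}),
        allele_calls=dict(alleles or {}),
        cph_total=10, cph_unconverted=0, mismatches=0,
    )


SNP = SnpDef("rs1", 5, "A", "G")


class TestSplitByAllele:
    def test_homozygote_single_row(self):
        t = _target([SNP])
        reads = [_ar(f"r{i}", "s1", {"rs1": "ref"}) for i in range(6)]
        groups, excluded = split_by_allele(reads, t)
        assert set(groups) == {("s1", REF)}
        assert len(groups[("s1", REF)]) == 6
        assert excluded == 0

    def test_heterozygote_two_rows_with_depths(self):
        t = _target([SNP])
        reads = [_ar(f"a{i}", "s1", {"rs1": "ref"}) for i in range(6)]
        reads += [_ar(f"b{i}", "s1", {"rs1": "alt"}) for i in range(7)]
        groups, _ = split_by_allele(reads, t)
        assert len(groups[("s1", REF)]) == 6
        assert len(groups[("s1", ALT)]) == 7

    def test_unknown_calls_excluded_for_heterozygote(self):
        t = _target([SNP])
        reads = [_ar(f"a{i}", "s1", {"rs1": "ref"}) for i in range(5)]
        reads += [_ar(f"b{i}", "s1", {"rs1": "alt"}) for i in range(5)]
        reads += [_ar("u1", "s1", {"rs1": "unknown"})]
        groups, excluded = split_by_allele(reads, t)
        assert excluded == 1
        assert len(groups[("s1", REF)]) == 5

    def test_multi_snp_conflict_excluded(self):
        snp2 = SnpDef("rs2", 10, "A", "T")
        t = _target([SNP, snp2])
        reads = [_ar(f"a{i}", "s1", {"rs1": "ref", "rs2": "ref"}) for i in range(5)]
        reads += [_ar(f"b{i}", "s1", {"rs1": "alt", "rs2": "alt"}) for i in range(5)]
        # one read whose rs2 call conflicts with the ref-group consensus
        reads += [_ar("x", "s1", {"rs1": "ref", "rs2": "alt"})]
        groups, excluded = split_by_allele(reads, t)
        assert excluded == 1
        assert all(r.read_id != "x" for r in groups[("s1", REF)])

    def test_truth_round_trip(self, tiny_targets, tiny_cohort, clean_run):
        from asmbs import reads as rd
        from asmbs.align import AmpliconAligner

        t = tiny_targets[0]
        aligner = AmpliconAligner(tiny_targets)
        truth = clean_run.truth.set_index("read_id")
        aligned = []
        for r in clean_run.libraries[0].reads:
            if truth.loc[r.read_id, "target"] != t.gene_label:
                continue
            insert = rd.trim_flanks(r)
            ar = aligner.align_insert(insert.sequence, read_id=r.read_id)
            ar.sample = truth.loc[r.read_id, "subject"]
            aligned.append(ar)
        groups, excluded = split_by_allele(aligned, t)
        assert excluded == 0
        for (sample, allele), grp in groups.items():
            for ar in grp:
                assert truth.loc[ar.read_id, "sort_allele"] == allele


class TestMethylationRates:
    def test_all_methylated(self):
        reads = [_ar(f"r{i}", "s", meth={3: 1}) for i in range(5)]
        m, d = methylation_rates(reads, [3])
        assert m[3] == 1.0
        assert d[3] == 5

    def test_fraction(self):
        reads = [_ar(f"r{i}", "s", meth={3: int(i < 2)}) for i in range(8)]
        m, _ = methylation_rates(reads, [3])
        assert m[3] == pytest.approx(0.25)

    def test_missing_excluded_from_denominator(self):
        reads = [_ar("a", "s", meth={3: 1}), _ar("b", "s", meth={3: -1})]
        m, d = methylation_rates(reads, [3])
        assert m[3] == 1.0
        assert d[3] == 1

    def test_rates_converge_to_truth(self, tiny_targets, tiny_cohort):
        from asmbs import synth

        subs = tiny_cohort[:2]
        mat = synth.sample_haplo_matrix(subs, tiny_targets[:1], depth=200, seed=8)
        label = tiny_targets[0].gene_label
        for s in subs:
            p_true = s.meth_probs[label].mean(axis=0)
            rows = mat.rates[label].xs(s.subject_id, level="sample")
            got = rows.mean(axis=0).to_numpy()
            se = np.sqrt(p_true * (1 - p_true) / 200) + 1e-3
            assert (np.abs(got - p_true) < 4 * se).mean() > 0.9


def _matrix(values, depths=None, row_depth=None, n=10, label="T1"):
    idx = pd.MultiIndex.from_tuples(
        [(f"s{i}", REF) for i in range(len(values))], names=["sample", "allele"]
    )
    rates = pd.DataFrame(values, index=idx)
    cell = pd.DataFrame(
        depths if depths is not None else np.full_like(rates, 10, dtype=int),
        index=idx, columns=rates.columns,
    )
    rd_ = pd.Series(row_depth if row_depth is not None else 10, index=idx)
    return HaploMethMatrix({label: rates}, {label: cell}, {label: rd_}, n)


class TestDepthAndCoverage:
    def test_depth_exactly_five_retained(self):
        mat = _matrix([[0.5], [0.5]], row_depth=[5, 4])
        out, removed = apply_depth_filter(mat, min_depth=5)
        assert len(out.rates["T1"]) == 1
        assert removed == [("T1", "s1", REF)]

    def test_starved_target_dropped(self):
        mat = _matrix([[0.5]] * 2)
        out, dropped = check_target_coverage(
            mat, [f"s{i}" for i in range(10)], min_sample_fraction=0.8
        )
        assert dropped == ["T1"]
        assert out.targets() == []

    def test_well_covered_retained(self):
        mat = _matrix([[0.5]] * 10)
        out, dropped = check_target_coverage(mat, [f"s{i}" for i in range(10)])
        assert dropped == []

    def test_zero_fraction_drops_nothing(self):
        mat = _matrix([[0.5]])
        out, dropped = check_target_coverage(mat, ["a", "b"], min_sample_fraction=0)
        assert dropped == []


class TestMasking:
    def test_cpg_snp_column_removed(self):
        t = _target([SnpDef("c1", 11, "C", "A", is_cpg_snp=True)])
        idx = pd.MultiIndex.from_tuples([("s0", REF)], names=["sample", "allele"])
        rates = pd.DataFrame([[0.1, 0.2, 0.3]], index=idx, columns=[11, 20, 25])
        cell = pd.DataFrame([[5, 5, 5]], index=idx, columns=[11, 20, 25])
        mat = HaploMethMatrix({"T1": rates}, {"T1": cell}, {"T1": pd.Series(5, idx)}, 1)
        out = mask_cpg_snps(mat, [t])
        assert list(out.rates["T1"].columns) == [20, 25]
        again = mask_cpg_snps(out, [t])
        assert list(again.rates["T1"].columns) == [20, 25]  # idempotent

    def test_no_cpg_snps_unchanged(self):
        mat = _matrix([[0.5, 0.6]])
        out = mask_cpg_snps(mat, [_target([SNP])])
        assert list(out.rates["T1"].columns) == list(mat.rates["T1"].columns)


class TestImputation:
    def test_column_mean(self):
        mat = _matrix([[0.2], [np.nan], [0.4]])
        out = impute_missing(mat)
        assert out.rates["T1"].iloc[1, 0] == pytest.approx(0.3)

    def test_identity_without_missing(self):
        mat = _matrix([[0.2], [0.4]])
        out = impute_missing(mat)
        pd.testing.assert_frame_equal(out.rates["T1"], mat.rates["T1"])

    def test_observed_cells_bitwise_unchanged(self):
        vals = np.array([[0.123456789, np.nan], [0.987654321, 0.5]])
        mat = _matrix(vals)
        out = impute_missing(mat)
        assert out.rates["T1"].iloc[0, 0] == vals[0, 0]
        assert out.rates["T1"].iloc[1, 0] == vals[1, 0]

    def test_column_means_preserved(self):
        mat = _matrix([[0.2, 0.1], [np.nan, 0.3], [0.4, np.nan]])
        out = impute_missing(mat)
        np.testing.assert_allclose(
            out.rates["T1"].mean(axis=0), mat.rates["T1"].mean(axis=0)
        )

    def test_fully_missing_column_errors(self):
        mat = _matrix([[np.nan], [np.nan]])
        with pytest.raises(ValueError, match="T1"):
            impute_missing(mat)


class TestLogitTransform:
    def test_half_is_zero(self):
        for n in (1, 2, 154, 1000):
            assert logit_transform(0.5, n) == pytest.approx(0.0)

    def test_value_at_one_for_study_n(self):
        # m' = (1*(154-1)+0.5)/154 = 153.5/154, M = ln(153.5/0.5) = ln(307)
        assert logit_transform(1.0, 154) == pytest.approx(np.log(307.0), abs=1e-12)

    @given(
        m=st.floats(0.0, 1.0, allow_nan=False),
        n=st.integers(1, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_antisymmetry(self, m, n):
        assert logit_transform(m, n) == pytest.approx(
            -logit_transform(1.0 - m, n), abs=1e-9
        )

    @given(n=st.integers(1, 5000))
    @settings(max_examples=50, deadline=None)
    def test_extreme_bound(self, n):
        bound = np.log((n - 0.5) / 0.5)
        assert abs(logit_transform(1.0, n)) == pytest.approx(bound)
        assert abs(logit_transform(0.0, n)) == pytest.approx(bound)

    def test_strictly_increasing(self):
        ms = np.linspace(0, 1, 50)
        M = logit_transform(ms, 154)
        assert np.all(np.diff(M) > 0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            logit_transform(0.5, 0)
        with pytest.raises(ValueError):
            logit_transform(1.5, 10)

    def test_to_logit_uses_matrix_n(self):
        mat = _matrix([[0.5], [1.0]], n=154)
        out = to_logit(mat)["T1"]
        assert out.iloc[0, 0] == pytest.approx(0.0)
        assert out.iloc[1, 0] == pytest.approx(np.log(307.0))


class TestSerialization:
    def test_tsv_round_trip(self, tmp_path):
        mat = _matrix([[0.25, np.nan], [0.75, 0.5]], n=7)
        p = tmp_path / "m.tsv"
        matrix_to_tsv(mat, p)
        back = matrix_from_tsv(p)
        assert back.n == 7
        pd.testing.assert_frame_equal(
            back.rates["T1"], mat.rates["T1"], check_names=False
        )


class TestRowCounts:
    def test_row_budget(self, tiny_targets, tiny_cohort):
        from asmbs import synth

        mat = synth.sample_haplo_matrix(tiny_cohort, tiny_targets, depth=20, seed=3)
        n_rows = sum(len(df) for df in mat.rates.values())
        assert n_rows <= 2 * len(tiny_cohort) * len(tiny_targets)
        for df in mat.rates.values():
            per_sample = df.groupby(level="sample").size()
            assert per_sample.isin([1, 2]).all()

    def test_usable_sorting_snp_skips_collapsed(self):
        t = _target([SnpDef("ct", 5, "C", "T"), SnpDef("ag", 10, "A", "G")])
        assert usable_sorting_snp(t).snp_id == "ag"
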