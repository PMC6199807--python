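"""Bisulfite-aware alignment: DP scores vs a brute-force oracle, methylation
and allele calling, conversion QC and de-duplication."""

import numpy as np
import pytest

from asmbs import reads as rd
from asmbs.align import (
    AlignedRead,
    AmpliconAligner,
    call_allele,
    conversion_rate,
    convert_reference,
    deduplicate,
    filter_conversion,
    gotoh_align,
    read_sam,
    write_sam,
)
from asmbs.targets import SnpDef, TargetDef


def gotoh_oracle(a, b, match=2.0, mismatch=-4.0, go=-6.0, ge=-1.0):
    """Unbanded affine-gap global alignment score by explicit recursion."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = go + ge * i
    for j in range(1, m + 1):
        Y[0][j] = go + ge * j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(M[i - 1][j] + go + ge, X[i - 1][j] + ge)
            Y[i][j] = max(M[i][j - 1] + go + ge, Y[i][j - 1] + ge)
    return max(M[n][m], X[n][m], Y[n][m])


class TestConvertReference:
    @pytest.mark.parametrize("seq,out", [("ACGC", "ATGT"), ("TTTT", "TTTT")])
    def test_examples(self, seq, out):
        assert convert_reference(seq) == out

    def test_idempotent(self):
        s = "ACGTNCCGG"
        assert convert_reference(convert_reference(s)) == convert_reference(s)

    def test_bad_characters(self):
        with pytest.raises(ValueError):
            convert_reference("ACGX")


class TestGotohVsOracle:
    def test_random_pairs_match_oracle(self):
        rng = np.random.default_rng(42)
        bases = np.array(list("ACGT"))
        for _ in range(40):
            n = int(rng.integers(4, 18))
            a = "".join(rng.choice(bases, n))
            # mutate a into b: substitutions and small indels
            b = list(a)
            for _ in range(int(rng.integers(0, 4))):
                op = rng.integers(0, 3)
                pos = int(rng.integers(0, max(1, len(b))))
                if op == 0 and b:
                    b[pos] = str(rng.choice(bases))
                elif op == 1 and b:
                    del b[pos]
                else:
                    b.insert(pos, str(rng.choice(bases)))
            b = "".join(b) or "A"
            expected = gotoh_oracle(a, b)
            score_full, _, _ = gotoh_align(a, b, band=None)
            score_band, _, _ = gotoh_align(a, b, band=10)
            assert score_full == pytest.approx(expected)
            # the true alignment fits a band of 10 for these small edits
            assert score_band == pytest.approx(expected)

    def test_identical_sequences(self):
        s = "ACGTACGTAAGG"
        score, cigar, ref2read = gotoh_align(s, s)
        assert score == 2.0 * len(s)
        assert cigar == f"{len(s)}M"
        assert list(ref2read) == list(range(len(s)))

    def test_deletion_appears_in_cigar(self):
        ref = "ACGTACGTTTACGGATCC"
        query = ref[:6] + ref[8:]  # 2 bp deletion
        score, cigar, _ = gotoh_align(query, ref)
        assert "2D" in cigar
        assert score == pytest.approx(gotoh_oracle(query, ref))


def _plus_target(seq, snps=()):
    return TargetDef(
        gene_label="T1",
        reference_cpg="cg0",
        chrom="c",
        start=1,
        end=len(seq),
        strand="+",
        expected_cpg_count=seq.count("CG"),
        snps=list(snps),
        reference_seq=seq,
    )


class TestAlignInsert:
    def test_fully_methylated_round_trip(self, tiny_targets):
        t = tiny_targets[0]
        aligner = AmpliconAligner(tiny_targets)
        ar = aligner.align_insert(t.reference_seq, read_id="r0")
        assert ar.gene_label == t.gene_label
        assert ar.cigar == f"{len(t.reference_seq)}M"
        assert all(v == 1 for v in ar.methylation_calls.values())
        assert ar.cph_unconverted == ar.cph_total  # nothing converted here

    def test_converted_read_calls_unmethylated(self, tiny_targets):
        t = tiny_targets[0]
        aligner = AmpliconAligner(tiny_targets)
        ar = aligner.align_insert(convert_reference(t.reference_seq))
        assert all(v == 0 for v in ar.methylation_calls.values())
        assert ar.cph_unconverted == 0

    def test_simulated_reads_assigned_to_true_target(self, tiny_targets, clean_run):
        aligner = AmpliconAligner(tiny_targets)
        truth = clean_run.truth.set_index("read_id")
        reads = clean_run.libraries[0].reads[:60]
        for r in reads:
            insert = rd.trim_flanks(r)
            ar = aligner.align_insert(insert.sequence, read_id=r.read_id)
            assert ar.gene_label == truth.loc[r.read_id, "target"]

    def test_junk_is_unmapped(self, tiny_targets):
        aligner = AmpliconAligner(tiny_targets, min_identity=0.8)
        rng = np.random.default_rng(1)
        junk = "".join(rng.choice(list("ACGT"), 300))
        assert aligner.align_insert(junk) is None


class TestCallAllele:
    def _aligned(self, target):
        aligner = AmpliconAligner([target])
        return aligner.align_insert(target.reference_seq)

    def test_ag_snp_plus_strand(self):
        seq = "ATTAGCAATTGGCATTAA"
        t = _plus_target(seq, [SnpDef("rs1", 5, "G", "A")])  # ref base G at pos 5
        ar = self._aligned(t)
        assert ar.allele_calls["rs1"] == "ref"
        alt_seq = seq[:4] + "A" + seq[5:]
        ar2 = AmpliconAligner([t]).align_insert(alt_seq)
        assert ar2.allele_calls["rs1"] == "alt"

    def test_ct_snp_plus_strand_always_unknown(self):
        seq = "ATTACCAATTGGCATTAA"
        t = _plus_target(seq, [SnpDef("rs2", 5, "C", "T")])
        ar = self._aligned(t)
        assert ar.allele_calls["rs2"] == "unknown"

    def test_ga_snp_minus_strand_always_unknown(self):
        # plus-strand G/A on a minus-strand amplicon reads as C/T on the
        # amplified strand and collapses away
        seq = "ATTAGCAATTGGCATTAA"
        t = TargetDef(
            "T2", "cg0", "c", 1, len(seq), "-", 0,
            snps=[SnpDef("rs3", 5, "G", "A")],
            reference_seq=seq,
        )
        ar = AmpliconAligner([t]).align_insert(seq)
        assert ar.allele_calls["rs3"] == "unknown"

    def test_snp_in_deletion_unknown(self):
        seq = "ATTAGCAATTGGCATTAAGGCC"
        t = _plus_target(seq, [SnpDef("rs4", 5, "G", "A")])
        query = seq[:3] + seq[7:]  # deletion spanning the SNP
        ar = AmpliconAligner([t], min_identity=0.5).align_insert(query)
        assert ar.allele_calls["rs4"] == "unknown"

    def test_snp_outside_target_errors(self):
        seq = "ATTAGCAATTGGCATTAA"
        t = _plus_target(seq)
        ar = self._aligned(t)
        with pytest.raises(ValueError, match="outside"):
            call_allele(ar, SnpDef("rs9", 999, "A", "G"))


def _ar(rid="r", sample="s", gene="T1", start=1, cigar="10M",
        meth=None, alleles=None, cph=(100, 0)):
    return AlignedRead(
        read_id=rid,
        sample=sample,
        gene_label=gene,
        cigar=cigar,
        aligned_start=start,
        score=0.0,
        identity=1.0,
        methylation_calls=dict(meth or {}),
        allele_calls=dict(alleles or {}),
        cph_total=cph[0],
        cph_unconverted=cph[1],
        mismatches=0,
    )


class TestConversionFilter:
    def test_strictly_below_threshold_passes(self):
        assert filter_conversion(_ar(cph=(100, 4)))

    def test_exactly_five_percent_fails(self):
        assert not filter_conversion(_ar(cph=(100, 5)))

    def test_zero_cph_vacuous_pass(self):
        assert filter_conversion(_ar(cph=(0, 0)))

    def test_conversion_rate_pooled(self):
        reads = [_ar(rid="a", cph=(50, 0)), _ar(rid="b", cph=(50, 2))]
        assert conversion_rate(reads) == pytest.approx(0.98)
        assert conversion_rate([_ar(cph=(0, 0))]) is None
        assert conversion_rate([_ar(cph=(10, 10))]) == 0.0


class TestDeduplicate:
    def test_identical_copies_collapse(self):
        a = _ar(rid="a", meth={5: 1}, alleles={"rs": "ref"})
        b = _ar(rid="b", meth={5: 1}, alleles={"rs": "ref"})
        out = deduplicate([a, b])
        assert [r.read_id for r in out] == ["a"]  # first by read_id

    def test_different_methylation_kept(self):
        a = _ar(rid="a", meth={5: 1})
        b = _ar(rid="b", meth={5: 0})
        assert len(deduplicate([a, b])) == 2
        assert len(deduplicate([a, b], loose=True)) == 1

    def test_idempotent(self):
        reads = [_ar(rid=f"r{i}", meth={5: i % 2}) for i in range(6)]
        once = deduplicate(reads)
        assert deduplicate(once) == once

    def test_simulated_duplicates_removed(self, tiny_targets, tiny_cohort):
        from asmbs import synth

        cfg = synth.ReadSimConfig(
            mean_depth=6,
            error_rate=0.0,
            conversion_efficiency=1.0,
            conversion_failure_rate=0.0,
            duplicate_rate=0.3,
            depth_multipliers={},
        )
        run = synth.simulate_reads(tiny_cohort[:3], tiny_targets[:1], cfg, seed=9)
        aligner = AmpliconAligner(tiny_targets[:1])
        truth = run.truth.set_index("read_id")
        aligned = []
        for r in run.libraries[0].reads:
            insert = rd.trim_flanks(r)
            ar = aligner.align_insert(insert.sequence, read_id=r.read_id)
            ar.sample = truth.loc[r.read_id, "subject"]
            aligned.append(ar)
        unique = deduplicate(aligned)
        n_molecules = int((~run.truth["duplicate"]).sum())
        # error-free duplicates are byte-identical, so the conservative key
        # recovers exactly the unique molecule count (distinct molecules can
        # still coincide by chance, hence <=)
        assert len(unique) <= n_molecules
        assert len(unique) >= 0.9 * n_molecules


class TestSamRoundTrip:
    def test_write_read(self, tmp_path, tiny_targets):
        aligner = AmpliconAligner(tiny_targets)
        t = tiny_targets[0]
        ar = aligner.align_insert(t.reference_seq, read_id="r1", sample="s1")
        p = tmp_path / "out.sam"
        write_sam([ar], tiny_targets, p)
        back = read_sam(p, tiny_targets)
        assert len(back) == 1
        assert back[0].read_id == "r1"
        assert back[0].sample == "s1"
        assert back[0].methylation_calls == ar.methylation_calls
        assert back[0].allele_calls == ar.allele_calls
        assert back[0].cph_total == ar.cph_total
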