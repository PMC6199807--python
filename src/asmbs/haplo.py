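"""Per-haplotype methylation quantification.

Reads are sorted into haplotype groups by the allele they carry at a target's
sorting SNP; each (sample, allele) group becomes one matrix row of per-CpG
methylation rates.  Heterozygotes contribute two rows per target, homozygotes
one.  Downstream steps — the 5x depth gate, target-coverage drop, CpG-SNP
masking, mean imputation and the smoothed logit transform — all operate on
this matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from collections import Counter, defaultdict
from typing import Sequence

import numpy as np
import pandas as pd

from .align import AlignedRead, _collapse
from .targets import SnpDef, TargetDef, genomic_cpg_positions

REF, ALT = "ref", "alt"


@dataclass
class HaploMethMatrix:
    """(sample, allele) x CpG methylation-rate matrices, one frame per target.

    ``rates`` holds methylation fractions (NaN = missing), ``cell_depth`` the
    number of informative calls behind each cell, ``row_depth`` the read count
    supporting each row, and ``n`` the analysis-set sample size used as the
    smoothing denominator of the logit transform.
    """

    rates: dict[str, pd.DataFrame]
    cell_depth: dict[str, pd.DataFrame]
    row_depth: dict[str, pd.Series]
    n: int

    def targets(self) -> list[str]:
        return list(self.rates)

    def samples(self) -> list[str]:
        out = set()
        for df in self.rates.values():
            out.update(df.index.get_level_values("sample"))
        return sorted(out)

    def with_n(self, n: int) -> "HaploMethMatrix":
        return replace(self, n=int(n))


def usable_sorting_snp(target: TargetDef) -> SnpDef | None:
    """First non-CpG SNP whose alleles survive bisulfite collapse on the
    amplified strand; None if the target has no usable polymorphism."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    for snp in target.snps:
        if snp.is_cpg_snp:
            continue
        if len(snp.ref_allele) != 1 or len(snp.alt_allele) != 1:
            continue
        if target.strand == "+":
            ra, aa = snp.ref_allele, snp.alt_allele
        else:
            ra, aa = comp[snp.ref_allele], comp[snp.alt_allele]
        if _collapse(ra) != _collapse(aa):
            return snp
    return None


def split_by_allele(
    reads: Sequence[AlignedRead],
    target: TargetDef,
    min_minor_reads: int = 2,
    het_min_fraction: float = 0.2,
) -> tuple[dict[tuple[str, str], list[AlignedRead]], int]:
    """Sort reads of one target into (sample, allele) haplotype groups.

    Genotype at the sorting SNP is inferred from read counts: heterozygous if
    the minor allele reaches ``min_minor_reads`` reads and
    ``het_min_fraction`` of informative reads.  For heterozygotes, reads with
    an unknown call are excluded; reads conflicting with their group's
    consensus at any additional usable SNP are excluded and counted.
    Homozygotes yield a single row (unknown-call reads included; minor-allele
    stragglers excluded).  Returns (groups, n_excluded).
    """
    snp = usable_sorting_snp(target)
    groups: dict[tuple[str, str], list[AlignedRead]] = {}
    n_excluded = 0
    by_sample: dict[str, list[AlignedRead]] = defaultdict(list)
    for ar in reads:
        if ar.gene_label == target.gene_label and ar.sample is not None:
            by_sample[ar.sample].append(ar)

    other_snps = [
        s
        for s in target.snps
        if snp is not None and s.snp_id != snp.snp_id and not s.is_cpg_snp
    ]

    for sample, sample_reads in by_sample.items():
        if snp is None:
            groups[(sample, REF)] = list(sample_reads)
            continue
        calls = Counter(ar.allele_calls.get(snp.snp_id, "unknown") for ar in sample_reads)
        n_ref, n_alt = calls[REF], calls[ALT]
        informative = n_ref + n_alt
        minor = min(n_ref, n_alt)
        het = (
            informative > 0
            and minor >= min_minor_reads
            and minor / informative >= het_min_fraction
        )
        if het:
            for allele in (REF, ALT):
                grp = [
                    ar
                    for ar in sample_reads
                    if ar.allele_calls.get(snp.snp_id) == allele
                ]
                grp, dropped = _drop_phase_conflicts(grp, other_snps)
                n_excluded += dropped
                groups[(sample, allele)] = grp
            n_excluded += calls["unknown"]
        else:
            major = REF if n_ref >= n_alt else ALT
            minor_allele = ALT if major == REF else REF
            grp = [
                ar
                for ar in sample_reads
                if ar.allele_calls.get(snp.snp_id, "unknown") != minor_allele
            ]
            n_excluded += len(sample_reads) - len(grp)
            groups[(sample, major)] = grp
    return groups, n_excluded


def _drop_phase_conflicts(
    grp: list[AlignedRead], other_snps: Sequence[SnpDef]
) -> tuple[list[AlignedRead], int]:
    if not other_snps or not grp:
        return grp, 0
    consensus = {}
    for s in other_snps:
        votes = Counter(
            ar.allele_calls.get(s.snp_id)
            for ar in grp
            if ar.allele_calls.get(s.snp_id) in (REF, ALT)
        )
        if votes:
            consensus[s.snp_id] = votes.most_common(1)[0][0]
    kept = []
    for ar in grp:
        ok = all(
            ar.allele_calls.get(sid) not in (REF, ALT)
            or ar.allele_calls[sid] == consensus[sid]
            for sid in consensus
        )
        if ok:
            kept.append(ar)
    return kept, len(grp) - len(kept)


def methylation_rates(
    reads: Sequence[AlignedRead], cpg_positions: Sequence[int]
) -> tuple[pd.Series, pd.Series]:
    """Per-CpG methylation fraction and informative-call depth for one row."""
    positions = list(cpg_positions)
    meth = np.zeros(len(positions))
    total = np.zeros(len(positions))
    pos_index = {p: i for i, p in enumerate(positions)}
    for ar in reads:
        for pos, call in ar.methylation_calls.items():
            i = pos_index.get(pos)
            if i is None or call < 0:
                continue
            total[i] += 1
            meth[i] += call
    with np.errstate(invalid="ignore"):
        m = np.where(total > 0, meth / np.maximum(total, 1), np.nan)
    return (
        pd.Series(m, index=positions),
        pd.Series(total.astype(int), index=positions),
    )


def build_matrix(
    reads: Sequence[AlignedRead],
    targets: Sequence[TargetDef],
    n: int | None = None,
) -> HaploMethMatrix:
    """Assemble the haplotype methylation matrix from QC-passing reads."""
    rates: dict[str, pd.DataFrame] = {}
    depth: dict[str, pd.DataFrame] = {}
    row_depth: dict[str, pd.Series] = {}
    for t in targets:
        if t.reference_seq is None:
            continue
        positions = genomic_cpg_positions(t)
        groups, _ = split_by_allele(
            [r for r in reads if r.gene_label == t.gene_label], t
        )
        if not groups:
            continue
        rows, drows, rdepth = [], [], []
        index = []
        for (sample, allele), grp in sorted(groups.items()):
            m, d = methylation_rates(grp, positions)
            rows.append(m)
            drows.append(d)
            rdepth.append(len(grp))
            index.append((sample, allele))
        idx = pd.MultiIndex.from_tuples(index, names=["sample", "allele"])
        rates[t.gene_label] = pd.DataFrame(rows, index=idx)
        depth[t.gene_label] = pd.DataFrame(drows, index=idx)
        row_depth[t.gene_label] = pd.Series(rdepth, index=idx)
    all_samples = {
        s for df in rates.values() for s in df.index.get_level_values("sample")
    }
    return HaploMethMatrix(
        rates=rates,
        cell_depth=depth,
        row_depth=row_depth,
        n=n if n is not None else len(all_samples),
    )


def apply_depth_filter(
    matrix: HaploMethMatrix, min_depth: int = 5
) -> tuple[HaploMethMatrix, list[tuple[str, str, str]]]:
    """Drop rows supported by fewer than ``min_depth`` reads ("minimum 5x").

    Returns the filtered matrix and a log of removed (target, sample, allele).
    """
    rates, depth, rdepth = {}, {}, {}
    removed = []
    for t, df in matrix.rates.items():
        keep = matrix.row_depth[t] >= min_depth
        removed.extend((t, s, a) for (s, a) in df.index[~keep])
        if keep.any():
            rates[t] = df.loc[keep]
            depth[t] = matrix.cell_depth[t].loc[keep]
            rdepth[t] = matrix.row_depth[t].loc[keep]
    return HaploMethMatrix(rates, depth, rdepth, matrix.n), removed


def check_target_coverage(
    matrix: HaploMethMatrix,
    all_samples: Sequence[str],
    min_sample_fraction: float = 0.8,
) -> tuple[HaploMethMatrix, list[str]]:
    """Drop targets covered in too small a fraction of the cohort.

    A target is retained iff the fraction of ``all_samples`` with at least one
    surviving row is >= ``min_sample_fraction`` (the starved-target rule that
    removed CACNA1D in the source study).
    """
    n_all = max(len(set(all_samples)), 1)
    rates, depth, rdepth = {}, {}, {}
    dropped = []
    for t, df in matrix.rates.items():
        frac = len(set(df.index.get_level_values("sample"))) / n_all
        if frac >= min_sample_fraction:
            rates[t] = df
            depth[t] = matrix.cell_depth[t]
            rdepth[t] = matrix.row_depth[t]
        else:
            dropped.append(t)
    return HaploMethMatrix(rates, depth, rdepth, matrix.n), dropped


def mask_cpg_snps(
    matrix: HaploMethMatrix, targets: Sequence[TargetDef]
) -> HaploMethMatrix:
    """Remove CpG columns whose dinucleotide overlaps a known CpG-SNP."""
    by_label = {t.gene_label: t for t in targets}
    rates, depth = {}, {}
    for label, df in matrix.rates.items():
        t = by_label.get(label)
        masked_pos = set()
        if t is not None:
            for snp in t.snps:
                if snp.is_cpg_snp:
                    masked_pos.update((snp.position, snp.position - 1))
            cols = [c for c in df.columns if c not in masked_pos]
        else:
            cols = list(df.columns)
        rates[label] = df[cols]
        depth[label] = matrix.cell_depth[label][cols]
    return HaploMethMatrix(rates, depth, dict(matrix.row_depth), matrix.n)


def impute_missing(matrix: HaploMethMatrix) -> HaploMethMatrix:
    """Column-mean imputation of missing rates; observed cells are untouched."""
    rates = {}
    for label, df in matrix.rates.items():
        fully_missing = df.columns[df.isna().all(axis=0)]
        if len(fully_missing):
            raise ValueError(
                f"{label}: CpG column(s) with no observed value: "
                f"{list(fully_missing)}"
            )
        rates[label] = df.fillna(df.mean(axis=0))
    return HaploMethMatrix(
        rates, dict(matrix.cell_depth), dict(matrix.row_depth), matrix.n
    )


def logit_transform(m, n: int):
    """Smoothed logit of a methylation rate.

    M = ln(m'/(1-m')) with m' = (m(n-1)+0.5)/n, where n is the analysis-set
    sample size; m' in (0,1) for any m in [0,1], so M is always finite.
    Natural logarithm (downstream t tests and logistic fits are invariant to
    the base).
    """
    if n < 1:
        raise ValueError("sample size n must be >= 1")
    arr = np.asarray(m, dtype=float)
    if np.nanmin(arr, initial=0.0) < 0 or np.nanmax(arr, initial=1.0) > 1:
        raise ValueError("methylation rates must lie in [0, 1]")
    mprime = (arr * (n - 1) + 0.5) / n
    out = np.log(mprime / (1.0 - mprime))
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def to_logit(matrix: HaploMethMatrix) -> dict[str, pd.DataFrame]:
    """Logit-transform every target frame with the matrix's own n."""
    return {
        label: pd.DataFrame(
            logit_transform(df.to_numpy(), matrix.n),
            index=df.index,
            columns=df.columns,
        )
        for label, df in matrix.rates.items()
    }


def matrix_to_tsv(matrix: HaploMethMatrix, path) -> None:
    """Serialise all target frames as one long TSV
    (target, sample, allele, pos, rate, depth, row_depth, n)."""
    rows = []
    for label, df in matrix.rates.items():
        d = matrix.cell_depth[label]
        rd = matrix.row_depth[label]
        for (sample, allele) in df.index:
            for pos in df.columns:
                rows.append(
                    (
                        label,
                        sample,
                        allele,
                        pos,
                        df.loc[(sample, allele), pos],
                        d.loc[(sample, allele), pos],
                        rd.loc[(sample, allele)],
                        matrix.n,
                    )
                )
    pd.DataFrame(
        rows,
        columns=["target", "sample", "allele", "pos", "rate", "depth", "row_depth", "n"],
    ).to_csv(path, sep="\t", index=False)


def matrix_from_tsv(path) -> HaploMethMatrix:
    """Load a matrix serialised by :func:`matrix_to_tsv`."""
    long = pd.read_csv(path, sep="\t")
    rates, depth, rdepth = {}, {}, {}
    n = int(long["n"].iloc[0]) if len(long) else 0
    for label, sub in long.groupby("target"):
        r = sub.pivot_table(
            index=["sample", "allele"], columns="pos", values="rate", dropna=False
        )
        d = sub.pivot_table(
            index=["sample", "allele"], columns="pos", values="depth", dropna=False
        )
        rates[label] = r
        depth[label] = d.astype(int)
        rdepth[label] = (
            sub.groupby(["sample", "allele"])["row_depth"].first().reindex(r.index)
        )
    return HaploMethMatrix(rates, depth, rdepth, n)
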