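"""Bisulfite-aware targeted alignment and per-read methylation/allele calling.

Reads are aligned in converted space: both the insert and each target's
amplified-strand reference are C->T collapsed, and the best-scoring target
wins.  Methylation is then called from the *original* read base over each
reference CpG C (C = methylated, T = unmethylated), CpH conversion is tallied
the same way, and SNP alleles are read after bisulfite equivalence-classing
({C,T} collapse on the amplified strand), which is what makes C>T plus-strand
and G>A minus-strand polymorphisms unusable for allele sorting.

The aligner is a banded global affine-gap (Gotoh) dynamic programme; a fast
edit-distance prescreen (edlib) picks the candidate target and orientation
before the DP runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

from ._util import revcomp, validate_dna
from .targets import SnpDef, TargetDef, amplicon_length

NEG_INF = -1e18

METHYLATED, UNMETHYLATED, MISSING = 1, 0, -1

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def convert_reference(seq: str) -> str:
    """C->T collapse of an uppercase DNA string (three-letter bisulfite space)."""
    validate_dna(seq)
    return seq.replace("C", "T")


@dataclass
class AlignedRead:
    read_id: str
    sample: str | None
    gene_label: str
    cigar: str
    aligned_start: int  # 1-based plus-strand genomic position of leftmost covered base
    score: float
    identity: float
    methylation_calls: dict[int, int]  # genomic CpG position -> 1/0/-1
    allele_calls: dict[str, str]  # snp_id -> ref/alt/unknown
    cph_total: int
    cph_unconverted: int
    mismatches: int
    target: TargetDef | None = field(default=None, repr=False)
    _orig_seq: str | None = field(default=None, repr=False)
    _ref2read: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.cph_unconverted > self.cph_total:
            raise ValueError("cph_unconverted exceeds cph_total")


# -- Gotoh global alignment --------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def gotoh_align(
    query: str,
    ref: str,
    match: float = 2.0,
    mismatch: float = -4.0,
    gap_open: float = -6.0,
    gap_extend: float = -1.0,
    band: int | None = 32,
):
    """Global affine-gap alignment; returns (score, cigar, ref2read).

    A gap of length L costs ``gap_open + L * gap_extend``.  ``band`` is the
    half-width added around the length-difference diagonal corridor; ``None``
    runs the full (unbanded) DP.  ``ref2read[j]`` is the 0-based query index
    aligned over reference base ``j``, or -1 for a deletion.
    """
    n, m = len(query), len(ref)
    if n == 0 or m == 0:
        raise ValueError("empty sequence in alignment")
    if band is None:
        band = max(n, m)
    dlo = min(0, m - n) - band
    dhi = max(0, m - n) + band
    W = dhi - dlo + 1
    a, b = _encode(query), _encode(ref)

    M = np.full((n + 1, W), NEG_INF)
    X = np.full((n + 1, W), NEG_INF)  # gap in ref (insertion in query)
    Y = np.full((n + 1, W), NEG_INF)  # gap in query (deletion)

    ks = np.arange(W)
    j0 = dlo + ks  # j at row 0
    origin = -dlo
    M[0, origin] = 0.0
    lead = (j0 >= 1) & (j0 <= m)
    Y[0, lead] = gap_open + gap_extend * j0[lead]

    go_ge = gap_open + gap_extend
    for i in range(1, n + 1):
        j_arr = i + dlo + ks
        valid = (j_arr >= 0) & (j_arr <= m)
        # X: query base i aligned to gap -> from (i-1, j) = band column k+1
        m_up = np.concatenate((M[i - 1, 1:], [NEG_INF]))
        x_up = np.concatenate((X[i - 1, 1:], [NEG_INF]))
        X[i] = np.maximum(m_up + go_ge, x_up + gap_extend)
        # M: diagonal from (i-1, j-1) = same band column
        jj = np.clip(j_arr - 1, 0, m - 1)
        sub = np.where(a[i - 1] == b[jj], match, mismatch)
        diag = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        Mi = sub + diag
        Mi[~valid | (j_arr < 1)] = NEG_INF
        M[i] = Mi
        # Y: within-row horizontal scan, Y[k] = max(M[k-1], ...) via cummax trick
        m_left = np.concatenate(([NEG_INF], M[i, :-1]))
        c = m_left + go_ge - gap_extend * ks
        with np.errstate(invalid="ignore"):
            z = np.maximum.accumulate(c)
        Yi = z + gap_extend * ks
        Yi[~valid] = NEG_INF
        Y[i] = Yi
        M[i, ~valid] = NEG_INF
        X[i, ~valid] = NEG_INF

    kend = m - n - dlo
    if not (0 <= kend < W):
        raise ValueError("band does not contain the global terminus")
    scores = (M[n, kend], X[n, kend], Y[n, kend])
    state = int(np.argmax(scores))  # ties resolve M > X > Y
    score = float(scores[state])
    if score <= NEG_INF / 2:
        raise ValueError("no alignment within band")

    # traceback
    ops: list[str] = []
    ref2read = np.full(m, -1, dtype=int)
    i, k = n, kend
    while True:
        j = i + dlo + k
        if i == 0 and j == 0:
            break
        if state == 0:  # M: consumed a[i-1], b[j-1]
            ops.append("M")
            ref2read[j - 1] = i - 1
            prev = np.array([M[i - 1, k], X[i - 1, k], Y[i - 1, k]])
            state = int(np.argmax(prev))  # first max -> prefer M
            i -= 1
        elif state == 1:  # X: consumed a[i-1]
            ops.append("I")
            m_up = M[i - 1, k + 1] if k + 1 < W else NEG_INF
            x_up = X[i - 1, k + 1] if k + 1 < W else NEG_INF
            state = 0 if m_up + go_ge >= x_up + gap_extend else 1
            i -= 1
            k += 1
        else:  # Y: consumed b[j-1]
            ops.append("D")
            m_left = M[i, k - 1] if k - 1 >= 0 else NEG_INF
            y_left = Y[i, k - 1] if k - 1 >= 0 else NEG_INF
            state = 0 if m_left + go_ge >= y_left + gap_extend else 2
            k -= 1
        if i == 0 and (i + dlo + k) == 0:
            break
    ops.reverse()
    # run-length encode to CIGAR
    cigar = ""
    run, cur = 0, ""
    for op in ops:
        if op == cur:
            run += 1
        else:
            if cur:
                cigar += f"{run}{cur}"
            cur, run = op, 1
    if cur:
        cigar += f"{run}{cur}"
    return score, cigar, ref2read


# -- targeted aligner --------------------------------------------------------


class AmpliconAligner:
    """Aligns inserts to a small registry of known amplicon references."""

    def __init__(
        self,
        targets: Sequence[TargetDef],
        band: int = 32,
        match: float = 2.0,
        mismatch: float = -4.0,
        gap_open: float = -6.0,
        gap_extend: float = -1.0,
        min_identity: float = 0.8,
    ):
        self.targets = [t for t in targets if t.reference_seq is not None]
        if not self.targets:
            raise ValueError("no targets carry a reference_seq")
        self.band = band
        self.match, self.mismatch = match, mismatch
        self.gap_open, self.gap_extend = gap_open, gap_extend
        self.min_identity = min_identity
        self._conv_refs = [convert_reference(t.reference_seq) for t in self.targets]
        self._cpg_locals = [t.cpg_local_indices() for t in self.targets]

    def align_insert(
        self, insert: str, read_id: str = "", sample: str | None = None
    ) -> AlignedRead | None:
        if not insert:
            return None
        fwd = insert.upper()
        rev = revcomp(fwd)
        conv = {False: convert_reference(fwd), True: convert_reference(rev)}
        best = None  # (distance, target_idx, flipped)
        for ti, cref in enumerate(self._conv_refs):
            for flipped in (False, True):
                d = edlib.align(conv[flipped], cref, mode="NW", task="distance")[
                    "editDistance"
                ]
                if best is None or d < best[0]:
                    best = (d, ti, flipped)
        _, ti, flipped = best
        target = self.targets[ti]
        orig = rev if flipped else fwd
        score, cigar, ref2read = gotoh_align(
            conv[flipped],
            self._conv_refs[ti],
            match=self.match,
            mismatch=self.mismatch,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            band=self.band,
        )
        return self._annotate(
            target, ti, orig, score, cigar, ref2read, read_id, sample
        )

    def _annotate(self, target, ti, orig, score, cigar, ref2read, read_id, sample):
        cref = self._conv_refs[ti]
        conv_orig = convert_reference(orig)
        covered = np.nonzero(ref2read >= 0)[0]
        if covered.size == 0:
            return None
        matches = sum(
            1 for j in covered if conv_orig[ref2read[j]] == cref[j]
        )
        identity = matches / amplicon_length(target)
        if identity < self.min_identity:
            return None
        mismatches = int(covered.size - matches)

        ref = target.reference_seq
        meth: dict[int, int] = {}
        for ci in self._cpg_locals[ti]:
            gpos = target.cpg_genomic_from_local(ci)
            ri = ref2read[ci]
            if ri < 0:
                meth[gpos] = MISSING
            else:
                base = orig[ri]
                meth[gpos] = (
                    METHYLATED if base == "C" else UNMETHYLATED if base == "T" else MISSING
                )
        cpg_set = set(self._cpg_locals[ti])
        cph_total = cph_unconv = 0
        for j in range(len(ref)):
            if ref[j] != "C" or j in cpg_set:
                continue
            ri = ref2read[j]
            if ri < 0:
                continue
            base = orig[ri]
            if base == "C":
                cph_total += 1
                cph_unconv += 1
            elif base == "T":
                cph_total += 1

        if target.strand == "+":
            aligned_start = target.start + int(covered[0])
        else:
            aligned_start = target.start + (len(ref) - 1 - int(covered[-1]))

        ar = AlignedRead(
            read_id=read_id,
            sample=sample,
            gene_label=target.gene_label,
            cigar=cigar,
            aligned_start=aligned_start,
            score=score,
            identity=identity,
            methylation_calls=meth,
            allele_calls={},
            cph_total=cph_total,
            cph_unconverted=cph_unconv,
            mismatches=mismatches,
            target=target,
            _orig_seq=orig,
            _ref2read=ref2read,
        )
        ar.allele_calls = {snp.snp_id: call_allele(ar, snp) for snp in target.snps}
        return ar


def _collapse(base: str) -> str:
    # bisulfite equivalence class on the amplified (read) strand
    return "T" if base in ("C", "T") else base


def call_allele(ar: AlignedRead, snp: SnpDef) -> str:
    """Call ref/alt/unknown for a SNP from the original read base.

    Alleles are translated onto the amplified strand, then {C,T}-collapsed;
    if both alleles land in the same class (the C>T / G>A cases) every read
    returns ``unknown``.
    """
    target = ar.target
    if target is None:
        raise ValueError("AlignedRead lacks its target context")
    if not (target.start <= snp.position <= target.end):
        raise ValueError(f"SNP {snp.snp_id} outside target {target.gene_label}")
    if len(snp.ref_allele) != 1 or len(snp.alt_allele) != 1:
        return "unknown"  # indel alleles are not called from single-base lookup
    if target.strand == "+":
        ref_a, alt_a = snp.ref_allele, snp.alt_allele
    else:
        ref_a, alt_a = _COMP[snp.ref_allele], _COMP[snp.alt_allele]
    ref_c, alt_c = _collapse(ref_a), _collapse(alt_a)
    if ref_c == alt_c:
        return "unknown"
    li = target.local_index(snp.position)
    ri = ar._ref2read[li] if ar._ref2read is not None else -1
    if ri < 0:
        return "unknown"
    base_c = _collapse(ar._orig_seq[ri])
    if base_c == ref_c:
        return "ref"
    if base_c == alt_c:
        return "alt"
    return "unknown"


# -- QC filters --------------------------------------------------------------


def filter_conversion(ar: AlignedRead, threshold: float = 0.05) -> bool:
    """Pass iff unconverted CpH fraction < threshold (strict); vacuous pass at 0 CpH."""
    if ar.cph_total == 0:
        return True
    return ar.cph_unconverted / ar.cph_total < threshold


def conversion_rate(reads: Iterable[AlignedRead]) -> float | None:
    """1 - pooled unconverted-CpH fraction over reads; None if no CpH observed."""
    tot = sum(r.cph_total for r in reads)
    if tot == 0:
        return None
    unc = sum(r.cph_unconverted for r in reads)
    return 1.0 - unc / tot


def deduplicate(
    reads: Sequence[AlignedRead], loose: bool = False
) -> list[AlignedRead]:
    """One representative per duplicate key within each (sample, target) group.

    The default (conservative) key is the full identity of the aligned
    molecule: start, CIGAR, methylation vector and allele vector.  ``loose``
    keys on start+CIGAR only.  The representative is the first read by
    read_id; output order is deterministic.
    """
    groups: dict[tuple, AlignedRead] = {}
    for ar in sorted(reads, key=lambda r: r.read_id):
        if loose:
            key = (ar.sample, ar.gene_label, ar.aligned_start, ar.cigar)
        else:
            key = (
                ar.sample,
                ar.gene_label,
                ar.aligned_start,
                ar.cigar,
                tuple(sorted(ar.methylation_calls.items())),
                tuple(sorted(ar.allele_calls.items())),
            )
        groups.setdefault(key, ar)
    return sorted(groups.values(), key=lambda r: r.read_id)


# -- SAM-style export --------------------------------------------------------


def write_sam(reads: Iterable[AlignedRead], targets: Sequence[TargetDef], path) -> None:
    """Plain-text SAM with per-read methylation/allele/CpH tags.

    Tags: XM (per-CpG calls ``pos:call``), XA (per-SNP calls), XC/XU
    (CpH total/unconverted).  Coordinates are local to the amplified-strand
    reference named by gene label.
    """
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for t in targets:
            if t.reference_seq is not None:
                fh.write(f"@SQ\tSN:{t.gene_label}\tLN:{amplicon_length(t)}\n")
        for ar in reads:
            meth = ",".join(f"{p}:{c}" for p, c in sorted(ar.methylation_calls.items()))
            alle = ",".join(f"{s}:{c}" for s, c in sorted(ar.allele_calls.items()))
            seq = ar._orig_seq or "*"
            fh.write(
                "\t".join(
                    [
                        ar.read_id,
                        "0",
                        ar.gene_label,
                        "1",
                        "255",
                        ar.cigar,
                        "*",
                        "0",
                        "0",
                        seq,
                        "*",
                        f"XM:Z:{meth or '.'}",
                        f"XA:Z:{alle or '.'}",
                        f"XC:i:{ar.cph_total}",
                        f"XU:i:{ar.cph_unconverted}",
                        f"XS:Z:{ar.sample or '.'}",
                    ]
                )
                + "\n"
            )


def read_sam(path, targets: Sequence[TargetDef]) -> list[AlignedRead]:
    """Import reads written by :func:`write_sam` (or bismark-like SAM with the
    same tags); methylation/allele calls come from the tags, not realignment."""
    by_label = {t.gene_label: t for t in targets}
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            qname, _, rname, _, _, cigar = fields[:6]
            tags = {f.split(":", 1)[0]: f.split(":", 2)[2] for f in fields[11:]}
            meth = {}
            if tags.get("XM", ".") != ".":
                for item in tags["XM"].split(","):
                    p, c = item.rsplit(":", 1)
                    meth[int(p)] = int(c)
            alle = {}
            if tags.get("XA", ".") != ".":
                for item in tags["XA"].split(","):
                    s, c = item.rsplit(":", 1)
                    alle[s] = c
            target = by_label.get(rname)
            out.append(
                AlignedRead(
                    read_id=qname,
                    sample=None if tags.get("XS", ".") == "." else tags["XS"],
                    gene_label=rname,
                    cigar=cigar,
                    aligned_start=target.start if target else 1,
                    score=0.0,
                    identity=1.0,
                    methylation_calls=meth,
                    allele_calls=alle,
                    cph_total=int(tags.get("XC", 0)),
                    cph_unconverted=int(tags.get("XU", 0)),
                    mismatches=0,
                    target=target,
                )
            )
    return out
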