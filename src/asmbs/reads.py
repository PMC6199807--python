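"""Raw-read handling: FASTQ I/O, quality filtering, demultiplexing, flank trimming.

Simulated (and, by the same layout, imported) reads are full-length amplicon
molecules wrapped in ligation-barcode flanks::

    [code1 (5 nt)] [U1 primer] [insert] [revcomp(U1)] [revcomp(code2)]

where ``code1`` comes from the first oligonucleotide set (8 codes) and
``code2`` from the second (12 codes), giving 96 distinct combinations per
library.  Barcode matching is exact: a single substitution in either
five-letter code discards the read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import revcomp

#: Shared 5'-tail primer of the suppression ("panhandle") PCR; both specific
#: primers carry it, so every amplicon is flanked by U1 / revcomp(U1).
U1_PRIMER = "GCAGTCGAACATGTAGCTGACTCAGGTCAC"

BARCODE_LEN = 5

#: Default five-letter code sets (synthetic stand-ins for the study's
#: unpublished oligo barcodes): 8 codes for the first adapter arm, 12 for the
#: second, pairwise Hamming distance >= 2 within each set.
DEFAULT_FIRST_SET = (
    "AACCT", "AGGAT", "ACTGC", "ATACG",
    "CAGTA", "CCAAG", "CTTCA", "CGCTT",
)
DEFAULT_SECOND_SET = (
    "GAACA", "GCCTA", "GTGAT", "GGTTC",
    "TACAG", "TCGGA", "TGTCT", "TTAGC",
    "AAGGC", "CATCC", "GATAC", "TCCTG",
)


@dataclass(eq=False)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: np.ndarray  # per-base phred scores
    assigned_sample: str | None = None
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=int)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence/quality length mismatch "
                f"({len(self.sequence)} vs {len(self.qualities)})"
            )

    def mean_quality(self) -> float:
        return float(np.mean(self.qualities)) if len(self.qualities) else 0.0


@dataclass
class BarcodeTable:
    """Two oligo code sets plus the (code1, code2) -> sample mapping."""

    first_set: Sequence[str]
    second_set: Sequence[str]
    sample_map: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, codes in (("first", self.first_set), ("second", self.second_set)):
            if len(set(codes)) != len(codes):
                raise ValueError(f"duplicate codes in {name} barcode set")
            if any(len(c) != BARCODE_LEN for c in codes):
                raise ValueError(f"{name} set contains a code that is not {BARCODE_LEN} nt")
        n_combos = len(self.first_set) * len(self.second_set)
        if len(self.sample_map) > n_combos:
            raise ValueError("more mapped samples than barcode combinations")
        valid = set(self.first_set), set(self.second_set)
        for c1, c2 in self.sample_map:
            if c1 not in valid[0] or c2 not in valid[1]:
                raise ValueError(f"sample map uses unknown code pair ({c1}, {c2})")


def count_barcode_combinations(table: BarcodeTable) -> int:
    """Number of distinct Y-adapter barcode combinations (|set1| x |set2|)."""
    return len(table.first_set) * len(table.second_set)


def default_barcode_table(sample_ids: Sequence[str]) -> BarcodeTable:
    """Map up to 96 samples onto the default 8 x 12 code sets, row-major."""
    if len(sample_ids) > len(DEFAULT_FIRST_SET) * len(DEFAULT_SECOND_SET):
        raise ValueError("more than 96 samples need multiple libraries")
    pairs = [(c1, c2) for c1 in DEFAULT_FIRST_SET for c2 in DEFAULT_SECOND_SET]
    mapping = {pairs[i]: sid for i, sid in enumerate(sample_ids)}
    return BarcodeTable(DEFAULT_FIRST_SET, DEFAULT_SECOND_SET, mapping)


def wrap_insert(insert: str, code1: str, code2: str) -> str:
    """Assemble the full read layout around an amplified-strand insert."""
    return code1 + U1_PRIMER + insert + revcomp(U1_PRIMER) + revcomp(code2)


def quality_filter(
    reads: Iterable[ReadRecord], min_mean_q: int = 30, per_base: bool = False
) -> list[ReadRecord]:
    """Keep reads with mean quality >= ``min_mean_q`` ("no less than Q30").

    ``per_base=True`` instead requires every base to meet the threshold.
    """
    if per_base:
        return [r for r in reads if len(r.qualities) and r.qualities.min() >= min_mean_q]
    return [r for r in reads if r.mean_quality() >= min_mean_q]


def _barcode_key(read: ReadRecord) -> tuple[tuple[str, str], tuple[str, str]] | None:
    seq = read.sequence
    if len(seq) < 2 * BARCODE_LEN:
        return None
    head, tail = seq[:BARCODE_LEN], seq[-BARCODE_LEN:]
    # forward orientation: (code1, code2); flipped: codes swap ends
    return (head, revcomp(tail)), (revcomp(tail), head)


def demultiplex(
    reads: Iterable[ReadRecord], table: BarcodeTable
) -> tuple[list[ReadRecord], int, dict[str, int]]:
    """Assign reads to samples by exact dual-barcode match.

    Returns (assigned reads, discard count, per-sample counts).  Each read is
    assigned to at most one sample; no barcode errors are tolerated.  Because
    the U1 flank layout is orientation-symmetric, the matching barcode pair
    also fixes the read's strand: reads matched in the flipped orientation
    are reverse-complemented here so downstream trimming sees the amplified
    strand.
    """
    assigned: list[ReadRecord] = []
    per_sample: dict[str, int] = {}
    n_discarded = 0
    for read in reads:
        keys = _barcode_key(read)
        sample = None
        if keys is not None:
            fwd, flp = keys
            if fwd in table.sample_map:
                sample = table.sample_map[fwd]
            elif flp in table.sample_map:
                sample = table.sample_map[flp]
                read = ReadRecord(
                    read.read_id,
                    revcomp(read.sequence),
                    read.qualities[::-1],
                    truth=read.truth,
                )
        if sample is None:
            n_discarded += 1
            continue
        read.assigned_sample = sample
        per_sample[sample] = per_sample.get(sample, 0) + 1
        assigned.append(read)
    return assigned, n_discarded, per_sample


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def trim_flanks(
    read: ReadRecord,
    u1_primer: str = U1_PRIMER,
    max_mismatch: int = 3,
) -> ReadRecord | None:
    """Strip barcodes and U1 flanks.

    Strand orientation is already normalised by :func:`demultiplex` (the U1
    layout alone is orientation-symmetric, so only the barcode sets can fix
    the strand); both orientations are still tried here for robustness on
    reads that bypassed demultiplexing.  Reads whose flanks do not match U1
    within ``max_mismatch`` substitutions are flagged unassignable (None).
    """
    lu = len(u1_primer)
    flank = BARCODE_LEN + lu
    if len(read.sequence) <= 2 * flank:
        return None
    for seq, qual in (
        (read.sequence, read.qualities),
        (revcomp(read.sequence), read.qualities[::-1]),
    ):
        left = seq[BARCODE_LEN : BARCODE_LEN + lu]
        right = seq[-(BARCODE_LEN + lu) : -BARCODE_LEN]
        if (
            _hamming(left, u1_primer) <= max_mismatch
            and _hamming(right, revcomp(u1_primer)) <= max_mismatch
        ):
            return ReadRecord(
                read_id=read.read_id,
                sequence=seq[flank:-flank],
                qualities=qual[flank:-flank],
                assigned_sample=read.assigned_sample,
                truth=read.truth,
            )
    return None


# -- FASTQ I/O ---------------------------------------------------------------


def read_fastq(path: str | Path) -> list[ReadRecord]:
    records = []
    for rec in SeqIO.parse(str(path), "fastq"):
        records.append(
            ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=np.array(rec.letter_annotations["phred_quality"], dtype=int),
            )
        )
    return records


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        recs.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fastq")
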