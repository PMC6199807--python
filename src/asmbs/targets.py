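"""Amplicon target registry and coordinate arithmetic.

Coordinates are 1-based inclusive throughout the package: the printed length of
an amplicon equals ``end - start + 1``.  For minus-strand targets the reference
sequence, when present, is stored as the *amplified* strand (the strand the
bisulfite primers amplify); CpG sites are nevertheless reported as plus-strand
genomic coordinates of the C of the CpG dinucleotide.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

from ._util import revcomp, validate_dna


@dataclass
class SnpDef:
    """A polymorphism inside an amplicon, in plus-strand genomic terms.

    ``is_cpg_snp`` flags SNPs that overlap a CpG dinucleotide; their
    methylation columns are masked downstream because the signal is
    confounded by genotype.
    """

    snp_id: str
    position: int  # 1-based genomic, plus strand
    ref_allele: str
    alt_allele: str
    is_cpg_snp: bool = False

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")


@dataclass
class TargetDef:
    """One bisulfite PCR amplicon.

    ``reference_cpg`` is the EWAS index probe ID (e.g. an Illumina cg number);
    ``index_cpg_pos``, when known, is the plus-strand genomic position of that
    probe's C and is what the "index" prediction model consumes.
    """

    gene_label: str
    reference_cpg: str
    chrom: str
    start: int
    end: int
    strand: str
    expected_cpg_count: int
    snps: list[SnpDef] = field(default_factory=list)
    reference_seq: str | None = None
    index_cpg_pos: int | None = None

    def __post_init__(self) -> None:
        self.strand = self.strand.replace("−", "-")  # typographic minus
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_label}: invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_label}: strand must be + or -, got {self.strand!r}")
        if self.expected_cpg_count < 0:
            raise ValueError(f"{self.gene_label}: negative expected_cpg_count")
        if self.reference_seq is not None:
            validate_dna(self.reference_seq)
            if len(self.reference_seq) != amplicon_length(self):
                raise ValueError(
                    f"{self.gene_label}: reference_seq length {len(self.reference_seq)} "
                    f"!= amplicon length {amplicon_length(self)}"
                )
        for snp in self.snps:
            if not (self.start <= snp.position <= self.end):
                raise ValueError(
                    f"{self.gene_label}: SNP {snp.snp_id} at {snp.position} outside "
                    f"{self.chrom}:{self.start}-{self.end}"
                )

    # -- coordinate helpers ------------------------------------------------

    def local_index(self, genomic_pos: int) -> int:
        """0-based index of a plus-strand genomic position on the amplified strand."""
        if not (self.start <= genomic_pos <= self.end):
            raise ValueError(f"position {genomic_pos} outside {self.gene_label}")
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - genomic_pos

    def plus_strand_seq(self) -> str:
        """Reference sequence on the plus strand (reverse complement for minus targets)."""
        if self.reference_seq is None:
            raise ValueError(f"{self.gene_label} has no reference_seq")
        return self.reference_seq if self.strand == "+" else revcomp(self.reference_seq)

    def cpg_local_indices(self) -> list[int]:
        """0-based indices (amplified strand) of the C of each CpG dinucleotide."""
        if self.reference_seq is None:
            raise ValueError(f"{self.gene_label} has no reference_seq")
        seq = self.reference_seq
        return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]

    def cpg_genomic_from_local(self, local_c_index: int) -> int:
        """Plus-strand genomic position of the plus-strand C of a CpG.

        On the amplified minus strand the C of a CG dinucleotide at local
        index *i* pairs with the plus-strand G; the plus-strand C of the same
        CpG sits one base before it, at ``end - i - 1``.
        """
        if self.strand == "+":
            return self.start + local_c_index
        return self.end - local_c_index - 1


def amplicon_length(target: TargetDef) -> int:
    """Amplicon length in bp (1-based inclusive coordinates)."""
    if target.start > target.end:
        raise ValueError("start > end")
    return target.end - target.start + 1


def cpg_positions(target: TargetDef, seq: str) -> list[int]:
    """Plus-strand genomic positions of CpG Cs in a plus-strand sequence.

    ``seq`` must cover the full amplicon; positions are strictly increasing
    and there is one per "CG" occurrence.
    """
    if len(seq) != amplicon_length(target):
        raise ValueError(
            f"sequence length {len(seq)} != amplicon length {amplicon_length(target)}"
        )
    return [target.start + i for i in range(len(seq) - 1) if seq[i : i + 2] == "CG"]


def genomic_cpg_positions(target: TargetDef) -> list[int]:
    """Sorted plus-strand genomic CpG positions of a target with a reference_seq."""
    return sorted(
        target.cpg_genomic_from_local(i) for i in target.cpg_local_indices()
    )


def _target_from_record(rec: dict, lineno: int | None = None) -> TargetDef:
    where = f" (line {lineno})" if lineno is not None else ""
    try:
        snps = [
            SnpDef(
                snp_id=s["snp_id"],
                position=int(s["position"]),
                ref_allele=s["ref_allele"],
                alt_allele=s["alt_allele"],
                is_cpg_snp=bool(s.get("is_cpg_snp", False)),
            )
            for s in rec.get("snps", [])
        ]
        return TargetDef(
            gene_label=rec["gene_label"],
            reference_cpg=rec["reference_cpg"],
            chrom=rec["chrom"],
            start=int(rec["start"]),
            end=int(rec["end"]),
            strand=rec["strand"],
            expected_cpg_count=int(rec["expected_cpg_count"]),
            snps=snps,
            reference_seq=rec.get("reference_seq"),
            index_cpg_pos=int(rec["index_cpg_pos"]) if rec.get("index_cpg_pos") else None,
        )
    except (KeyError, ValueError) as exc:
        raise ValueError(f"malformed target record{where}: {exc}") from exc


def load_targets(path: str | Path) -> list[TargetDef]:
    """Load a target registry from TSV (one row per target) or JSON.

    The TSV columns are gene_label, reference_cpg, chrom, start, end, strand,
    expected_cpg_count; JSON additionally carries SNP lists and reference
    sequences.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        records = json.loads(text) if text.strip() else []
        return [_target_from_record(rec) for rec in records]
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    header = lines[0].rstrip("\n").split("\t")
    out = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        if len(fields) != len(header):
            raise ValueError(f"malformed registry line {lineno}: {line!r}")
        out.append(_target_from_record(dict(zip(header, fields)), lineno))
    return out


def save_targets(targets: Sequence[TargetDef], path: str | Path) -> None:
    """Write a registry (with sequences and SNPs) as JSON, loadable by load_targets."""
    records = []
    for t in targets:
        records.append(
            {
                "gene_label": t.gene_label,
                "reference_cpg": t.reference_cpg,
                "chrom": t.chrom,
                "start": t.start,
                "end": t.end,
                "strand": t.strand,
                "expected_cpg_count": t.expected_cpg_count,
                "reference_seq": t.reference_seq,
                "index_cpg_pos": t.index_cpg_pos,
                "snps": [
                    {
                        "snp_id": s.snp_id,
                        "position": s.position,
                        "ref_allele": s.ref_allele,
                        "alt_allele": s.alt_allele,
                        "is_cpg_snp": s.is_cpg_snp,
                    }
                    for s in t.snps
                ],
            }
        )
    Path(path).write_text(json.dumps(records, indent=1))


def default_registry() -> list[TargetDef]:
    """The six packaged hg19 smoking-EWAS amplicons (no reference sequences)."""
    with resources.as_file(
        resources.files("asmbs.data").joinpath("targets_hg19.tsv")
    ) as p:
        return load_targets(p)
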