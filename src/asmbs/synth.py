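"""Synthetic cohort and bisulfite-read generation.

The generator emulates the statistical structure the analysis assumes: a
cohort of ~154 subjects, about one third smokers, two thirds patients/controls
mix, six ~1.3 kbp amplicon targets with 17-114 CpGs each, smoking effects
concentrated on the index CpG and its neighbours, an allele-specific
methylation (ASM) shift on the alt-carrying haplotype at one CpG in two
targets, beta-distributed biological dispersion, incomplete bisulfite
conversion, sequencing error, PCR duplicates and a starved target (the
CACNA1D analogue) that the coverage gate must drop.

Two sampling routes share one cohort truth:

* :func:`simulate_reads` — full read-level FASTQ with barcodes and flanks,
  used to validate the sequencing pipeline end to end;
* :func:`sample_haplo_matrix` — direct binomial sampling of per-haplotype
  methylation rates at a given read depth, used for the statistical power and
  model-comparison studies where read-level detail is irrelevant.

All effects are injected on the logit scale so that truth and downstream
estimates are directly comparable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import expit, logit, revcomp
from .haplo import ALT, REF, HaploMethMatrix, usable_sorting_snp
from .reads import (
    BarcodeTable,
    ReadRecord,
    default_barcode_table,
    wrap_insert,
)
from .targets import SnpDef, TargetDef, genomic_cpg_positions

#: Table-style geometry of the default synthetic registry: label, index probe,
#: synthetic chromosome, amplicon length, strand, planted CpG count.  Lengths
#: and CpG counts mirror the six study amplicons.
DEFAULT_GEOMETRY = (
    ("AHRR", "cg05575921", "sim1", 1342, "+", 44),
    ("ALPPL2", "cg21566642", "sim2", 1301, "-", 114),
    ("IER3", "cg06126421", "sim3", 1319, "+", 19),
    ("GNG12", "cg25189904", "sim4", 1304, "-", 85),
    ("GFI1", "cg09935388", "sim5", 1358, "+", 73),
    ("CACNA1D", "cg15417641", "sim6", 1300, "-", 17),
)

_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_C, _G, _T = 67, 71, 84


@dataclass
class CohortConfig:
    """Cohort-level study conditions.

    Defaults are the source cohort's: 154 subjects, 50/154 smokers, 83/154
    schizophrenia patients, ~50% women, age ~N(26.6, 6.5) years.  Effects are
    logit-scale shifts keyed by (target label, CpG ordinal in ascending
    genomic order); ``dispersion`` is the beta concentration of
    subject-to-subject methylation jitter (``inf`` = none).
    """

    n_subjects: int = 154
    smoking_prevalence: float = 50 / 154
    age_mean: float = 26.6
    age_sd: float = 6.5
    female_prob: float = 0.5
    diagnosis_prob: float = 83 / 154
    alt_freq: float = 0.3
    dispersion: float = 8.0
    smoker_exposure_sd: float = 0.6  # dose heterogeneity among smokers
    nonsmoker_exposure_sd: float = 0.3  # passive/residual exposure spread
    smoking_age_shift: float = 0.0  # confounding knob, off by default
    baseline_means: dict[str, np.ndarray] | None = None
    smoking_effects: dict[str, dict[int, float]] | None = None
    asm_effects: dict[str, dict[int, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("smoking_prevalence", "female_prob", "diagnosis_prob", "alt_freq"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not math.isfinite(self.dispersion) and self.dispersion != math.inf:
            raise ValueError("dispersion must be positive or inf")


@dataclass
class ReadSimConfig:
    """Read-level conditions: ~100 molecules per haplotype (so ~200 reads per
    barcode per target, matching the study's median 202), Q40 constant base
    quality, 1% bisulfite conversion failure at CpH, and a starved CACNA1D
    analogue whose depth multiplier forces the coverage gate to drop it."""

    mean_depth: float = 100.0  # molecules per haplotype per target
    nb_size: float = 8.0  # negative-binomial size (depth overdispersion)
    error_rate: float = 1e-4
    conversion_efficiency: float = 0.99  # P(unmethylated CpG C reads T)
    conversion_failure_rate: float = 0.01  # P(CpH C stays C)
    duplicate_rate: float = 0.05
    base_quality: int = 40
    flip_prob: float = 0.5
    depth_multipliers: dict[str, float] = field(
        default_factory=lambda: {"CACNA1D": 0.02}
    )

    def __post_init__(self) -> None:
        for name in (
            "error_rate",
            "conversion_efficiency",
            "conversion_failure_rate",
            "duplicate_rate",
            "flip_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class SubjectTruth:
    subject_id: str
    smoking: bool
    age: float
    gender: int  # 1 = female
    diagnosis: int  # 1 = patient
    exposure: float  # smoking-dose multiplier applied to the smoking shifts
    diplotypes: dict[str, tuple[tuple[int, ...], tuple[int, ...]]]
    meth_probs: dict[str, np.ndarray]  # (2 haplotypes, n_cpg) probabilities


@dataclass
class Library:
    barcode_table: BarcodeTable
    reads: list[ReadRecord]


@dataclass
class SimulatedRun:
    libraries: list[Library]
    truth: pd.DataFrame  # per-read provenance


# -- synthetic target registry ----------------------------------------------


def _cg_free_background(rng: np.random.Generator, length: int) -> np.ndarray:
    arr = rng.choice(_BASES, size=length, p=[0.3, 0.25, 0.15, 0.3])
    cg = (arr[:-1] == _C) & (arr[1:] == _G)
    arr[1:][cg] = 65  # G -> A kills the dinucleotide without creating a new one
    return arr


def _plant_cpgs(rng: np.random.Generator, arr: np.ndarray, k: int) -> list[int]:
    length = len(arr)
    chosen: list[int] = []
    for cand in rng.permutation(length - 3) + 1:
        if all(abs(cand - c) > 2 for c in chosen):
            chosen.append(int(cand))
            if len(chosen) == k:
                break
    if len(chosen) < k:
        raise ValueError("amplicon too short for requested CpG count")
    for c in chosen:
        arr[c] = _C
        arr[c + 1] = _G
        if arr[c - 1] == _C:  # avoid an accidental upstream CG
            arr[c - 1] = _T
        if c + 2 < length and arr[c + 2] == _G and arr[c + 1] == _C:
            arr[c + 2] = 65
    return sorted(chosen)


def synthetic_registry(
    seed: int = 0,
    geometry: Sequence[tuple] = DEFAULT_GEOMETRY,
    with_cpg_snp: bool = True,
) -> list[TargetDef]:
    """Build a synthetic amplicon registry with planted CpGs and SNPs.

    Each target gets a CG-free random background with exactly the requested
    number of planted CpG dinucleotides, one usable sorting SNP (A/G on
    plus-strand targets, A/T on minus-strand ones, so the alleles survive
    bisulfite collapse) and, on the first target, one CpG-SNP destined for
    masking.  Sequences are labelled synthetic via their sim* chromosomes.
    """
    targets = []
    ss = np.random.SeedSequence(seed)
    for child, (label, probe, chrom, length, strand, n_cpg) in zip(
        ss.spawn(len(geometry)), geometry
    ):
        rng = np.random.default_rng(child)
        arr = _cg_free_background(rng, length)
        cpg_local = _plant_cpgs(rng, arr, n_cpg)
        cpg_set = set(cpg_local)
        # usable sorting SNP roughly a third of the way in
        li = None
        for cand in range(length // 3, length - 2):
            near_cpg = any(cand - 1 <= c <= cand + 1 for c in cpg_set)
            if not near_cpg and arr[cand - 1] != _C and arr[cand + 1] != _G:
                li = cand
                break
        if li is None:
            raise ValueError("could not place sorting SNP")
        start, end = 1, length
        if strand == "+":
            arr[li] = 65  # plus-strand ref allele A
            pos = start + li
            ref_a, alt_a = "A", "G"
        else:
            arr[li] = _T  # amplified-strand T = plus-strand A
            pos = end - li
            ref_a, alt_a = "A", "T"
        snps = [SnpDef(f"snp_{label}", pos, ref_a, alt_a)]
        seq = arr.tobytes().decode()
        t = TargetDef(
            gene_label=label,
            reference_cpg=probe,
            chrom=chrom,
            start=start,
            end=end,
            strand=strand,
            expected_cpg_count=n_cpg,
            snps=snps,
            reference_seq=seq,
        )
        positions = genomic_cpg_positions(t)
        assert len(positions) == n_cpg, f"{label}: planted {len(positions)} != {n_cpg}"
        t.index_cpg_pos = positions[n_cpg // 2]
        if with_cpg_snp and label == geometry[0][0] and strand == "+":
            # destroyable CpG: plus-strand C -> A at the third CpG
            t.snps.append(SnpDef(f"cpgsnp_{label}", positions[2], "C", "A", True))
        targets.append(t)
    return targets


# -- cohort ------------------------------------------------------------------


def default_baselines(
    targets: Sequence[TargetDef], seed: int = 0
) -> dict[str, np.ndarray]:
    """Smooth per-CpG baseline methylation profiles (logit random walk in
    roughly [0.35, 0.85]), one array per target in ascending genomic order."""
    out = {}
    ss = np.random.SeedSequence((seed, 101))
    for child, t in zip(ss.spawn(len(targets)), targets):
        rng = np.random.default_rng(child)
        k = t.expected_cpg_count
        walk = logit(0.7) + np.cumsum(rng.normal(0.0, 0.2, size=k))
        walk = np.clip(walk, logit(0.35), logit(0.85))
        out[t.gene_label] = expit(walk)
    return out


def default_effects(
    targets: Sequence[TargetDef],
    smoking_shift: float = -1.5,
    n_smoking_cpgs: int = 3,
    asm_shift: float = 1.0,
    asm_targets: Sequence[str] = ("AHRR", "IER3"),
) -> tuple[dict[str, dict[int, float]], dict[str, dict[int, float]]]:
    """Study-condition effect maps: a smoking shift at the index CpG and its
    flanking neighbours on every target, and an ASM shift at one CpG (the
    index neighbour) in two targets."""
    smoking: dict[str, dict[int, float]] = {}
    asm: dict[str, dict[int, float]] = {}
    for t in targets:
        k = t.expected_cpg_count
        mid = k // 2
        span = range(
            max(0, mid - (n_smoking_cpgs - 1) // 2),
            min(k, mid + n_smoking_cpgs // 2 + 1),
        )
        smoking[t.gene_label] = {o: smoking_shift for o in span}
        if t.gene_label in asm_targets:
            # ASM sits on the index CpG itself, as observed at the reference
            # CpGs of the two ASM-positive study targets
            asm[t.gene_label] = {mid: asm_shift}
    return smoking, asm


def study_conditions(targets: Sequence[TargetDef], seed: int = 0) -> CohortConfig:
    """A fully-populated CohortConfig at the study's default conditions."""
    smoking, asm = default_effects(targets)
    return CohortConfig(
        baseline_means=default_baselines(targets, seed),
        smoking_effects=smoking,
        asm_effects=asm,
        seed=seed,
    )


def simulate_cohort(
    config: CohortConfig, targets: Sequence[TargetDef]
) -> list[SubjectTruth]:
    """Draw subject covariates, diplotypes and per-haplotype CpG methylation
    probabilities.

    Each haplotype's probability at CpG ordinal c is
    inverse-logit(logit(baseline_c) + smoking_shift_c * dose
    + asm_shift_c * carries_alt), jittered by a Beta with the configured
    concentration.  ``dose`` is a per-subject exposure multiplier —
    max(0, N(1, smoker_exposure_sd)) for smokers, max(0, N(0,
    nonsmoker_exposure_sd)) otherwise — so with both spreads at zero the
    shift reduces exactly to smoking_shift_c * is_smoker.  Deterministic
    under a fixed seed.
    """
    if config.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 7)))
    baselines = config.baseline_means or default_baselines(targets, config.seed)
    smoking_eff = config.smoking_effects or {}
    asm_eff = config.asm_effects or {}

    subjects = []
    for i in range(config.n_subjects):
        smoker = bool(rng.random() < config.smoking_prevalence)
        age = float(
            rng.normal(config.age_mean, config.age_sd)
            + config.smoking_age_shift * smoker
        )
        gender = int(rng.random() < config.female_prob)
        diagnosis = int(rng.random() < config.diagnosis_prob)
        if smoker:
            dose = max(0.0, float(rng.normal(1.0, config.smoker_exposure_sd)))
        else:
            dose = max(0.0, float(rng.normal(0.0, config.nonsmoker_exposure_sd)))
        diplotypes = {}
        probs = {}
        for t in targets:
            hap_alleles = tuple(
                tuple(int(rng.random() < config.alt_freq) for _ in t.snps)
                for _ in range(2)
            )
            diplotypes[t.gene_label] = hap_alleles
            base = baselines[t.gene_label]
            k = len(base)
            shift = np.zeros((2, k))
            for o, s in smoking_eff.get(t.gene_label, {}).items():
                shift[:, o] += s * dose
            snp = usable_sorting_snp(t)
            if snp is not None:
                snp_idx = next(
                    j for j, s in enumerate(t.snps) if s.snp_id == snp.snp_id
                )
                for h in range(2):
                    if hap_alleles[h][snp_idx] == 1:
                        for o, s in asm_eff.get(t.gene_label, {}).items():
                            shift[h, o] += s
            p = expit(logit(np.clip(base, 1e-6, 1 - 1e-6))[None, :] + shift)
            if math.isfinite(config.dispersion):
                kappa = config.dispersion
                p = np.clip(p, 1e-6, 1 - 1e-6)
                p = rng.beta(p * kappa, (1.0 - p) * kappa)
            probs[t.gene_label] = p
        subjects.append(
            SubjectTruth(
                subject_id=f"S{i:03d}",
                smoking=smoker,
                age=age,
                gender=gender,
                diagnosis=diagnosis,
                exposure=dose,
                diplotypes=diplotypes,
                meth_probs=probs,
            )
        )
    return subjects


def covariate_frame(subjects: Sequence[SubjectTruth]) -> pd.DataFrame:
    """Subject-level covariates (smoking, age, gender, diagnosis), indexed by id."""
    return pd.DataFrame(
        {
            "smoking": [int(s.smoking) for s in subjects],
            "age": [s.age for s in subjects],
            "gender": [s.gender for s in subjects],
            "diagnosis": [s.diagnosis for s in subjects],
        },
        index=pd.Index([s.subject_id for s in subjects], name="sample"),
    )


# -- matrix-level sampling ---------------------------------------------------


def sample_haplo_matrix(
    subjects: Sequence[SubjectTruth],
    targets: Sequence[TargetDef],
    depth: int = 30,
    seed: int = 0,
) -> HaploMethMatrix:
    """Binomially sample per-haplotype methylation rates at a fixed depth.

    Heterozygotes (at the sorting SNP) yield two rows at ``depth`` reads each;
    homozygotes one pooled row at ``2 * depth``.  Columns are ascending
    genomic CpG positions; ``n`` is the cohort size.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 13)))
    rates: dict[str, pd.DataFrame] = {}
    cell_depth: dict[str, pd.DataFrame] = {}
    row_depth: dict[str, pd.Series] = {}
    for t in targets:
        snp = usable_sorting_snp(t)
        snp_idx = (
            next(j for j, s in enumerate(t.snps) if s.snp_id == snp.snp_id)
            if snp is not None
            else None
        )
        positions = (
            genomic_cpg_positions(t)
            if t.reference_seq is not None
            else list(range(t.expected_cpg_count))
        )
        index, rows, drows, rdepth = [], [], [], []
        for s in subjects:
            p = s.meth_probs[t.gene_label]
            if snp_idx is None:
                alleles = (0, 0)
            else:
                alleles = (
                    s.diplotypes[t.gene_label][0][snp_idx],
                    s.diplotypes[t.gene_label][1][snp_idx],
                )
            if alleles[0] != alleles[1]:
                for h in range(2):
                    label = ALT if alleles[h] else REF
                    counts = rng.binomial(depth, p[h])
                    index.append((s.subject_id, label))
                    rows.append(counts / depth)
                    drows.append(np.full(len(positions), depth))
                    rdepth.append(depth)
            else:
                label = ALT if alleles[0] else REF
                counts = rng.binomial(depth, p[0]) + rng.binomial(depth, p[1])
                index.append((s.subject_id, label))
                rows.append(counts / (2 * depth))
                drows.append(np.full(len(positions), 2 * depth))
                rdepth.append(2 * depth)
        idx = pd.MultiIndex.from_tuples(index, names=["sample", "allele"])
        rates[t.gene_label] = pd.DataFrame(rows, index=idx, columns=positions)
        cell_depth[t.gene_label] = pd.DataFrame(drows, index=idx, columns=positions)
        row_depth[t.gene_label] = pd.Series(rdepth, index=idx)
    return HaploMethMatrix(rates, cell_depth, row_depth, n=len(subjects))


# -- read-level simulation ---------------------------------------------------


def _haplotype_seq(t: TargetDef, alleles: Sequence[int]) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    seq = list(t.reference_seq)
    for snp, a in zip(t.snps, alleles):
        base = snp.alt_allele if a else snp.ref_allele
        if len(base) != 1:
            continue
        if t.strand == "-":
            base = comp[base]
        seq[t.local_index(snp.position)] = base
    return "".join(seq)


def simulate_reads(
    subjects: Sequence[SubjectTruth],
    targets: Sequence[TargetDef],
    readcfg: ReadSimConfig | None = None,
    seed: int = 0,
) -> SimulatedRun:
    """Emit barcoded bisulfite reads plus a per-read truth table.

    Every CpG cytosine of a sampled haplotype molecule reads C with that
    molecule's drawn methylation state (unmethylated Cs convert to T with
    ``conversion_efficiency``); every CpH cytosine reads T except with
    ``conversion_failure_rate``; sequencing errors are uniform substitutions;
    duplicates are exact byte copies.  Subjects beyond 96 roll over into
    additional barcode libraries.
    """
    cfg = readcfg or ReadSimConfig()
    for t in targets:
        if t.reference_seq is None:
            raise ValueError(f"{t.gene_label} has no reference_seq")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 29)))

    libraries: list[Library] = []
    chunks = [subjects[i : i + 96] for i in range(0, len(subjects), 96)]
    truth_rows = []
    counter = 0
    for lib_idx, chunk in enumerate(chunks):
        table = default_barcode_table([s.subject_id for s in chunk])
        code_of = {sid: pair for pair, sid in table.sample_map.items()}
        lib_reads: list[ReadRecord] = []
        for s in chunk:
            code1, code2 = code_of[s.subject_id]
            for t in targets:
                ref_positions = genomic_cpg_positions(t)
                pos_to_ord = {p: o for o, p in enumerate(ref_positions)}
                mult = cfg.depth_multipliers.get(t.gene_label, 1.0)
                mean = cfg.mean_depth * mult
                for h in range(2):
                    if mean <= 0:
                        continue
                    p_nb = cfg.nb_size / (cfg.nb_size + mean)
                    n_mol = int(rng.negative_binomial(cfg.nb_size, p_nb))
                    if n_mol == 0:
                        continue
                    hap_seq = _haplotype_seq(t, s.diplotypes[t.gene_label][h])
                    arr = np.frombuffer(hap_seq.encode(), dtype=np.uint8).copy()
                    is_c = arr == _C
                    next_g = np.zeros_like(is_c)
                    next_g[:-1] = arr[1:] == _G
                    cg_local = np.nonzero(is_c & next_g)[0]
                    cph_local = np.nonzero(is_c & ~next_g)[0]
                    probs = np.array(
                        [
                            s.meth_probs[t.gene_label][
                                h, pos_to_ord[t.cpg_genomic_from_local(int(i))]
                            ]
                            if t.cpg_genomic_from_local(int(i)) in pos_to_ord
                            else 0.7
                            for i in cg_local
                        ]
                    )
                    mat = np.tile(arr, (n_mol, 1))
                    meth = rng.random((n_mol, len(cg_local))) < probs
                    converts = rng.random((n_mol, len(cg_local))) < cfg.conversion_efficiency
                    cpg_base = np.where(meth | ~converts, _C, _T)
                    mat[:, cg_local] = cpg_base
                    stays = rng.random((n_mol, len(cph_local))) < cfg.conversion_failure_rate
                    mat[:, cph_local] = np.where(stays, _C, _T)
                    if cfg.error_rate > 0:
                        err = rng.random(mat.shape) < cfg.error_rate
                        codes = np.array(
                            [_CODE.get(b, 0) for b in range(256)], dtype=np.uint8
                        )[mat]
                        shift = rng.integers(1, 4, size=mat.shape)
                        newbase = _BASES[(codes + shift) % 4]
                        mat = np.where(err, newbase, mat).astype(np.uint8)
                    sort_snp = usable_sorting_snp(t)
                    sort_allele = ""
                    if sort_snp is not None:
                        k = next(
                            j for j, sn in enumerate(t.snps) if sn.snp_id == sort_snp.snp_id
                        )
                        sort_allele = ALT if s.diplotypes[t.gene_label][h][k] else REF
                    ref_locals = [
                        (t.local_index(p) if t.strand == "+" else t.end - p - 1)
                        for p in ref_positions
                    ]
                    local_to_col = {int(i): c for c, i in enumerate(cg_local)}
                    for mi in range(n_mol):
                        insert = mat[mi].tobytes().decode()
                        full = wrap_insert(insert, code1, code2)
                        if rng.random() < cfg.flip_prob:
                            full = revcomp(full)
                        meth_str = "".join(
                            (
                                "."
                                if rl not in local_to_col
                                else ("1" if meth[mi, local_to_col[rl]] else "0")
                            )
                            for rl in ref_locals
                        )
                        copies = 1
                        while rng.random() < cfg.duplicate_rate:
                            copies += 1
                        for c in range(copies):
                            rid = f"m{counter:08d}"
                            counter += 1
                            lib_reads.append(
                                ReadRecord(
                                    read_id=rid,
                                    sequence=full,
                                    qualities=np.full(len(full), cfg.base_quality),
                                )
                            )
                            truth_rows.append(
                                (
                                    rid,
                                    s.subject_id,
                                    t.gene_label,
                                    h,
                                    sort_allele,
                                    c > 0,
                                    meth_str,
                                    lib_idx,
                                )
                            )
        libraries.append(Library(barcode_table=table, reads=lib_reads))
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "read_id",
            "subject",
            "target",
            "haplotype",
            "sort_allele",
            "duplicate",
            "meth",
            "library",
        ],
    )
    return SimulatedRun(libraries=libraries, truth=truth)
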