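"""End-to-end orchestration: simulate -> demux -> align -> QC -> matrices ->
association statistics -> prediction models, with per-stage counters and a
reproducible run manifest."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as al
from . import haplo, models, reads as rd, stats, synth
from .targets import TargetDef, save_targets


@dataclass
class PipelineConfig:
    """Thresholds default to the quoted QC gates: mean quality >= Q30, CpH
    unconverted fraction < 5%, minimum 5x per-haplotype depth, 80% cohort
    coverage per target."""

    out_dir: str = "asmbs_run"
    n_subjects: int = 154
    min_q: int = 30
    conv_threshold: float = 0.05
    min_depth: int = 5
    min_sample_fraction: float = 0.8
    alpha: float = 0.05
    sim_seed: int = 0
    split_seed: int = 0
    depth: float = 100.0  # molecules per haplotype (read route)
    geometry: tuple = synth.DEFAULT_GEOMETRY
    boruta_kwargs: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def process_reads(
    raw: list[rd.ReadRecord],
    table: rd.BarcodeTable,
    targets: list[TargetDef],
    min_q: int = 30,
    conv_threshold: float = 0.05,
) -> tuple[list[al.AlignedRead], dict]:
    """Quality filter, demultiplex, trim, align, conversion-filter one library.

    Returns the passing aligned reads plus per-stage counters (assigned >=
    quality-passing >= aligned >= conversion-passing, non-increasing).
    """
    counts = {"input": len(raw)}
    passing = rd.quality_filter(raw, min_mean_q=min_q)
    counts["quality_pass"] = len(passing)
    assigned, discarded, _ = rd.demultiplex(passing, table)
    counts["assigned"] = len(assigned)
    counts["demux_discarded"] = discarded
    aligner = al.AmpliconAligner(targets)
    aligned = []
    for read in assigned:
        insert = rd.trim_flanks(read)
        if insert is None:
            continue
        ar = aligner.align_insert(
            insert.sequence, read_id=read.read_id, sample=read.assigned_sample
        )
        if ar is not None:
            aligned.append(ar)
    counts["aligned"] = len(aligned)
    conv_pass = [ar for ar in aligned if al.filter_conversion(ar, conv_threshold)]
    counts["conversion_pass"] = len(conv_pass)
    return conv_pass, counts


def run_pipeline(config: PipelineConfig) -> dict:
    """Synthetic end-to-end run; writes all reports under ``out_dir`` and
    returns the manifest (also written as manifest.json)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seeds": {"sim": config.sim_seed, "split": config.split_seed},
        "stages": {},
    }

    targets = synth.synthetic_registry(config.sim_seed, geometry=config.geometry)
    save_targets(targets, out / "registry.json")
    cohort = synth.study_conditions(targets, config.sim_seed)
    cohort.n_subjects = config.n_subjects
    subjects = synth.simulate_cohort(cohort, targets)
    covariates = synth.covariate_frame(subjects)
    covariates.to_csv(out / "sample_sheet.tsv", sep="\t")
    readcfg = synth.ReadSimConfig(mean_depth=config.depth)
    run = synth.simulate_reads(subjects, targets, readcfg, seed=config.sim_seed)
    run.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    for i, lib in enumerate(run.libraries):
        rd.write_fastq(lib.reads, out / f"library{i}.fastq")
    manifest["stages"]["simulate"] = {
        "subjects": len(subjects),
        "reads": int(sum(len(l.reads) for l in run.libraries)),
        "libraries": len(run.libraries),
    }

    aligned_all: list[al.AlignedRead] = []
    proc_counts: dict[str, int] = {}
    for lib in run.libraries:
        conv_pass, counts = process_reads(
            lib.reads, lib.barcode_table, targets, config.min_q, config.conv_threshold
        )
        aligned_all.extend(conv_pass)
        for k, v in counts.items():
            proc_counts[k] = proc_counts.get(k, 0) + v
    manifest["stages"]["process"] = proc_counts

    deduped = al.deduplicate(aligned_all)
    manifest["stages"]["deduplicate"] = {"unique": len(deduped)}
    conv_rates = {}
    for t in targets:
        r = al.conversion_rate([a for a in deduped if a.gene_label == t.gene_label])
        conv_rates[t.gene_label] = r
    manifest["conversion_rate"] = conv_rates
    al.write_sam(deduped, targets, out / "aligned.sam")

    matrix = haplo.build_matrix(deduped, targets)
    matrix, removed = haplo.apply_depth_filter(matrix, config.min_depth)
    matrix, dropped = haplo.check_target_coverage(
        matrix, covariates.index, config.min_sample_fraction
    )
    matrix = haplo.mask_cpg_snps(matrix, targets)
    manifest["stages"]["matrix"] = {
        "targets_retained": matrix.targets(),
        "targets_dropped": dropped,
        "rows_removed_depth": len(removed),
    }
    if not matrix.targets() or len(matrix.samples()) < 4:
        manifest["status"] = "no-model"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return manifest
    matrix = haplo.impute_missing(matrix)
    haplo.matrix_to_tsv(matrix, out / "matrix.tsv")

    asm = stats.asm_test(matrix, covariates)
    scan = stats.covariate_scan(matrix, covariates)
    scan.to_csv(out / "covariate_tests.tsv", sep="\t", index=False)
    asm_rows = []
    for label, res in asm.items():
        for pos, r in res.iterrows():
            asm_rows.append((label, pos, r["stat"], r["p"], r["adj_p"], r["direction"]))
    pd.DataFrame(
        asm_rows, columns=["target", "pos", "stat", "p", "adj_p", "direction"]
    ).to_csv(out / "asm_tests.tsv", sep="\t", index=False)

    reports = models.evaluate_three_models(
        matrix,
        covariates,
        targets,
        seed=config.split_seed,
        boruta_kwargs=config.boruta_kwargs,
    )
    model_json = {
        name: {
            "auc": rep.auc,
            "selected": {k: [int(c) for c in v] for k, v in rep.selected.items()},
            "stacked_coef": list(map(float, rep.stacked_coef)),
            "stacked_intercept": rep.stacked_intercept,
            "n_train": len(rep.train_subjects),
            "n_test": len(rep.test_subjects),
        }
        for name, rep in reports.items()
    }
    (out / "model_report.json").write_text(json.dumps(model_json, indent=1))
    for name, rep in reports.items():
        pd.DataFrame({"fpr": rep.fpr, "tpr": rep.tpr}).to_csv(
            out / f"roc_{name.replace('.', '_')}.tsv", sep="\t", index=False
        )
    manifest["stages"]["predict"] = {name: rep.auc for name, rep in reports.items()}
    manifest["status"] = "ok"
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
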