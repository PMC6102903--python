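"""End-to-end orchestration of the read- and contig-based workflow.

The default preset mirrors the analysis order used for virome studies:
quality filtering → (optional subsampling) → tiered read classification →
taxonomic profiles, with an optional contig path (ORF calling → per-ORF
classification → majority vote → grouped GenBank output). Decontamination
runs before any transmission analysis. All outputs are tabular or GenBank;
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import logging
import os
import time
from typing import Sequence

import pandas as pd

from . import contigs as contig_mod
from . import reads as read_mod
from .config import PipelineConfig
from .seqio import SequenceRecord, read_fasta, read_fastq, write_annotated_contigs
from .taxonomy import ReferenceTier, load_tier

logger = logging.getLogger("viromekit")


def load_configured_tiers(config: PipelineConfig, kind: str = "nucleotide") -> list[ReferenceTier]:
    if not config.tiers:
        raise ValueError("config lists no reference tiers")
    return [
        load_tier(spec["name"], priority, spec["fasta"], spec.get("taxonomy"), kind=kind)
        for priority, spec in enumerate(config.tiers, start=1)
    ]


def load_reads(path) -> list[SequenceRecord]:
    text = str(path)
    stripped = text[:-3] if text.endswith(".gz") else text
    if stripped.endswith((".fastq", ".fq")):
        return list(read_fastq(path))
    return list(read_fasta(path))


def _log_stage(stage: str, n_in: int, n_kept: int, started: float,
               rows: list[dict]) -> None:
    n_removed = n_in - n_kept
    logger.info("stage=%s in=%d kept=%d removed=%d seconds=%.2f",
                stage, n_in, n_kept, n_removed, time.time() - started)
    rows.append({"stage": stage, "reads_in": n_in, "reads_kept": n_kept,
                 "reads_removed": n_removed})


def run_pipeline(config: PipelineConfig, reads_path=None, contigs_path=None,
                 tiers: Sequence[ReferenceTier] | None = None,
                 protein_tiers: Sequence[ReferenceTier] | None = None,
                 out_dir=None) -> str:
    """Execute the preset workflow; returns the output directory.

    Stages log read counts in/out; every numeric threshold comes from
    ``config``. A stage failure aborts with the stage name while earlier
    outputs remain on disk.
    """
    out_dir = str(out_dir or config.out_dir)
    os.makedirs(out_dir, exist_ok=True)
    stage_rows: list[dict] = []
    stage = "setup"
    try:
        if reads_path is not None:
            if tiers is None:
                stage = "load-tiers"
                tiers = load_configured_tiers(config)
            stage = "load-reads"
            raw = load_reads(reads_path)

            stage = "quality-filter"
            started = time.time()
            kept, _ = read_mod.quality_filter(raw, config.min_read_len,
                                              config.min_mean_quality)
            _log_stage(stage, len(raw), len(kept), started, stage_rows)

            if config.subsample_n is not None and config.subsample_n < len(kept):
                stage = "subsample"
                started = time.time()
                kept = read_mod.subsample(kept, config.subsample_n, config.seed)
                _log_stage(stage, len(raw), len(kept), started, stage_rows)

            stage = "classify-reads"
            started = time.time()
            params = config.alignment_params()
            classifications = read_mod.classify_reads(kept, tiers, params)
            n_classified = sum(c.classified for c in classifications)
            _log_stage(stage, len(kept), n_classified, started, stage_rows)
            read_mod.write_assignments(classifications,
                                       os.path.join(out_dir, "read_assignments.tsv"))

            stage = "profile"
            for rank in (config.rank, "family"):
                prof = read_mod.profile(classifications, rank)
                read_mod.write_profile(prof, os.path.join(out_dir, f"profile_{rank}.tsv"))
            viral = read_mod.viral_profile(classifications, config.rank)
            read_mod.write_profile(viral, os.path.join(out_dir, "profile_viral.tsv"))

        if contigs_path is not None:
            if protein_tiers is None:
                raise ValueError("contig classification requires protein tiers")
            stage = "annotate-contigs"
            started = time.time()
            contig_records = list(read_fasta(contigs_path))
            annotated = contig_mod.annotate_contigs(
                contig_records, protein_tiers,
                config.alignment_params(protein=True),
                min_len_aa=config.min_orf_len_aa,
                min_len_nt=config.contig_gate_nt)
            _log_stage(stage, len(contig_records),
                       sum(cls.classified for _, cls, _ in annotated),
                       started, stage_rows)
            table = contig_mod.classification_table([cls for _, cls, _ in annotated])
            table.to_csv(os.path.join(out_dir, "contig_classification.tsv"),
                         sep="\t", index=False)
            write_annotated_contigs(annotated, os.path.join(out_dir, "genbank"),
                                    group_rank="family")

        pd.DataFrame(stage_rows, columns=["stage", "reads_in", "reads_kept",
                                          "reads_removed"]) \
            .to_csv(os.path.join(out_dir, "stage_log.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out_dir
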