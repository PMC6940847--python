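"""One-sample survey orchestration: QC -> k-mer survey -> GC-depth -> SSR -> markers.

``run_full_survey`` wires the stage modules together on either real FASTQ
input or a simulation spec, writes machine-readable outputs (JSON report plus
per-table TSVs) and records enough provenance to re-run bit-identically.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, StageError
from .gcdepth import GcDepthWindow, load_fasta, window_depth, window_gc, windows_to_tsv
from .kmerspec import (
    DEFAULT_K,
    DEFAULT_MIN_DEPTH,
    DEFAULT_REPEAT_MULTIPLIER,
    KmerIndex,
    SurveyEstimates,
    estimate_from_histogram,
)
from .marker import MarkerHit, kmer_containment
from .readqc import QcReport, ReadPair, filter_read_pairs, read_fastq_pairs
from .simulate import SimulationSpec, inject_artifacts, simulate_diploid_genome, simulate_reads
from .ssr import SsrSummary, loci_to_misa_table, scan_sequences, summarize_ssrs

logger = logging.getLogger("genomesurvey")


def percent_ratio(part: float, whole: float, decimals: int = 1) -> float:
    """Plain percent ratio utility (e.g. completeness: found / searched)."""
    if whole <= 0:
        raise ConfigurationError("percent_ratio: whole must be positive")
    return round(100.0 * part / whole, decimals)


@dataclass
class SurveyConfig:
    """Inputs and per-stage parameters for one survey run."""

    simulation: Optional[SimulationSpec] = None
    fastq1: Optional[str] = None
    fastq2: Optional[str] = None
    assembly: Optional[str] = None  # FASTA; simulated runs default to haplotype A
    markers: Dict[str, str] = field(default_factory=dict)  # id -> sequence
    adapter: Optional[str] = None
    k: int = DEFAULT_K
    min_depth: int = DEFAULT_MIN_DEPTH
    repeat_multiplier: float = DEFAULT_REPEAT_MULTIPLIER
    window: int = 10_000
    max_gap: int = 100
    min_flank: int = 100
    outdir: Optional[str] = None

    def validate(self) -> None:
        if self.simulation is None and not (self.fastq1 and self.fastq2):
            raise ConfigurationError(
                "config needs either a simulation spec or paired FASTQ paths"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SurveyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationSpec(**sim)
        return cfg


@dataclass
class SurveyReport:
    qc: QcReport
    estimates: SurveyEstimates
    ssr_summary: Optional[SsrSummary] = None
    gc_depth_path: Optional[str] = None
    marker_hits: List[MarkerHit] = field(default_factory=list)
    provenance: Dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "qc": self.qc.to_dict(),
            "estimates": asdict(self.estimates),
            "estimates_display": self.estimates.to_row(),
            "ssr_summary": self.ssr_summary.to_dict() if self.ssr_summary else None,
            "gc_depth_path": self.gc_depth_path,
            "marker_hits": [asdict(h) for h in self.marker_hits],
            "provenance": self.provenance,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise StageError(name, exc) from exc

    return wrap


def run_full_survey(config: SurveyConfig) -> SurveyReport:
    """Run every configured stage and consolidate one report.

    Any stage failure aborts with the stage name; outputs written before the
    failure are retained under ``config.outdir``.
    """
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    # --- input stage: simulate or read FASTQ ---------------------------------
    assembly_seqs: Optional[Dict[str, str]] = None
    try:
        if config.simulation is not None:
            spec = config.simulation
            truth = simulate_diploid_genome(spec)
            pairs = simulate_reads(truth, spec)
            pairs, _tags = inject_artifacts(pairs, spec)
            assembly_seqs = {"hapA": truth.haplotype_a}
            logger.info("simulated %d pairs from a %d bp diploid genome", len(pairs), spec.genome_length)
        else:
            pairs = list(read_fastq_pairs(config.fastq1, config.fastq2))
            logger.info("read %d pairs from FASTQ", len(pairs))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("input", exc) from exc
    if config.assembly:
        assembly_seqs = load_fasta(config.assembly)

    # --- qc ------------------------------------------------------------------
    clean, qc = _stage("readqc")(filter_read_pairs, pairs, config.adapter)
    logger.info("qc: %d/%d pairs kept (%.2f%% effective)", qc.pairs_out, qc.pairs_in, qc.effective_rate)

    # --- k-mer survey --------------------------------------------------------
    def _kmer() -> tuple[KmerIndex, SurveyEstimates]:
        seqs: List[str] = []
        for p in clean:
            seqs.append(p.seq1)
            seqs.append(p.seq2)
        index = KmerIndex.from_sequences(seqs, k=config.k)
        hist = index.histogram()
        est = estimate_from_histogram(
            hist, min_depth=config.min_depth, repeat_multiplier=config.repeat_multiplier
        )
        if outdir:
            hist.to_tsv(outdir / "histogram.tsv")
        return index, est

    index, estimates = _stage("kmerspec")(_kmer)
    logger.info(
        "kmer survey: peak %dx, genome %.2f Mbp, het %.2f%%, repeats %.2f%%",
        estimates.peak_depth,
        estimates.genome_size / 1e6,
        estimates.heterozygosity_rate * 100,
        estimates.repeat_ratio * 100,
    )

    # --- gc-depth + ssr (need an assembly-like sequence set) -----------------
    ssr_summary = None
    gc_depth_path = None
    if assembly_seqs:
        def _gcdepth() -> str | None:
            windows = window_gc(assembly_seqs, window=config.window)
            read_length = len(clean[0].seq1) if clean else None
            window_depth(windows, assembly_seqs, index, config.k, read_length=read_length)
            if outdir:
                path = outdir / "gcdepth.tsv"
                windows_to_tsv(windows, path)
                return path.name  # relative to outdir, keeps reports seed-stable
            return None

        gc_depth_path = _stage("gcdepth")(_gcdepth)

        def _ssr() -> SsrSummary:
            loci = scan_sequences(
                assembly_seqs,
                max_gap=config.max_gap,
                min_flank=config.min_flank,
            )
            if outdir:
                loci_to_misa_table(loci).to_csv(outdir / "ssr.tsv", sep="\t", index=False)
            return summarize_ssrs(loci, sequences_examined=len(assembly_seqs))

        ssr_summary = _stage("ssr")(_ssr)
        logger.info("ssr: %d loci on %d sequences", ssr_summary.total_ssrs, ssr_summary.sequences_examined)

    # --- marker screening ----------------------------------------------------
    marker_hits: List[MarkerHit] = []
    if config.markers:
        def _markers() -> List[MarkerHit]:
            hits = []
            for mid, seq in config.markers.items():
                containment = kmer_containment(seq, index, config.k)
                hits.append(
                    MarkerHit(marker_id=mid, present=containment >= 0.5, kmer_containment=containment)
                )
            return hits

        marker_hits = _stage("marker")(_markers)

    provenance = {
        "version": __version__,
        "parameters": {
            "k": config.k,
            "min_depth": config.min_depth,
            "repeat_multiplier": config.repeat_multiplier,
            "window": config.window,
            "max_gap": config.max_gap,
            "min_flank": config.min_flank,
            "adapter": config.adapter,
        },
        "inputs": (
            {"simulation": asdict(config.simulation)}
            if config.simulation is not None
            else {"fastq1": config.fastq1, "fastq2": config.fastq2}
        ),
        "seed": config.simulation.seed if config.simulation is not None else None,
    }
    report = SurveyReport(
        qc=qc,
        estimates=estimates,
        ssr_summary=ssr_summary,
        gc_depth_path=gc_depth_path,
        marker_hits=marker_hits,
        provenance=provenance,
    )
    if outdir:
        report.to_json(outdir / "report.json")
        pd.DataFrame([qc.to_table_row()]).to_csv(outdir / "table1.tsv", sep="\t", index=False)
        pd.DataFrame([estimates.to_row()]).to_csv(outdir / "table2.tsv", sep="\t", index=False)
        if ssr_summary:
            pd.DataFrame([ssr_summary.to_dict()]).to_csv(outdir / "table5.tsv", sep="\t", index=False)
    return report
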