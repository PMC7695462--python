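"""End-to-end orchestration: simulate -> convert -> call -> profile.

``run_pipeline`` is the library entry point behind the command-line
interface: it builds (or loads) a donor reference, obtains reads either
from the simulator or from a SAM/BAM file, converts them to tracks,
calls footprints at the configured threshold, and writes all artefacts
(tracks TSV, footprint BED/TSV, per-strand summary, length and bin
tables, footprint maps) into one output directory.  Deterministic for a
fixed config seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import convert, peaks, profile, simulate, substrates
from .refmodel import DonorReference, load_reference

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("dloopmap")


@dataclass
class RunConfig:
    """One pipeline run.

    Either ``substrate`` (a packaged homology, embedded in a synthetic
    donor with ``flank``-nt non-homologous flanks) or ``reference_fasta``
    + ``homology_window`` must be given.  ``sam`` switches the read
    source from the simulator to an existing alignment file.
    """

    substrate: str | None = "ds98-931"
    flank: int = 1000
    reference_fasta: str | None = None
    homology_window: tuple[int, int] | None = None
    sam: str | None = None
    threshold: str = "t40w50"
    seed: int = 0
    out: str = "dloopmap_out"
    simulation: dict = field(default_factory=dict)
    bin_size: int = 100
    length_cutoff: int = 400
    write_png: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "homology_window" in raw and raw["homology_window"] is not None:
            raw["homology_window"] = tuple(raw["homology_window"])
        return cls(**raw)


@dataclass
class PipelineResult:
    reference: DonorReference
    counts: convert.FilterCounts
    summaries: dict
    out_dir: Path
    n_footprints: int


def _build_reference(config: RunConfig) -> DonorReference:
    if config.reference_fasta:
        if config.homology_window is None:
            raise ValueError("homology_window is required with reference_fasta")
        return load_reference(config.reference_fasta, config.homology_window)
    if config.substrate is None:
        raise ValueError("either substrate or reference_fasta must be set")
    return substrates.build_donor(config.substrate, flank=config.flank)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run all stages and write artefacts under ``config.out``."""
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    threshold = peaks.parse_threshold(config.threshold)

    try:
        reference = _build_reference(config)
    except Exception as exc:
        raise RuntimeError(f"stage refmodel: {exc}") from exc
    log.info("reference %s: %d nt, homology [%d, %d)", reference.name,
             len(reference), reference.homology_start, reference.homology_end)

    if config.sam:
        reads = simulate.read_sam(config.sam)
        log.info("loaded %d alignments from %s", len(reads), config.sam)
    else:
        sim_kwargs = dict(config.simulation)
        sim_kwargs.setdefault("seed", config.seed)
        sim_config = simulate.SimulationConfig(**sim_kwargs)
        reads, truth = simulate.simulate_dataset(sim_config, reference)
        simulate.write_sam(reads, reference, out / "reads.sam")
        simulate.write_truth_bed(truth, out / "truth.bed", ref_name=reference.name)
        simulate.write_manifest(truth, out / "truth.tsv")
        with open(out / "simulation_config.yaml", "w") as fh:
            yaml.safe_dump(sim_config.to_dict(), fh)
        log.info("simulated %d molecules (%d with a D-loop)",
                 len(reads), sum(t.has_dloop for t in truth))

    tracks, counts = convert.process_reads(reads, reference)
    convert.write_tracks_tsv(tracks, out / "tracks.tsv")
    log.info(
        "reads: %d in = %d length-filtered + %d unknown-strand + %d kept "
        "(%d top, %d bottom)",
        counts.n_input, counts.n_length_filtered, counts.n_unknown_strand,
        counts.n_kept, counts.n_kept_top, counts.n_kept_bottom,
    )

    fps_by_read = peaks.call_peaks_all(tracks, threshold)
    all_fps = [fp for fps in fps_by_read.values() for fp in fps]
    peaks.write_footprints_bed(all_fps, reference, out / "footprints.bed")
    peaks.write_footprints_tsv(all_fps, out / "footprints.tsv")

    summaries = profile.summarize_sample(tracks, fps_by_read, config.length_cutoff)
    import pandas as pd

    pd.DataFrame([s.to_row() for s in summaries.values()]).to_csv(
        out / "summary.tsv", sep="\t", index=False
    )
    for strand, s in summaries.items():
        if s.percent_peak is not None:
            log.info("%s strand: %d/%d reads with footprint (%% Peak = %.2f) at %s",
                     strand, s.n_peak_reads, s.n_total_reads, s.percent_peak, threshold)

    top_fps = [fp for fp in all_fps if fp.strand == "top"]
    dist = profile.bin_distribution(top_fps, reference, config.bin_size) if top_fps else None
    if dist is not None:
        dist.to_frame().to_csv(out / "bins_top.tsv", sep="\t", index=False)
    if all_fps:
        pd.DataFrame(
            {"read_id": [fp.read_id for fp in all_fps],
             "strand": [fp.strand for fp in all_fps],
             "length": [fp.length for fp in all_fps]}
        ).to_csv(out / "lengths.tsv", sep="\t", index=False)

    for strand in ("top", "bottom"):
        strand_tracks = [t for t in tracks if t.active_strand == strand]
        if strand_tracks:
            profile.export_footprint_map(
                strand_tracks, fps_by_read, reference,
                out / f"map_{strand}", png=config.write_png,
            )

    return PipelineResult(
        reference=reference,
        counts=counts,
        summaries=summaries,
        out_dir=out,
        n_footprints=len(all_fps),
    )
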