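"""End-to-end synthetic demonstration: genome -> coverage -> peaks -> motif.

``run_demo`` plants operator sites in a synthetic prophage-scale
genome, simulates replicate coverage, calls and merges peaks, discovers
the operator motif under the peaks, scans the genome for occurrences,
and writes FASTA/bedGraph/BED/MEME outputs plus a deterministic
plain-text report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as mio
from .exceptions import InputError, MrprError, NoCandidatePeakError
from .motif import ZoopsMotifEM, extract_peak_sequences
from .peaks import RickerPeakCaller
from .simulate import (
    DEFAULT_OPERATOR_CONSENSUS,
    CoverageSimConfig,
    gen_genome,
    plant_sites,
    simulate_coverage,
)

logger = logging.getLogger("mrpr")

__all__ = ["PipelineConfig", "run_demo", "default_site_positions"]


def default_site_positions(n_sites: int, genome_length: int, margin: int = 5000) -> list[int]:
    """Evenly spaced planting positions with a safety margin at the ends."""
    if n_sites == 0:
        return []
    return list(
        np.linspace(margin, genome_length - margin, n_sites).astype(int)
    )


@dataclass
class PipelineConfig:
    """Parameters of the synthetic end-to-end demonstration."""

    seed: int = 1
    out_dir: str = "mrpr_demo"
    genome_length: int = 130_000
    gc: float = 0.44
    n_sites: int = 10
    consensus: str = DEFAULT_OPERATOR_CONSENSUS
    mutation_rate: float = 0.0
    mean_depth: float = 50.0
    enrichment: float = 20.0
    peak_shape_sd: float = 75.0
    n_replicates: int = 3
    threshold_mult: float = 3.0
    min_motif_width: int = 8
    max_motif_width: int = 20
    motif_restarts: int = 10
    flank: int = 50
    scan_threshold_frac: float = 0.8

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Sectioned ``key = value`` config file; unknown keys are rejected."""
        known = {f.name: f.type for f in fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line or (line.startswith("[") and line.endswith("]")):
                    continue
                if "=" not in line:
                    raise InputError(f"{path}:{lineno}: expected 'key = value'")
                key, value = (s.strip() for s in line.split("=", 1))
                if key not in known:
                    raise InputError(f"{path}:{lineno}: unknown key {key!r}")
                current = getattr(cls(), key)
                if isinstance(current, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(current, int):
                    kwargs[key] = int(value)
                elif isinstance(current, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        return cls(**kwargs)


def run_demo(config: PipelineConfig) -> str:
    """Run the full synthetic pipeline; returns the report text."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines: list[str] = ["# synthetic pipeline report"]
    for f in fields(config):
        lines.append(f"param {f.name} = {getattr(config, f.name)}")
        logger.info("param %s = %s", f.name, getattr(config, f.name))

    try:
        genome = gen_genome(config.genome_length, config.gc, seed=config.seed, name="synthetic_prophage")
        positions = default_site_positions(config.n_sites, config.genome_length)
        genome = plant_sites(
            genome,
            config.consensus,
            positions,
            mutation_rate=config.mutation_rate,
            seed=config.seed + 1,
        )
        mio.write_fasta({genome.name: genome.sequence}, out / "genome.fasta")
        mio.write_sites_bed(genome, out / "planted_sites.bed")
    except MrprError as exc:
        raise MrprError(f"[simulate] {exc}") from exc

    try:
        cov_cfg = CoverageSimConfig(
            mean_depth=config.mean_depth,
            peak_shape_sd=config.peak_shape_sd,
            enrichment=config.enrichment,
            noise="poisson",
            seed=config.seed + 100,
            n_replicates=config.n_replicates,
        )
        tracks = simulate_coverage(genome, cov_cfg)
        for t in tracks:
            mio.write_bedgraph(t, out / f"coverage_rep{t.replicate}.bedgraph")
    except MrprError as exc:
        raise MrprError(f"[coverage] {exc}") from exc

    try:
        caller = RickerPeakCaller(threshold_mult=config.threshold_mult)
        try:
            peaks = caller.fit(tracks).predict(tracks)
            lines.append(f"expected_peak_width = {caller.expected_width_}")
        except NoCandidatePeakError:
            peaks = []
            lines.append("expected_peak_width = NA (no enrichment detected)")
        mio.write_peaks_bed(peaks, out / "peaks.bed")
        lines.append(f"n_merged_peaks = {len(peaks)}")
    except MrprError as exc:
        raise MrprError(f"[peakcall] {exc}") from exc

    # per-site recovery table
    lines.append("site_recovery: planted_center -> nearest_summit (distance)")
    summits = np.array([p.summit for p in peaks]) if peaks else np.array([])
    for site in genome.planted_sites:
        if summits.size:
            j = int(np.argmin(np.abs(summits - site.center)))
            d = int(summits[j] - site.center)
            lines.append(f"  {site.center} -> {int(summits[j])} ({d:+d})")
        else:
            lines.append(f"  {site.center} -> none")

    if not peaks:
        lines.append("motif stage skipped: no peaks called")
    else:
        try:
            seqs = extract_peak_sequences(
                {genome.name: genome.sequence}, peaks, flank=config.flank
            )
            est = ZoopsMotifEM(
                min_width=config.min_motif_width,
                max_width=config.max_motif_width,
                restarts=config.motif_restarts,
                random_state=config.seed,
            ).fit(seqs)
            mio.write_meme(est.pwm_, out / "motif.meme")
            thr = config.scan_threshold_frac * est.pwm_.max_score()
            hits = est.scan({genome.name: genome.sequence}, thr)
            mio.write_hits_bed(hits, est.width_, out / "motif_hits.bed")
            lines.append(f"motif_width = {est.width_}")
            lines.append(f"motif_consensus = {est.pwm_.consensus()}")
            lines.append(f"n_motif_hits = {len(hits)}")
        except MrprError as exc:
            raise MrprError(f"[motif] {exc}") from exc

    report = "\n".join(lines) + "\n"
    (out / "report.txt").write_text(report)
    return report
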