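"""Readers and writers for the plain-text formats the pipeline touches.

Coverage comes in as bedGraph or wiggle (fixedStep / variableStep),
peaks go out as BED6+4, motifs as MEME minimal text so third-party
scanners can consume them, genomes as FASTA via Biopython.  All genome
coordinates are 0-based half-open on disk (BED/bedGraph convention);
wiggle input is 1-based per its spec.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import InputError
from .motif import PWM, ALPHABET, MotifHit
from .peaks import CoverageTrack, Peak

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "read_wiggle",
    "read_coverage",
    "write_peaks_bed",
    "write_hits_bed",
    "write_meme",
    "read_fasta",
    "write_fasta",
    "write_sites_bed",
]


def read_bedgraph(path, sample_id: str = "sample", replicate: int = 1) -> CoverageTrack:
    """Load a single-contig bedGraph into a per-base coverage track."""
    intervals = []
    contig = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, start, end, value = line.split()[:4]
            if contig is None:
                contig = chrom
            elif chrom != contig:
                raise InputError("multi-contig bedGraph not supported")
            intervals.append((int(start), int(end), float(value)))
    if not intervals:
        raise InputError(f"no data lines in {path}")
    length = max(e for _, e, _ in intervals)
    values = np.zeros(length)
    for s, e, v in intervals:
        values[s:e] = v
    return CoverageTrack(contig=contig, values=values, sample_id=sample_id, replicate=replicate)


def write_bedgraph(track: CoverageTrack, path, name: str | None = None) -> None:
    """Run-length-compressed bedGraph of a per-base track."""
    v = track.values
    change = np.flatnonzero(np.diff(v)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [v.size]])
    with open(path, "w") as fh:
        if name:
            fh.write(f'track type=bedGraph name="{name}"\n')
        for s, e in zip(starts, ends):
            fh.write(f"{track.contig}\t{s}\t{e}\t{v[s]:g}\n")


def read_wiggle(path, sample_id: str = "sample", replicate: int = 1) -> CoverageTrack:
    """Minimal wiggle reader (fixedStep and variableStep, span supported)."""
    contig = None
    entries: list[tuple[int, int, float]] = []  # (0-based start, span, value)
    mode = None
    pos = step = 1
    span = 1
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep") or line.startswith("variableStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                chrom = fields["chrom"]
                if contig is None:
                    contig = chrom
                elif chrom != contig:
                    raise InputError("multi-contig wiggle not supported")
                span = int(fields.get("span", 1))
                if line.startswith("fixedStep"):
                    mode = "fixed"
                    pos = int(fields["start"])
                    step = int(fields.get("step", 1))
                else:
                    mode = "variable"
                continue
            if mode == "fixed":
                entries.append((pos - 1, span, float(line)))
                pos += step
            elif mode == "variable":
                p, v = line.split()[:2]
                entries.append((int(p) - 1, span, float(v)))
            else:
                raise InputError("wiggle data before any step declaration")
    if not entries:
        raise InputError(f"no data lines in {path}")
    length = max(s + sp for s, sp, _ in entries)
    values = np.zeros(length)
    for s, sp, v in entries:
        values[s : s + sp] = v
    return CoverageTrack(contig=contig, values=values, sample_id=sample_id, replicate=replicate)


def read_coverage(path, sample_id: str = "sample", replicate: int = 1) -> CoverageTrack:
    """Dispatch on extension: .wig/.wiggle -> wiggle, else bedGraph."""
    suffix = Path(path).suffix.lower()
    if suffix in (".wig", ".wiggle"):
        return read_wiggle(path, sample_id, replicate)
    return read_bedgraph(path, sample_id, replicate)


def write_peaks_bed(peaks: list[Peak], path) -> None:
    """BED6+4: name, scaled score, strand, raw, normalized, summit, n_reps.

    The BED score column is the convolution score scaled to 0-1000
    within the file.
    """
    max_score = max((p.conv_score for p in peaks), default=1.0) or 1.0
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            scaled = int(round(1000 * max(p.conv_score, 0.0) / max_score))
            norm = p.normalized_intensity if p.normalized_intensity is not None else 0.0
            fh.write(
                f"{p.contig}\t{p.start}\t{p.end}\tpeak_{i}\t{scaled}\t.\t"
                f"{p.raw_intensity:.6g}\t{norm:.6g}\t{p.summit}\t{p.n_replicates}\n"
            )


def write_hits_bed(hits: list[MotifHit], width: int, path) -> None:
    """Motif hits as BED6 with the log-odds (bits) in the score column."""
    with open(path, "w") as fh:
        for i, h in enumerate(hits, start=1):
            fh.write(
                f"{h.contig}\t{h.start}\t{h.start + width}\thit_{i}\t"
                f"{h.log_odds:.3f}\t{h.strand}\n"
            )


def write_meme(pwm: PWM, path, name: str = "MOTIF_1") -> None:
    """MEME minimal text format (version, alphabet, background, matrix)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.4f}" for b, f in zip(ALPHABET, pwm.background)) + "\n\n"
        )
        fh.write(f"MOTIF {name}\n")
        fh.write(
            f"letter-probability matrix: alength= 4 w= {pwm.width} "
            f"nsites= {max(int(round(pwm.n_sites)), 1)} E= 0\n"
        )
        for col in pwm.probs.T:
            fh.write(" " + " ".join(f"{p:.6f}" for p in col) + "\n")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_sites_bed(genome, path) -> None:
    """Ground-truth sidecar: planted operator sites as BED4."""
    with open(path, "w") as fh:
        for s in genome.planted_sites:
            fh.write(
                f"{genome.name}\t{s.position}\t{s.position + s.width}\t{s.motif_id}\n"
            )
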