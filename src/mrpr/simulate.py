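"""Synthetic data generators with known ground truth.

Every input the pipeline consumes can be generated here: a synthetic
prophage-scale genome with operator sites planted at chosen positions,
Poisson-sampled coverage tracks with Gaussian-shaped enrichment over
those sites, tiled-peptide HDX-MS measurement tables driven by
per-residue exchange kinetics, single-site ITC titrations under the
13-injection schedule, and two-baseline Boltzmann melt curves.

All generators are bit-reproducible for a fixed seed; replicate tracks
derive sub-seeds deterministically (master seed + replicate index).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .binding import (
    InjectionSchedule,
    ITCModelParams,
    MeltCurve,
    TitrationExperiment,
    boltzmann,
    isotherm_heats,
)
from .exceptions import InputError
from .peaks import CoverageTrack

__all__ = [
    "PlantedSite",
    "SyntheticGenome",
    "CoverageSimConfig",
    "HDXSimConfig",
    "DEFAULT_OPERATOR_CONSENSUS",
    "gen_genome",
    "plant_sites",
    "simulate_coverage",
    "simulate_hdx",
    "simulate_itc",
    "simulate_dsf",
    "random_exchange_rates",
]

#: Fixed synthetic 15-bp operator consensus used by the demo pipeline.
#: An arbitrary stand-in chosen (by a seeded search) to have no strong
#: self-overlap under shift or reverse complement, so the planted motif
#: width is well defined; self-overlapping (palindromic) consensi make
#: width recovery intrinsically ambiguous.  The real operator's letters
#: play no role in any computation here.
DEFAULT_OPERATOR_CONSENSUS = "ACAGTAAGCCCATCA"

_BASES = np.array(list("ACGT"))


@dataclass
class PlantedSite:
    position: int  # 0-based start of the motif instance
    motif_id: str
    enrichment: float | None = None  # fold; None = use coverage config value
    width: int = 0

    @property
    def center(self) -> int:
        return self.position + self.width // 2


@dataclass
class SyntheticGenome:
    name: str
    sequence: str
    planted_sites: list[PlantedSite] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise InputError("genome sequence must be non-empty")
        if set(self.sequence) - set("ACGT"):
            raise InputError("genome alphabet must be exactly {A,C,G,T}")
        for s in self.planted_sites:
            if s.position < 0 or s.position + s.width > len(self.sequence):
                raise InputError("planted site outside genome")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CoverageSimConfig:
    """Coverage simulation: mean depth, peak shape, noise model, replicates."""

    mean_depth: float = 50.0
    peak_shape_sd: float = 75.0
    enrichment: float = 20.0
    noise: str = "poisson"  # {'poisson', 'none', 'negbin'}
    seed: int = 0
    n_replicates: int = 1
    nb_dispersion: float | None = None  # negbin only: var = mu + mu^2/k

    def __post_init__(self) -> None:
        if self.mean_depth <= 0:
            raise InputError("mean_depth must be positive")
        if self.peak_shape_sd <= 0:
            raise InputError("peak_shape_sd must be positive")
        if self.enrichment < 0:
            raise InputError("enrichment must be non-negative")
        if self.noise not in ("poisson", "none", "negbin"):
            raise InputError("noise must be 'poisson', 'none' or 'negbin'")
        if self.noise == "negbin" and not (self.nb_dispersion and self.nb_dispersion > 0):
            raise InputError("negbin noise requires positive nb_dispersion")
        if self.n_replicates < 1:
            raise InputError("n_replicates must be >= 1")


@dataclass
class HDXSimConfig:
    """HDX simulation: per-residue exchange rates observed at five times.

    ``d2o_fraction`` defaults to 0.9 (ten-fold dilution into D2O buffer);
    no back-exchange correction is modelled.
    """

    protein_sequence: str = ""
    exchange_rates: np.ndarray | None = None  # 1/s, one per residue
    timepoints: tuple = (10.0, 30.0, 100.0, 1000.0, 10000.0)
    d2o_fraction: float = 0.9
    peptide_mean_len: int = 12
    peptide_overlap: int = 6
    noise_sd: float = 0.05  # Da
    n_replicates: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.protein_sequence) == 0:
            raise InputError("protein sequence must be non-empty")
        if not (0 < self.d2o_fraction <= 1):
            raise InputError("d2o_fraction must be in (0, 1]")
        if self.exchange_rates is not None:
            self.exchange_rates = np.asarray(self.exchange_rates, dtype=float)
            if self.exchange_rates.shape != (len(self.protein_sequence),):
                raise InputError("need one exchange rate per residue")
            if np.any(self.exchange_rates < 0):
                raise InputError("exchange rates must be >= 0")
        if self.peptide_mean_len < 2:
            raise InputError("peptide_mean_len must be >= 2")
        if not (0 <= self.peptide_overlap < self.peptide_mean_len):
            raise InputError("peptide_overlap must be in [0, peptide_mean_len)")


def gen_genome(length: int, gc: float = 0.5, seed: int = 0, name: str = "synthetic") -> SyntheticGenome:
    """I.i.d. random genome with P(G)+P(C) = ``gc``."""
    if length < 1:
        raise InputError("genome length must be >= 1")
    if not (0 <= gc <= 1):
        raise InputError("gc must be in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=p))
    return SyntheticGenome(name=name, sequence=seq)


def plant_sites(
    genome: SyntheticGenome,
    consensus: str,
    positions,
    mutation_rate: float = 0.0,
    seed: int = 0,
    enrichment: float | None = None,
) -> SyntheticGenome:
    """Overwrite the genome with (optionally mutated) consensus copies.

    Each planted copy is mutated independently per position at
    ``mutation_rate`` (substitution to a uniformly random different
    base).  Positions must be non-overlapping and in range.
    """
    consensus = consensus.upper()
    if set(consensus) - set("ACGT"):
        raise InputError("consensus must be over {A,C,G,T}")
    w = len(consensus)
    positions = sorted(int(p) for p in positions)
    for a, b in zip(positions, positions[1:]):
        if b < a + w:
            raise InputError("planted positions overlap")
    rng = np.random.default_rng(seed)
    seq = np.array(list(genome.sequence))
    sites = list(genome.planted_sites)
    for pos in positions:
        if pos < 0 or pos + w > genome.length:
            raise InputError(f"position {pos} out of range for width {w}")
        inst = np.array(list(consensus))
        mut = rng.random(w) < mutation_rate
        for i in np.flatnonzero(mut):
            choices = [b for b in "ACGT" if b != inst[i]]
            inst[i] = choices[rng.integers(3)]
        seq[pos : pos + w] = inst
        sites.append(
            PlantedSite(position=pos, motif_id=consensus, enrichment=enrichment, width=w)
        )
    return SyntheticGenome(name=genome.name, sequence="".join(seq), planted_sites=sites)


def expected_coverage(genome: SyntheticGenome, cfg: CoverageSimConfig) -> np.ndarray:
    """Noise-free expectation: depth x (1 + sum of Gaussian enrichments)."""
    mu = np.ones(genome.length)
    x = np.arange(genome.length, dtype=float)
    for site in genome.planted_sites:
        enr = site.enrichment if site.enrichment is not None else cfg.enrichment
        c = site.center
        sd = cfg.peak_shape_sd
        lo = max(0, int(c - 6 * sd))
        hi = min(genome.length, int(c + 6 * sd) + 1)
        mu[lo:hi] += enr * np.exp(-((x[lo:hi] - c) ** 2) / (2 * sd ** 2))
    return cfg.mean_depth * mu


def simulate_coverage(
    genome: SyntheticGenome, cfg: CoverageSimConfig
) -> list[CoverageTrack]:
    """One coverage track per replicate under the configured noise model."""
    mu = expected_coverage(genome, cfg)
    tracks = []
    for rep in range(1, cfg.n_replicates + 1):
        rng = np.random.default_rng(cfg.seed + rep - 1)
        if cfg.noise == "none":
            values = mu.copy()
        elif cfg.noise == "poisson":
            values = rng.poisson(mu).astype(float)
        else:  # negbin with var = mu + mu^2 / k
            k = cfg.nb_dispersion
            values = rng.negative_binomial(k, k / (k + mu)).astype(float)
        tracks.append(
            CoverageTrack(
                contig=genome.name, values=values, sample_id="sim", replicate=rep
            )
        )
    return tracks


def random_exchange_rates(
    n_residues: int, seed: int = 0, low: float = 1e-4, high: float = 1.0
) -> np.ndarray:
    """Log-uniform per-residue exchange rates (1/s), a simple stand-in for
    the orders-of-magnitude spread of amide protection in a folded protein."""
    rng = np.random.default_rng(seed)
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n_residues))


def residue_uptake_closed_form(
    rates: np.ndarray, t: float, d2o_fraction: float
) -> np.ndarray:
    """Per-residue uptake D(t) = d2o_fraction * (1 - exp(-k t))."""
    return d2o_fraction * (1.0 - np.exp(-np.asarray(rates, float) * t))


def _tile_peptides(n_res: int, mean_len: int, overlap: int, rng) -> list[tuple[int, int]]:
    """Tile [1, n_res] with overlapping peptides (1-based inclusive)."""
    spans = []
    start = 1
    while start <= n_res:
        length = int(np.clip(round(rng.normal(mean_len, 2)), 5, 30))
        end = min(start + length - 1, n_res)
        if n_res - end < 3:  # absorb a tiny tail into the last peptide
            end = n_res
        spans.append((start, end))
        if end == n_res:
            break
        start = end - overlap + 1
    return spans


def simulate_hdx(cfg: HDXSimConfig) -> pd.DataFrame:
    """Peptide-level HDX table from per-residue exchange kinetics.

    Two tilings of overlapping peptides are produced, one per protease
    (pepsin and the fungal-protease mix), offset against each other.
    Peptide uptake at each timepoint is the sum of the per-residue
    closed-form uptakes plus Gaussian noise; ancillary quality columns
    (intensity, products, mass error, RT drift, non-deuterated IDs) are
    drawn so the downstream filters are exercisable and pass by
    default.
    """
    n_res = len(cfg.protein_sequence)
    rates = (
        cfg.exchange_rates
        if cfg.exchange_rates is not None
        else random_exchange_rates(n_res, seed=cfg.seed)
    )
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for protease, offset in (("pepsin", 0), ("fungal", cfg.peptide_mean_len // 3)):
        spans = _tile_peptides(n_res - offset, cfg.peptide_mean_len, cfg.peptide_overlap, rng)
        spans = [(a + offset, b + offset) for a, b in spans]
        for idx, (start, end) in enumerate(spans):
            pid = f"{protease[:3]}_{idx:03d}"
            pep_seq = cfg.protein_sequence[start - 1 : end]
            intensity = float(rng.uniform(2e4, 5e5))
            n_products = int(rng.integers(2, 9))
            mass_error = float(rng.normal(0.0, 5.0))
            rt_delta = float(rng.normal(0.0, 0.1))
            for t in cfg.timepoints:
                clean = float(
                    residue_uptake_closed_form(
                        rates[start - 1 : end], t, cfg.d2o_fraction
                    ).sum()
                )
                for rep in range(1, cfg.n_replicates + 1):
                    noisy = clean + float(rng.normal(0.0, cfg.noise_sd)) if cfg.noise_sd > 0 else clean
                    rows.append(
                        (
                            pid,
                            pep_seq,
                            start,
                            end,
                            protease,
                            rep,
                            t,
                            max(noisy, 0.0),
                            intensity,
                            n_products,
                            mass_error,
                            rt_delta,
                            3,
                        )
                    )
    from .hdx import PEPTIDE_COLUMNS

    return pd.DataFrame(rows, columns=PEPTIDE_COLUMNS)


def simulate_itc(
    true_params: ITCModelParams,
    schedule: InjectionSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationExperiment:
    """Single-site titration heats plus Gaussian noise (ucal)."""
    schedule = schedule or InjectionSchedule()
    heats = isotherm_heats(true_params, schedule)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return TitrationExperiment(schedule=schedule, heats=heats, true_params=true_params)


def simulate_dsf(
    tm: float,
    slope: float = 2.0,
    low: float = 0.8,
    high: float = 1.0,
    t_range: tuple[float, float] = (20.0, 95.0),
    step: float = 0.5,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> MeltCurve:
    """Two-baseline Boltzmann melt curve on a regular temperature grid."""
    if slope == 0:
        raise InputError("slope must be nonzero")
    if t_range[1] <= t_range[0] or step <= 0:
        raise InputError("t_range must be increasing with positive step")
    t = np.arange(t_range[0], t_range[1] + step / 2, step)
    r = boltzmann(t, tm, slope, low, high)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + rng.normal(0.0, noise_sd, size=r.shape)
    return MeltCurve(temperature=t, ratio=r)
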