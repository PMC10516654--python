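"""Convolution-based peak calling for ChAP-seq/ChIP-seq coverage tracks.

The caller is a matched filter: per-base coverage is convolved with a
mean-subtracted Ricker kernel (the negative second derivative of a
Gaussian), which responds positively to bump-shaped enrichment and is
exactly blind to constant background.  The kernel width is chosen
adaptively from the data:

1. find all coverage peaks higher than ``threshold_mult`` times the
   genome-wide mean coverage;
2. for each, measure the distance between the flanking points where
   coverage drops below half the peak height;
3. take the median of those widths as the expected peak width.

Summits are positions where the first derivative of the convolution
response changes from positive to negative; each summit defines a peak
bounded by the nearest zero-crossings of the response.  Peaks are kept
when the raw summit coverage exceeds ``threshold_mult`` times the mean
and the convolution score is positive.  Replicate peak sets are merged
by summit proximity, and intensities are normalized by the per-sample
background coverage (total coverage minus coverage inside peaks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from sklearn.base import BaseEstimator

from .exceptions import DegenerateBackgroundError, InputError, NoCandidatePeakError

__all__ = [
    "CoverageTrack",
    "Kernel",
    "Peak",
    "PeakCallConfig",
    "estimate_expected_width",
    "build_kernel",
    "convolve_track",
    "call_peaks",
    "normalize_and_merge",
    "RickerPeakCaller",
]


@dataclass
class CoverageTrack:
    """Per-base read coverage of one contig for one sample/replicate."""

    contig: str
    values: np.ndarray
    sample_id: str = "sample"
    replicate: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InputError("coverage values must be a non-empty 1-D array")
        if np.any(self.values < 0):
            raise InputError("coverage values must be non-negative")

    @property
    def length(self) -> int:
        return int(self.values.size)


@dataclass
class Kernel:
    """Mean-subtracted Ricker kernel truncated at four sigmas."""

    sigma: float
    half_width: int
    weights: np.ndarray

    @property
    def support(self) -> int:
        return int(self.weights.size)


@dataclass
class Peak:
    """A called binding region (0-based half-open coordinates)."""

    contig: str
    start: int
    end: int
    summit: int
    raw_intensity: float
    conv_score: float
    normalized_intensity: float | None = None
    n_replicates: int = 1
    replicate: int | None = None

    def __post_init__(self) -> None:
        if not (self.start <= self.summit < self.end):
            raise InputError("peak must satisfy start <= summit < end")
        if self.raw_intensity <= 0:
            raise InputError("raw_intensity must be positive")


@dataclass
class PeakCallConfig:
    threshold_mult: float = 3.0
    fixed_width: int | None = None
    min_score: float | None = None

    def __post_init__(self) -> None:
        if self.threshold_mult <= 0:
            raise InputError("threshold_mult must be positive")


def estimate_expected_width(track: CoverageTrack, threshold_mult: float = 3.0) -> int:
    """Median half-height width of coverage peaks above the threshold.

    Candidate summits are (plateau-aware) local maxima of the raw
    coverage with value above ``threshold_mult`` times the genome-wide
    mean.  The width of each candidate is the number of positions
    between the nearest flanking points at which coverage drops below
    half the summit value.
    """
    cov = track.values
    thr = threshold_mult * cov.mean()
    summits, _ = signal.find_peaks(cov, height=thr)
    if summits.size == 0:
        raise NoCandidatePeakError(
            f"no coverage peak exceeds {threshold_mult} x mean coverage "
            f"({thr:.3g}); supply fixed_width to override"
        )
    widths = []
    n = cov.size
    for s in summits:
        half = cov[s] / 2.0
        below = cov < half
        left_idx = np.flatnonzero(below[:s])
        left = left_idx[-1] if left_idx.size else -1
        right_idx = np.flatnonzero(below[s + 1 :])
        right = s + 1 + right_idx[0] if right_idx.size else n
        widths.append(right - left - 1)
    return int(round(float(np.median(widths))))


def build_kernel(expected_width: float) -> Kernel:
    """Ricker kernel matched to ``expected_width`` (sigma = width / 2).

    The raw shape is w(x) = (1 - x^2/sigma^2) exp(-x^2 / 2 sigma^2),
    truncated at four sigmas and mean-subtracted over the truncated
    support so the weights sum exactly to zero.
    """
    if expected_width < 2:
        raise InputError("expected_width must be >= 2 bp")
    sigma = expected_width / 2.0
    half = int(math.ceil(4.0 * sigma))
    x = np.arange(-half, half + 1, dtype=float)
    w = (1.0 - (x / sigma) ** 2) * np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    w -= w.mean()
    return Kernel(sigma=sigma, half_width=half, weights=w)


def convolve_track(
    track: CoverageTrack, kernel: Kernel, circular: bool = False
) -> np.ndarray:
    """Per-base kernel response: response[x] = sum_d w[d] cov[x+d].

    Edges use reflect padding by default; ``circular=True`` wraps, for
    tracks representing a circular chromosome.
    """
    if kernel.support > track.length:
        raise InputError("kernel support exceeds track length")
    mode = "wrap" if circular else "reflect"
    return ndimage.correlate1d(track.values, kernel.weights, mode=mode)


def _find_summits(response: np.ndarray) -> np.ndarray:
    """Positions where the discrete first derivative flips + -> -.

    For a zero-derivative plateau the leftmost plateau position is
    reported, which makes the output deterministic.
    """
    d = np.diff(response)
    sign = np.sign(d)
    summits = []
    last_pos_idx = None  # index into d of the last strictly positive step
    for i, s in enumerate(sign):
        if s > 0:
            last_pos_idx = i
        elif s < 0:
            if last_pos_idx is not None:
                summits.append(last_pos_idx + 1)
            last_pos_idx = None
    return np.asarray(summits, dtype=int)


def call_peaks(
    track: CoverageTrack,
    kernel: Kernel,
    cfg: PeakCallConfig | None = None,
    circular: bool = False,
    response: np.ndarray | None = None,
) -> list[Peak]:
    """Detect peaks on the convolution response of one track.

    Summit = first-derivative sign change of the response; the peak
    interval spans the nearest non-positive response values flanking the
    summit.  Peaks are retained when raw coverage at the summit exceeds
    ``threshold_mult`` times the track mean and the convolution score is
    positive (and ``min_score`` if configured).
    """
    cfg = cfg or PeakCallConfig()
    if response is None:
        response = convolve_track(track, kernel, circular=circular)
    cov = track.values
    cov_thr = cfg.threshold_mult * cov.mean()
    n = cov.size

    nonpos = response <= 0
    peaks: list[Peak] = []
    for summit in _find_summits(response):
        score = response[summit]
        if score <= 0:
            continue
        if cov[summit] <= cov_thr:
            continue
        if cfg.min_score is not None and score <= cfg.min_score:
            continue
        left_idx = np.flatnonzero(nonpos[:summit])
        start = int(left_idx[-1]) + 1 if left_idx.size else 0
        right_idx = np.flatnonzero(nonpos[summit + 1 :])
        end = int(summit + 1 + right_idx[0]) if right_idx.size else n
        raw = float(cov[start:end].sum())
        if raw <= 0:
            continue
        peaks.append(
            Peak(
                contig=track.contig,
                start=start,
                end=end,
                summit=int(summit),
                raw_intensity=raw,
                conv_score=float(score),
                replicate=track.replicate,
            )
        )
    peaks.sort(key=lambda p: p.summit)
    return peaks


def _normalization_coefficient(track: CoverageTrack, peaks: list[Peak]) -> float:
    total = float(track.values.sum())
    in_peaks = float(sum(p.raw_intensity for p in peaks))
    coeff = total - in_peaks
    if coeff <= 0:
        raise DegenerateBackgroundError(
            "called peaks absorb all coverage; background coefficient <= 0"
        )
    return coeff


def normalize_and_merge(
    peak_sets: list[list[Peak]],
    tracks: list[CoverageTrack],
    overlap_tol: float,
    normalization: str = "ratio",
) -> list[Peak]:
    """Background-normalize per replicate, then merge peaks across replicates.

    The per-sample normalization coefficient is the track's background
    coverage, C = total coverage - sum of raw peak intensities.  Under
    the default ``ratio`` reading, normalized intensity is
    ``raw_intensity / C * 1e6`` (parts-per-million of background
    coverage, invariant to global track scaling); ``literal`` keeps the
    inverse reading ``C / raw_intensity``.

    Peaks whose summits lie within ``overlap_tol`` bp are clustered
    (single linkage on sorted summits); each cluster reports the number
    of distinct replicates supporting it and the mean normalized
    intensity.
    """
    if len(peak_sets) != len(tracks):
        raise InputError("need exactly one track per peak set")
    if normalization not in ("ratio", "literal"):
        raise InputError("normalization must be 'ratio' or 'literal'")

    flat: list[Peak] = []
    for peaks, track in zip(peak_sets, tracks):
        if not peaks:
            continue
        coeff = _normalization_coefficient(track, peaks)
        for p in peaks:
            if normalization == "ratio":
                norm = p.raw_intensity / coeff * 1e6
            else:
                norm = coeff / p.raw_intensity
            flat.append(
                Peak(
                    contig=p.contig,
                    start=p.start,
                    end=p.end,
                    summit=p.summit,
                    raw_intensity=p.raw_intensity,
                    conv_score=p.conv_score,
                    normalized_intensity=norm,
                    replicate=track.replicate,
                )
            )
    if not flat:
        return []

    flat.sort(key=lambda p: (p.contig, p.summit))
    clusters: list[list[Peak]] = [[flat[0]]]
    for p in flat[1:]:
        prev = clusters[-1][-1]
        if p.contig == prev.contig and p.summit - prev.summit <= overlap_tol:
            clusters[-1].append(p)
        else:
            clusters.append([p])

    merged: list[Peak] = []
    for cluster in clusters:
        reps = {p.replicate for p in cluster}
        best = max(cluster, key=lambda p: p.conv_score)
        merged.append(
            Peak(
                contig=best.contig,
                start=min(p.start for p in cluster),
                end=max(p.end for p in cluster),
                summit=int(round(np.mean([p.summit for p in cluster]))),
                raw_intensity=float(np.mean([p.raw_intensity for p in cluster])),
                conv_score=best.conv_score,
                normalized_intensity=float(
                    np.mean([p.normalized_intensity for p in cluster])
                ),
                n_replicates=len(reps),
            )
        )
    merged.sort(key=lambda p: (p.contig, p.summit))
    return merged


class RickerPeakCaller(BaseEstimator):
    """Adaptive Ricker-kernel peak caller, scikit-learn estimator style.

    ``fit`` estimates the expected peak width (median half-height width
    of above-threshold coverage peaks, pooled over the supplied tracks)
    and builds the matched kernel; ``predict`` calls peaks on one or
    more replicate tracks and, for multiple tracks, merges them with
    replicate support counts.

    Parameters
    ----------
    threshold_mult : float, default 3.0
        Detection threshold as a multiple of the genome-wide mean
        coverage, applied both during width estimation and as the final
        summit filter.
    fixed_width : int, optional
        Skip the adaptive estimate and use this expected width (bp).
    min_score : float, optional
        Additional lower bound on the convolution score.
    circular : bool, default False
        Wrap-around convolution for circular chromosomes.
    normalization : {'ratio', 'literal'}, default 'ratio'
        Direction of the background normalization (see
        :func:`normalize_and_merge`).
    overlap_tol : float, optional
        Summit distance for replicate merging; default is half the
        expected width.

    Attributes
    ----------
    expected_width_ : int
        Estimated (or fixed) expected peak width in bp.
    kernel_ : Kernel
        The mean-subtracted Ricker kernel in use.
    """

    def __init__(
        self,
        threshold_mult: float = 3.0,
        fixed_width: int | None = None,
        min_score: float | None = None,
        circular: bool = False,
        normalization: str = "ratio",
        overlap_tol: float | None = None,
    ) -> None:
        self.threshold_mult = threshold_mult
        self.fixed_width = fixed_width
        self.min_score = min_score
        self.circular = circular
        self.normalization = normalization
        self.overlap_tol = overlap_tol

    @staticmethod
    def _as_track_list(tracks) -> list[CoverageTrack]:
        if isinstance(tracks, CoverageTrack):
            return [tracks]
        tracks = list(tracks)
        if not tracks:
            raise InputError("at least one coverage track is required")
        return tracks

    def fit(self, tracks) -> "RickerPeakCaller":
        tracks = self._as_track_list(tracks)
        if self.fixed_width is not None:
            self.expected_width_ = int(self.fixed_width)
        else:
            widths = [
                estimate_expected_width(t, self.threshold_mult) for t in tracks
            ]
            self.expected_width_ = int(round(float(np.median(widths))))
        self.kernel_ = build_kernel(self.expected_width_)
        return self

    def transform(self, tracks) -> list[np.ndarray]:
        """Convolution response per track (for inspection/bedGraph export)."""
        return [
            convolve_track(t, self.kernel_, circular=self.circular)
            for t in self._as_track_list(tracks)
        ]

    def predict(self, tracks) -> list[Peak]:
        """Call peaks; with several tracks, merge replicates."""
        tracks = self._as_track_list(tracks)
        cfg = PeakCallConfig(
            threshold_mult=self.threshold_mult,
            fixed_width=self.fixed_width,
            min_score=self.min_score,
        )
        peak_sets = [
            call_peaks(t, self.kernel_, cfg, circular=self.circular) for t in tracks
        ]
        tol = (
            self.overlap_tol
            if self.overlap_tol is not None
            else self.expected_width_ / 2.0
        )
        return normalize_and_merge(
            peak_sets, tracks, overlap_tol=tol, normalization=self.normalization
        )
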