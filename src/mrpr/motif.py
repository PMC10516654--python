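"""PWM motif discovery (ZOOPS-EM) and genome scanning.

The discovery stage replaces a MEME-ChIP run: for every candidate motif
width it fits a "zero or one occurrence per sequence" (ZOOPS) finite
mixture by expectation-maximization, restarted from several seeded
initializations, and selects the width maximizing a length-penalized
log-likelihood-ratio score.  Both strands enter the E-step as mixture
components.  Scanning reports log-odds hits of the PWM against a
0-order background on both strands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator

from .exceptions import InputError

__all__ = [
    "PWM",
    "MotifHit",
    "extract_peak_sequences",
    "ZoopsMotifEM",
    "discover_motif",
    "scan_genome",
]

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as int8 indices; rejects other letters."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    if np.any(out < 0):
        raise InputError("sequence contains letters outside {A,C,G,T}")
    return out


def revcomp(seq: str) -> str:
    return seq.upper().translate(str.maketrans("ACGT", "TGCA"))[::-1]


@dataclass
class PWM:
    """Position weight matrix over (A, C, G, T) with a 0-order background."""

    probs: np.ndarray  # shape (4, width)
    background: np.ndarray  # shape (4,)
    pseudocount: float = 0.25
    n_sites: float = 0.0
    score: float = float("-inf")

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 1:
            raise InputError("probs must be a 4 x width matrix")
        if np.any(self.probs <= 0):
            raise InputError("PWM entries must be strictly positive (pseudocounted)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise InputError("PWM columns must sum to 1")

    @property
    def width(self) -> int:
        return int(self.probs.shape[1])

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def log_odds(self) -> np.ndarray:
        """Per-column log2(p / background) matrix (bits)."""
        return np.log2(self.probs / self.background[:, None])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=0).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
            n_sites=self.n_sites,
            score=self.score,
        )


@dataclass
class MotifHit:
    contig: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    log_odds: float  # bits


def _get_contig_sequences(genome) -> dict[str, str]:
    """Accept a dict, a pyfaidx.Fasta, or an iterable of SeqRecords."""
    if isinstance(genome, dict):
        return {k: str(v) for k, v in genome.items()}
    if hasattr(genome, "keys") and hasattr(genome, "__getitem__"):
        return {k: str(genome[k][:]) for k in genome.keys()}
    out = {}
    for rec in genome:
        out[getattr(rec, "id", getattr(rec, "name"))] = str(rec.seq)
    return out


def extract_peak_sequences(genome, peaks, flank: int = 50) -> list[str]:
    """Uppercase subsequences [summit-flank, summit+flank+1) per peak.

    Windows are clipped at contig ends; peak order is preserved.
    """
    contigs = _get_contig_sequences(genome)
    seqs = []
    for p in peaks:
        if p.contig not in contigs:
            raise InputError(f"peak contig {p.contig!r} missing from genome")
        seq = contigs[p.contig]
        lo = max(0, p.summit - flank)
        hi = min(len(seq), p.summit + flank + 1)
        seqs.append(seq[lo:hi].upper())
    return seqs


def _window_matrix(enc: np.ndarray, width: int) -> np.ndarray:
    return sliding_window_view(enc, width)


class ZoopsMotifEM(BaseEstimator):
    """ZOOPS-EM motif discovery with automatic width selection.

    For each width w in ``[min_width, max_width]`` the sequences are
    modelled as a mixture: with probability gamma a sequence carries one
    motif occurrence at a uniformly chosen position and strand, and with
    probability 1-gamma it is pure background.  EM alternates posterior
    site responsibilities with pseudocounted PWM and gamma updates; the
    optimized MAP objective (log-likelihood plus the Dirichlet
    pseudocount prior) is non-decreasing by construction and asserted
    every iteration.

    Width selection maximizes 2*(LL_w - LL_bg) - 3*w*ln(N), a BIC-style
    penalty treating each of the N sequences as one observation per PWM
    column; the winning PWM's edges are then trimmed of columns whose
    information content falls below ``trim_ic_frac`` times the median
    column IC, countering the tendency of per-sequence offset/strand
    selection to inflate weak flanking columns.

    Parameters
    ----------
    min_width, max_width : int
        Candidate motif widths (bp), inclusive.
    mode : {'zoops', 'oops'}
        ZOOPS allows motif-free sequences; OOPS forces one site each.
    restarts : int, default 10
        Seeded random EM initializations per width; the best final
        objective wins.
    pseudocount : float, default 0.25
        Dirichlet pseudocount per base per column.
    random_state : int, default 0
        Master seed for all restarts.

    Attributes
    ----------
    pwm_ : PWM
        Best motif across widths (its ``score`` is the selection score).
    width_ : int
        Selected width.
    objective_trace_ : list of float
        MAP objective per EM iteration of the winning run.
    loglik_ : float
        Observed-data log-likelihood of the winning run.
    scores_by_width_ : dict
        Selection score per candidate width.
    """

    def __init__(
        self,
        min_width: int = 8,
        max_width: int = 20,
        mode: str = "zoops",
        restarts: int = 10,
        pseudocount: float = 0.25,
        max_iter: int = 200,
        tol: float = 1e-7,
        trim_ic_frac: float = 0.5,
        random_state: int = 0,
    ) -> None:
        self.min_width = min_width
        self.max_width = max_width
        self.mode = mode
        self.restarts = restarts
        self.pseudocount = pseudocount
        self.max_iter = max_iter
        self.tol = tol
        self.trim_ic_frac = trim_ic_frac
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _init_probs(init_window: np.ndarray, width: int) -> np.ndarray:
        # enrich the seed window's letters
        probs = np.full((4, width), 0.1)
        probs[init_window, np.arange(width)] = 0.7
        return probs / probs.sum(axis=0, keepdims=True)

    def _em_run(self, windows, bg, width, probs, gamma0=0.5, max_iter=None):
        """One EM run at fixed width; returns (objective, pwm, gamma, trace, ll)."""
        pc = self.pseudocount
        oops = self.mode == "oops"
        log_bg = np.log(bg)
        if max_iter is None:
            max_iter = self.max_iter
        probs = probs.copy()
        gamma = 1.0 if oops else gamma0
        trace: list[float] = []
        prev_obj = -np.inf
        ll = -np.inf
        for _ in range(max_iter):
            log_ratio = np.log(probs) - log_bg[:, None]
            obj_ll = 0.0
            counts = np.full((4, width), pc)
            occ_sum = 0.0
            z_store = []
            for win_all, n_f, n_r in windows:
                # log likelihood-ratio of a site at each (position, strand)
                site_lr = log_ratio[win_all, np.arange(width)[None, :]].sum(axis=1)
                m = n_f + n_r
                if oops:
                    log_w = site_lr - np.log(m)
                    mx = log_w.max()
                    denom = np.exp(log_w - mx).sum()
                    obj_ll += mx + np.log(denom)
                    z = np.exp(log_w - mx) / denom
                    occ = 1.0
                else:
                    log_w = site_lr + np.log(gamma / m)
                    mx = max(log_w.max(), np.log1p(-gamma) if gamma < 1 else -np.inf)
                    terms = np.exp(log_w - mx)
                    denom = terms.sum() + np.exp(np.log1p(-gamma) - mx)
                    obj_ll += mx + np.log(denom)
                    z = terms / denom
                    occ = float(z.sum())
                occ_sum += occ
                z_store.append(z)
                np.add.at(counts, (win_all.ravel(), np.tile(np.arange(width), m)),
                          np.repeat(z, width))
            # obj_ll is sum log [ ... ] relative to background; add prior
            obj = obj_ll + pc * np.log(probs).sum()
            trace.append(obj)
            assert obj >= prev_obj - 1e-8, "EM objective decreased"
            if obj - prev_obj < self.tol * (1.0 + abs(obj)):
                prev_obj = obj
                ll = obj_ll
                break
            prev_obj = obj
            ll = obj_ll
            probs = counts / counts.sum(axis=0, keepdims=True)
            if not oops:
                gamma = float(np.clip(occ_sum / len(windows), 1e-6, 1 - 1e-6))
        return prev_obj, probs, gamma, trace, ll

    def fit(self, sequences) -> "ZoopsMotifEM":
        seqs = [s.upper() for s in sequences]
        if len(seqs) < 2:
            raise InputError("need at least 2 sequences")
        if min(len(s) for s in seqs) < self.max_width:
            raise InputError(
                "every sequence must be at least max_width long"
            )
        enc_f = [encode(s) for s in seqs]
        enc_r = [_COMPLEMENT[e][::-1] for e in enc_f]
        counts = np.bincount(np.concatenate(enc_f), minlength=4).astype(float)
        bg = (counts + 1.0) / (counts.sum() + 4.0)
        # strand-symmetric background so '+'/'-' sites score comparably
        bg = (bg + bg[::-1]) / 2.0

        rng = np.random.default_rng(self.random_state)
        n_seqs = len(seqs)
        best = None  # (sel_score, -width, probs, gamma, trace, ll)
        self.scores_by_width_ = {}
        n_pilot = max(10 * self.restarts, 50)
        for width in range(self.min_width, self.max_width + 1):
            windows = []
            for ef, er in zip(enc_f, enc_r):
                f = _window_matrix(ef, width)
                r = _window_matrix(er, width)
                windows.append(
                    (np.concatenate([f, r], axis=0), f.shape[0], r.shape[0])
                )
            # starting-point search: short pilot runs from many candidate
            # windows, full EM only from the most promising ones
            pilots = []
            for _ in range(n_pilot):
                si = rng.integers(n_seqs)
                pool = windows[si][0]
                init = self._init_probs(pool[rng.integers(pool.shape[0])], width)
                obj0, probs0, gamma0, _, _ = self._em_run(
                    windows, bg, width, init, max_iter=2
                )
                pilots.append((obj0, probs0, gamma0))
            pilots.sort(key=lambda p: p[0], reverse=True)
            best_run = None
            for _, probs0, gamma0 in pilots[: self.restarts]:
                run = self._em_run(windows, bg, width, probs0, gamma0)
                if best_run is None or run[0] > best_run[0]:
                    best_run = run
            obj, probs, gamma, trace, ll = best_run
            # ll is already LL - LL_background (background factor cancels)
            sel = 2.0 * ll - 3.0 * width * np.log(n_seqs)
            self.scores_by_width_[width] = float(sel)
            key = (sel, -width)
            if best is None or key > best[0]:
                best = (key, width, probs, gamma, trace, ll)

        _, width, probs, gamma, trace, ll = best
        self.untrimmed_width_ = width
        # EM alignment freedom lets weakly informative flanking columns
        # creep in; trim edge columns whose information content falls
        # below trim_ic_frac times the median column IC (MEME-style).
        if self.trim_ic_frac > 0:
            ic = (probs * np.log2(probs / bg[:, None])).sum(axis=0)
            thr = self.trim_ic_frac * float(np.median(ic))
            lo, hi = 0, width
            while hi - lo > self.min_width and ic[lo] < thr:
                lo += 1
            while hi - lo > self.min_width and ic[hi - 1] < thr:
                hi -= 1
            probs = probs[:, lo:hi]
            width = hi - lo
        self.width_ = width
        self.gamma_ = gamma
        self.objective_trace_ = trace
        self.loglik_ = float(ll)
        self.pwm_ = PWM(
            probs=probs,
            background=bg,
            pseudocount=self.pseudocount,
            n_sites=float(gamma * n_seqs),
            score=self.scores_by_width_[self.untrimmed_width_],
        )
        return self

    def scan(self, genome, threshold: float) -> list[MotifHit]:
        return scan_genome(genome, self.pwm_, threshold)


def discover_motif(
    seqs,
    width_range: tuple[int, int] = (8, 20),
    mode: str = "zoops",
    restarts: int = 10,
    seed: int = 0,
) -> PWM:
    """Discover a PWM by ZOOPS-EM with automatic width selection."""
    est = ZoopsMotifEM(
        min_width=width_range[0],
        max_width=width_range[1],
        mode=mode,
        restarts=restarts,
        random_state=seed,
    ).fit(seqs)
    return est.pwm_


def scan_genome(genome, pwm: PWM, threshold: float) -> list[MotifHit]:
    """Log-odds scan of every position on both strands.

    Returns hits with score >= threshold (bits), sorted by position.
    Palindromic sites may yield one hit per strand at the same start.
    """
    if not np.isfinite(threshold):
        raise InputError("threshold must be finite")
    if isinstance(genome, str):
        genome = {"seq": genome}
    contigs = _get_contig_sequences(genome)
    lo = pwm.log_odds()
    w = pwm.width
    hits: list[MotifHit] = []
    for name, seq in contigs.items():
        if len(seq) < w:
            continue
        enc = encode(seq)
        wins = _window_matrix(enc, w)
        cols = np.arange(w)[None, :]
        fwd_scores = lo[wins, cols].sum(axis=1)
        enc_rc = _COMPLEMENT[enc][::-1]
        wins_rc = _window_matrix(enc_rc, w)
        rev_scores = lo[wins_rc, cols].sum(axis=1)
        n = enc.size
        for j in np.flatnonzero(fwd_scores >= threshold):
            hits.append(MotifHit(name, int(j), "+", float(fwd_scores[j])))
        for j in np.flatnonzero(rev_scores >= threshold):
            hits.append(MotifHit(name, int(n - w - j), "-", float(rev_scores[j])))
    hits.sort(key=lambda h: (h.contig, h.start, h.strand))
    return hits
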