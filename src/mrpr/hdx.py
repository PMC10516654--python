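"""HDX-MS data reduction: peptide filtering, residue-level assignment,
and differential uptake profiles.

Peptide-level deuterium uptake tables (one row per peptide, timepoint
and replicate, pooled over the two protease digestions) are reduced in
three steps:

1. quality filtering on identification reproducibility, intensity,
   peptide length, fragment products, mass error and retention-time
   drift, followed by replicate averaging;
2. residue-level assignment: a residue covered by a single peptide
   inherits that peptide's uptake; with overlapping coverage the
   shortest covering peptide wins, ties resolved by proximity of the
   residue to the peptide C-terminus, then by peptide id;
3. differential profiles between two states, classifying residues as
   increased / decreased / unchanged against a threshold.

Residue coordinates are 1-based inclusive throughout (proteomics
convention).  No proline or N-terminal exclusion and no back-exchange
correction is applied: the residue value is literally that of the
chosen peptide.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InputError

__all__ = [
    "PEPTIDE_COLUMNS",
    "FilterCriteria",
    "PeptideFilter",
    "filter_and_merge",
    "residue_uptake",
    "differential_uptake",
]

#: canonical columns of a peptide-level measurement table
PEPTIDE_COLUMNS = [
    "peptide_id",
    "sequence",
    "start",
    "end",
    "protease",
    "replicate",
    "timepoint",
    "uptake",
    "intensity",
    "n_products",
    "mass_error",
    "rt_delta",
    "n_nondeut_ids",
]


@dataclass
class FilterCriteria:
    """Peptide quality thresholds.

    Defaults: identification in >=2 of 3 non-deuterated runs, minimum
    intensity 10,000 counts, maximum length 30 residues, at least 2
    fragment products, mass error <= 25 ppm, retention-time drift
    <= 0.5 min.
    """

    min_nondeut_ids: int = 2
    min_intensity: float = 10_000.0
    max_length: int = 30
    min_products: int = 2
    max_mass_error: float = 25.0
    max_rt_delta: float = 0.5

    def __post_init__(self) -> None:
        for name in (
            "min_nondeut_ids",
            "min_intensity",
            "max_length",
            "min_products",
            "max_mass_error",
            "max_rt_delta",
        ):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")


def _passes(table: pd.DataFrame, c: FilterCriteria) -> pd.Series:
    length = table["end"] - table["start"] + 1
    ok = (
        (table["n_nondeut_ids"] >= c.min_nondeut_ids)
        & (table["intensity"] >= c.min_intensity)
        & (length <= c.max_length)
        & (table["n_products"] >= c.min_products)
        & (table["mass_error"].abs() <= c.max_mass_error)
        & (table["rt_delta"].abs() <= c.max_rt_delta)
    )
    return ok


def filter_and_merge(
    tables, criteria: FilterCriteria | None = None
) -> pd.DataFrame:
    """Filter peptide tables and average replicate uptake.

    ``tables`` may be a single DataFrame or an iterable of per-protease
    DataFrames sharing the residue coordinate system.  Rows failing any
    criterion are dropped; survivors from all proteases are
    concatenated and uptake is averaged over replicates per
    (peptide_id, timepoint), retaining the replicate standard deviation
    as ``uptake_sd`` and the replicate count as ``n_replicates``.
    """
    criteria = criteria or FilterCriteria()
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    combined = pd.concat(list(tables), ignore_index=True)
    if "replicate" not in combined.columns:
        # already replicate-averaged: filtering alone, which is idempotent
        return combined[_passes(combined, criteria)].reset_index(drop=True)
    kept = combined[_passes(combined, criteria)].copy()
    if kept.empty:
        warnings.warn("no peptides survived quality filtering", stacklevel=2)
        cols = list(combined.columns) + ["uptake_sd", "n_replicates"]
        return pd.DataFrame(columns=[c for c in cols if c != "replicate"])

    meta_cols = [
        c
        for c in kept.columns
        if c not in ("peptide_id", "timepoint", "uptake", "replicate",
                     "uptake_sd", "n_replicates")
    ]
    agg = {c: "first" for c in meta_cols}
    grouped = (
        kept.groupby(["peptide_id", "timepoint"], sort=True)
        .agg(
            uptake=("uptake", "mean"),
            uptake_sd=("uptake", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
            n_replicates=("uptake", "size"),
            **{c: (c, f) for c, f in agg.items()},
        )
        .reset_index()
    )
    # keep prior replicate counts when re-filtering an already merged table
    if "n_replicates_x" in grouped.columns:  # pragma: no cover - defensive
        grouped = grouped.drop(columns=["n_replicates_x"])
    order = ["peptide_id", "timepoint", "uptake", "uptake_sd", "n_replicates"] + meta_cols
    return grouped[order]


class PeptideFilter(BaseEstimator, TransformerMixin):
    """Transformer wrapper around :func:`filter_and_merge`."""

    def __init__(self, criteria: FilterCriteria | None = None) -> None:
        self.criteria = criteria

    def fit(self, X, y=None) -> "PeptideFilter":
        self.criteria_ = self.criteria or FilterCriteria()
        return self

    def transform(self, X) -> pd.DataFrame:
        if not hasattr(self, "criteria_"):
            self.fit(X)
        return filter_and_merge(X, self.criteria_)


def residue_uptake(table: pd.DataFrame, timepoint: float) -> pd.DataFrame:
    """Residue-specific uptake at one labeling time.

    For every residue covered by at least one peptide the assigned
    uptake is that of the single covering peptide, or — with
    overlapping coverage — of the shortest covering peptide; among
    equally short peptides the one whose C-terminus is closest to the
    residue wins, and remaining ties go to the lexicographically
    smallest peptide id.  Uncovered residues are absent from the
    output.
    """
    if timepoint not in set(table["timepoint"]):
        raise InputError(f"timepoint {timepoint!r} not present in table")
    sub = table[table["timepoint"] == timepoint]
    records = []
    has_sd = "uptake_sd" in sub.columns
    for row in sub.itertuples(index=False):
        length = row.end - row.start + 1
        for res in range(int(row.start), int(row.end) + 1):
            records.append(
                (
                    res,
                    length,
                    row.end - res,
                    str(row.peptide_id),
                    row.uptake,
                    getattr(row, "uptake_sd", 0.0) if has_sd else 0.0,
                )
            )
    if not records:
        return pd.DataFrame(
            columns=["residue", "timepoint", "uptake", "uptake_sd", "source_peptide_id"]
        )
    cand = pd.DataFrame(
        records,
        columns=["residue", "length", "cterm_dist", "peptide_id", "uptake", "uptake_sd"],
    )
    cand = cand.sort_values(
        ["residue", "length", "cterm_dist", "peptide_id"], kind="mergesort"
    )
    chosen = cand.groupby("residue", sort=True).first().reset_index()
    out = pd.DataFrame(
        {
            "residue": chosen["residue"].astype(int),
            "timepoint": timepoint,
            "uptake": chosen["uptake"],
            "uptake_sd": chosen["uptake_sd"],
            "source_peptide_id": chosen["peptide_id"],
        }
    )
    return out.reset_index(drop=True)


def residue_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Residue-level profile across every timepoint present in the table."""
    parts = [residue_uptake(table, t) for t in sorted(set(table["timepoint"]))]
    return pd.concat(parts, ignore_index=True)


def differential_uptake(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    threshold: float | None = None,
) -> pd.DataFrame:
    """Per-residue, per-timepoint uptake difference (state B minus A).

    Only residues/timepoints present in both profiles are reported.
    Each residue is classified ``increased`` / ``decreased`` when
    |delta| exceeds the threshold at any timepoint (the sign of the
    largest-magnitude excursion decides the direction), otherwise
    ``unchanged``.  When ``threshold`` is None it defaults to twice the
    pooled replicate standard deviation, which requires ``uptake_sd``
    columns in both profiles.
    """
    merged = profile_a.merge(
        profile_b, on=["residue", "timepoint"], suffixes=("_a", "_b")
    )
    if merged.empty:
        warnings.warn("profiles share no residue/timepoint", stacklevel=2)
        return pd.DataFrame(columns=["residue", "timepoint", "delta", "classification"])
    if threshold is None:
        if "uptake_sd_a" not in merged.columns or "uptake_sd_b" not in merged.columns:
            raise InputError(
                "threshold=None requires uptake_sd in both profiles"
            )
        pooled = np.sqrt(
            np.mean(
                np.concatenate(
                    [merged["uptake_sd_a"] ** 2, merged["uptake_sd_b"] ** 2]
                )
            )
        )
        threshold = 2.0 * float(pooled)
    merged["delta"] = merged["uptake_b"] - merged["uptake_a"]

    def classify(group: pd.DataFrame) -> str:
        i = group["delta"].abs().idxmax()
        top = group.loc[i, "delta"]
        if abs(top) > threshold:
            return "increased" if top > 0 else "decreased"
        return "unchanged"

    cls = {
        res: classify(g) for res, g in merged.groupby("residue", sort=True)
    }
    out = merged[["residue", "timepoint", "delta"]].copy()
    out["classification"] = out["residue"].map(cls)
    out.attrs["threshold"] = threshold
    return out.sort_values(["residue", "timepoint"]).reset_index(drop=True)
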