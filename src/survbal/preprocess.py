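"""Input tables, taxon filtering, zero replacement and closure.

The pipeline starts from a raw count table (samples x taxa) and a metadata
table carrying a positive time column and a 0/1 event indicator.  Taxa are
filtered on mean relative abundance, zeros are replaced by an additive
pseudocount, and rows are closed to a strictly positive composition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "Composition",
    "SurvivalOutcome",
    "read_tables",
    "filter_taxa",
    "close_composition",
]


@dataclass(frozen=True)
class CountTable:
    """Raw nonnegative integer abundances, samples in rows, taxa in columns."""

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    counts: np.ndarray  # (n_samples, n_taxa), nonnegative integers

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValidationError("counts must be a 2-D matrix (samples x taxa)")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if np.any(counts < 0):
            raise ValidationError("counts must be nonnegative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise ValidationError("duplicate taxon identifiers")
        object.__setattr__(self, "counts", counts)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass(frozen=True)
class Composition:
    """Strictly positive relative abundances; every row sums to 1."""

    sample_ids: tuple[str, ...]
    taxon_ids: tuple[str, ...]
    X: np.ndarray  # (n_samples, n_taxa), positive, rows sum to 1

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2 or X.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError("composition matrix shape mismatch")
        if np.any(X <= 0):
            raise ValidationError("composition entries must be strictly positive")
        if not np.allclose(X.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValidationError("composition rows must sum to 1 within 1e-12")
        object.__setattr__(self, "X", X)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)


@dataclass(frozen=True)
class SurvivalOutcome:
    """Per-sample follow-up time, event indicator and optional covariates.

    ``event`` is 1 for an observed event and 0 for right censoring.  The row
    order is aligned with the count table it was read alongside.
    """

    time: np.ndarray
    event: np.ndarray
    covariates: np.ndarray | None = None  # (n_samples, p)
    covariate_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        time = np.asarray(self.time, dtype=float)
        event = np.asarray(self.event)
        if time.ndim != 1 or event.shape != time.shape:
            raise ValidationError("time and event must be aligned 1-D vectors")
        if np.any(~np.isfinite(time)) or np.any(time <= 0):
            raise ValidationError("survival times must be positive and finite")
        if not np.all(np.isin(event, (0, 1))):
            raise ValidationError("event indicator must contain only 0 and 1")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(int))
        if self.covariates is not None:
            Z = np.asarray(self.covariates, dtype=float)
            if Z.ndim == 1:
                Z = Z[:, None]
            if Z.shape[0] != time.shape[0]:
                raise ValidationError("covariate rows must match number of samples")
            if np.any(~np.isfinite(Z)):
                raise ValidationError("covariates must be finite")
            object.__setattr__(self, "covariates", Z)
            if not self.covariate_names:
                object.__setattr__(
                    self,
                    "covariate_names",
                    tuple(f"z{j}" for j in range(Z.shape[1])),
                )

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx: np.ndarray) -> "SurvivalOutcome":
        Z = None if self.covariates is None else self.covariates[idx]
        return SurvivalOutcome(self.time[idx], self.event[idx], Z, self.covariate_names)


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    frame.index = frame.index.astype(str)
    return frame


def read_tables(
    counts_path: str | Path,
    metadata_path: str | Path,
    time_col: str,
    event_col: str,
    covariate_cols: Sequence[str] = (),
) -> tuple[CountTable, SurvivalOutcome]:
    """Read a count table and a metadata table and align them by sample id.

    Both files are TSV (or CSV by extension) with the sample identifier in
    the first column.  Samples missing from either table are dropped with a
    logged count; zero overlap is fatal.
    """
    counts_df = _read_frame(counts_path)
    meta_df = _read_frame(metadata_path)

    for col in (time_col, event_col, *covariate_cols):
        if col not in meta_df.columns:
            raise ValidationError(f"metadata is missing required column {col!r}")

    shared = [s for s in counts_df.index if s in set(meta_df.index)]
    dropped = (len(counts_df) - len(shared)) + (len(meta_df) - len(shared))
    if not shared:
        raise ValidationError("no overlapping samples between counts and metadata")
    if len(shared) < 3:
        raise ValidationError("fewer than 3 overlapping samples")
    if counts_df.shape[1] < 2:
        raise ValidationError("count table must have at least 2 taxa")
    if dropped:
        logger.info("dropped %d samples absent from one of the tables", dropped)

    counts_df = counts_df.loc[shared]
    meta_df = meta_df.loc[shared]

    counts = counts_df.to_numpy()
    if not np.issubdtype(counts.dtype, np.number):
        raise ValidationError("count table contains non-numeric entries")

    time = pd.to_numeric(meta_df[time_col], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(meta_df[event_col], errors="coerce").to_numpy(dtype=float)
    if np.any(np.isnan(time)) or np.any(np.isnan(event)):
        raise ValidationError("time/event columns must be numeric and complete")

    Z = None
    if covariate_cols:
        Z = meta_df[list(covariate_cols)].apply(pd.to_numeric, errors="coerce").to_numpy()
        if np.any(np.isnan(Z)):
            raise ValidationError("covariate columns must be numeric and complete")

    table = CountTable(tuple(shared), tuple(counts_df.columns), np.asarray(counts))
    outcome = SurvivalOutcome(time, event, Z, tuple(covariate_cols))
    return table, outcome


def mean_relative_abundance(tab: CountTable) -> np.ndarray:
    """Per-taxon mean (over samples) of count / sample total, before zero
    replacement.  Samples with an all-zero row contribute zeros."""
    totals = tab.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(totals > 0, tab.counts / totals, 0.0)
    return rel.mean(axis=0)


def filter_taxa(
    tab: CountTable,
    mode: Literal["remove_rare", "keep_common"],
    threshold: float,
) -> CountTable:
    """Filter taxa on mean relative abundance.

    ``remove_rare`` drops taxa strictly below ``threshold``; ``keep_common``
    keeps taxa strictly above it.  Surviving taxa preserve input order and at
    least two must remain.
    """
    if not 0 <= threshold < 1:
        raise ValidationError("threshold must lie in [0, 1)")
    mra = mean_relative_abundance(tab)
    if mode == "remove_rare":
        keep = mra >= threshold
    elif mode == "keep_common":
        keep = mra > threshold
    else:
        raise ValidationError(f"unknown filter mode {mode!r}")
    if keep.sum() < 2:
        raise ValidationError(
            f"fewer than 2 taxa survive {mode} filtering at threshold {threshold}"
        )
    idx = np.flatnonzero(keep)
    logger.info("taxon filter %s@%g: kept %d of %d", mode, threshold, len(idx), tab.n_taxa)
    return CountTable(
        tab.sample_ids,
        tuple(tab.taxon_ids[i] for i in idx),
        tab.counts[:, idx],
    )


def close_composition(tab: CountTable, pseudocount: float = 0.5) -> Composition:
    """Add a pseudocount to every count and close each row to sum 1."""
    if not pseudocount > 0:
        raise ValidationError("pseudocount must be strictly positive")
    shifted = tab.counts.astype(float) + pseudocount
    X = shifted / shifted.sum(axis=1, keepdims=True)
    return Composition(tab.sample_ids, tab.taxon_ids, X)


def close_raw(tab: CountTable) -> np.ndarray:
    """Relative abundances WITHOUT pseudocount (zeros preserved), used by
    abundance-based ecological distances.  Rows with zero total become zeros."""
    totals = tab.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(totals > 0, tab.counts / totals, 0.0)
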