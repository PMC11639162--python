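"""Normalized log-ratio balances of two disjoint taxon sets.

For a composition row ``x`` and disjoint index sets ``plus`` (size k+) and
``minus`` (size k-), the balance is

    sqrt(k+ k- / (k+ + k-)) * log( gmean(x[plus]) / gmean(x[minus]) )

with natural logarithms, computed in log space.  It is a scale-invariant
log-contrast, so it is well defined on relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ValidationError
from .preprocess import Composition

__all__ = ["BalanceSpec", "compute_balance", "swap_sign"]


@dataclass(frozen=True)
class BalanceSpec:
    """Two disjoint ordered sets of taxon indices defining a balance."""

    plus: tuple[int, ...]
    minus: tuple[int, ...]

    def __post_init__(self) -> None:
        plus = tuple(int(i) for i in self.plus)
        minus = tuple(int(i) for i in self.minus)
        if len(plus) < 1 or len(minus) < 1:
            raise ValidationError("both sides of a balance need at least one taxon")
        if len(set(plus)) != len(plus) or len(set(minus)) != len(minus):
            raise ValidationError("duplicate taxon index within a balance side")
        if set(plus) & set(minus):
            raise ValidationError("plus and minus sets must be disjoint")
        object.__setattr__(self, "plus", plus)
        object.__setattr__(self, "minus", minus)

    @property
    def k_plus(self) -> int:
        return len(self.plus)

    @property
    def k_minus(self) -> int:
        return len(self.minus)

    @property
    def size(self) -> int:
        return self.k_plus + self.k_minus

    def taxa(self) -> frozenset[int]:
        return frozenset(self.plus) | frozenset(self.minus)

    def canonical(self) -> "BalanceSpec":
        """Side-order-insensitive representative (sorted indices)."""
        return BalanceSpec(tuple(sorted(self.plus)), tuple(sorted(self.minus)))

    def validate_against(self, n_taxa: int) -> None:
        if any(i < 0 or i >= n_taxa for i in self.plus + self.minus):
            raise ValidationError(f"balance indices out of range for {n_taxa} taxa")


def _as_matrix(X: Composition | np.ndarray) -> np.ndarray:
    M = X.X if isinstance(X, Composition) else np.asarray(X, dtype=float)
    if np.any(M <= 0):
        raise ValidationError("balance requires strictly positive abundances")
    return M


def compute_balance(X: Composition | np.ndarray, spec: BalanceSpec) -> np.ndarray:
    """Per-sample balance values for ``spec``.

    Accepts a :class:`Composition` or a strictly positive matrix (any row
    scale; the balance is scale invariant).
    """
    M = _as_matrix(X)
    spec.validate_against(M.shape[1])
    logM = np.log(M)
    kp, km = spec.k_plus, spec.k_minus
    coef = np.sqrt(kp * km / (kp + km))
    mean_plus = logM[:, spec.plus].mean(axis=1)
    mean_minus = logM[:, spec.minus].mean(axis=1)
    return coef * (mean_plus - mean_minus)


def swap_sign(spec: BalanceSpec) -> BalanceSpec:
    """Exchange the plus and minus sides; negates the balance exactly."""
    return BalanceSpec(spec.minus, spec.plus)


def spec_with_names(spec: BalanceSpec, taxon_ids: Iterable[str]) -> dict:
    """JSON-friendly view of a balance with taxon names resolved."""
    ids = list(taxon_ids)
    return {
        "plus": [ids[i] for i in spec.plus],
        "minus": [ids[i] for i in spec.minus],
        "plus_indices": list(spec.plus),
        "minus_indices": list(spec.minus),
        "k_plus": spec.k_plus,
        "k_minus": spec.k_minus,
    }
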