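"""Dirichlet-multinomial compositions and balance-driven survival outcomes.

Every test scenario in the package is generated here: a latent composition
per sample, multinomial sequencing counts, and censored event times whose
hazard (Cox mode) or log time (Weibull/AFT mode) depends on the balance of a
planted pair of taxon sets.  The true balance is computed on the latent,
zero-free composition, so the generative truth is exact while the analysis
pipeline only ever sees counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .balance import BalanceSpec, compute_balance
from .errors import ValidationError
from .preprocess import Composition, CountTable, SurvivalOutcome
from .selection import SelectionResult

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "simulate_composition",
    "simulate_survival",
    "simulate_dataset",
    "evaluate_selection",
]


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 100
    n_taxa: int = 10
    planted_plus: tuple[int, ...] = (0,)
    planted_minus: tuple[int, ...] = (1,)
    gamma_true: float = 1.0
    model: str = "cox"  # "cox" | "weibull"
    baseline_shape: float = 1.5
    baseline_scale: float = 1.0
    censoring_rate: float = 0.2
    sequencing_depth: int = 10_000
    dirichlet_alpha: float | tuple[float, ...] = 1.0
    aft_intercept: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 3 or self.n_taxa < 2:
            raise ValidationError("need at least 3 samples and 2 taxa")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must lie in [0, 1)")
        if set(self.planted_plus) & set(self.planted_minus):
            raise ValidationError("planted sets must be disjoint")
        if self.model not in ("cox", "weibull"):
            raise ValidationError("model must be 'cox' or 'weibull'")
        if self.baseline_shape <= 0 or self.baseline_scale <= 0:
            raise ValidationError("baseline shape/scale must be positive")

    @property
    def truth(self) -> BalanceSpec:
        return BalanceSpec(tuple(self.planted_plus), tuple(self.planted_minus))

    def alpha_vector(self) -> np.ndarray:
        a = np.asarray(self.dirichlet_alpha, dtype=float)
        if a.ndim == 0:
            a = np.full(self.n_taxa, float(a))
        if a.shape != (self.n_taxa,) or np.any(a <= 0):
            raise ValidationError("dirichlet_alpha must be positive, scalar or length n_taxa")
        return a


@dataclass(frozen=True)
class SimulatedDataset:
    counts: CountTable
    outcome: SurvivalOutcome
    truth: BalanceSpec
    true_balance: np.ndarray
    latent: Composition


def simulate_composition(cfg: SimulationConfig) -> tuple[Composition, CountTable]:
    """Latent Dirichlet compositions and multinomial counts at fixed depth."""
    rng = np.random.default_rng(cfg.seed)
    alpha = cfg.alpha_vector()
    X = rng.dirichlet(alpha, size=cfg.n_samples)
    # keep the latent composition strictly positive for exact log-ratios
    X = np.clip(X, 1e-12, None)
    X = X / X.sum(axis=1, keepdims=True)
    counts = rng.multinomial(cfg.sequencing_depth, X)
    sample_ids = tuple(f"s{i:04d}" for i in range(cfg.n_samples))
    taxon_ids = tuple(f"taxon_{j:03d}" for j in range(cfg.n_taxa))
    return (
        Composition(sample_ids, taxon_ids, X),
        CountTable(sample_ids, taxon_ids, counts),
    )


def _censoring_bound(T: np.ndarray, rate: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target expected
    rate: E[fraction censored] = mean_i P(C_i < T_i) = mean_i min(T_i/c, 1)."""
    def expected(c: float) -> float:
        return float(np.mean(np.minimum(T / c, 1.0)))
    lo, hi = T.min() * 1e-6, T.max() * 1e6
    if expected(hi) > rate:  # cannot censor this rarely within bracket
        return hi
    return float(optimize.brentq(lambda c: expected(c) - rate, lo, hi, xtol=1e-12))


def simulate_survival(
    composition: Composition | np.ndarray,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> SurvivalOutcome:
    """Event times driven by the planted balance, with uniform censoring.

    Cox mode: inverse-transform sampling from a Weibull baseline cumulative
    hazard (t/scale)^shape multiplied by exp(gamma * B).  Weibull mode:
    log T = intercept + gamma * B + (1/shape) * G with G standard minimum
    extreme-value noise, so T is Weibull.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    B = compute_balance(composition, cfg.truth)
    n = B.shape[0]
    if cfg.model == "cox":
        E = rng.exponential(size=n)
        T = cfg.baseline_scale * (E / np.exp(cfg.gamma_true * B)) ** (1.0 / cfg.baseline_shape)
    else:
        G = np.log(rng.exponential(size=n))  # standard Gumbel-min
        logT = cfg.aft_intercept + cfg.gamma_true * B + G / cfg.baseline_shape
        T = np.exp(logT)
    if cfg.censoring_rate == 0:
        return SurvivalOutcome(T, np.ones(n, dtype=int))
    c = _censoring_bound(T, cfg.censoring_rate)
    C = rng.uniform(0.0, c, size=n)
    time = np.minimum(T, C)
    event = (T <= C).astype(int)
    if event.sum() == 0:  # degenerate draw; keep the largest time as an event
        event[np.argmax(T)] = 1
        time[np.argmax(T)] = T[np.argmax(T)]
    return SurvivalOutcome(time, event)


def simulate_dataset(cfg: SimulationConfig) -> SimulatedDataset:
    """Composition + counts + outcome + exact truth, reproducible from cfg."""
    latent, counts = simulate_composition(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    outcome = simulate_survival(latent, cfg, rng)
    return SimulatedDataset(
        counts=counts,
        outcome=outcome,
        truth=cfg.truth,
        true_balance=compute_balance(latent, cfg.truth),
        latent=latent,
    )


def evaluate_selection(
    result: SelectionResult | BalanceSpec,
    truth: BalanceSpec,
) -> tuple[float, float]:
    """Selection precision and recall against the planted balance.

    Matching is orientation agnostic: the selected sides are paired with the
    planted sides in whichever of the two orientations maximizes the total
    overlap.  Precision = overlap / #selected, recall = overlap / #planted.
    """
    spec = result.best_spec if isinstance(result, SelectionResult) else result
    sel_p, sel_m = set(spec.plus), set(spec.minus)
    tru_p, tru_m = set(truth.plus), set(truth.minus)
    n_selected = len(sel_p) + len(sel_m)
    n_planted = len(tru_p) + len(tru_m)
    if n_selected == 0:
        return 0.0, 0.0
    same = len(sel_p & tru_p) + len(sel_m & tru_m)
    flipped = len(sel_p & tru_m) + len(sel_m & tru_p)
    overlap = max(same, flipped)
    return overlap / n_selected, overlap / n_planted
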