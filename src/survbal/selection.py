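"""Greedy step-wise search for the balance most associated with survival.

The search initializes with the best single-taxon-vs-single-taxon balance
(exhaustive over pairs), then repeatedly tries every unused taxon on each
side and accepts the single addition that improves the model log-likelihood
the most, stopping when the improvement drops to ``tol`` or the balance
reaches ``max_taxa`` members.  Ties break toward the plus side and the
lowest taxon index.  The reported orientation always has a nonnegative
balance effect, so the plus set is hazard-increasing under the Cox model and
survival-time-increasing under an AFT model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .balance import BalanceSpec, compute_balance, swap_sign
from .community import KernelTestResult, community_test, gate_warning
from .errors import NumericalError, ValidationError
from .preprocess import Composition, CountTable, SurvivalOutcome
from .survival import AFTFit, CoxFit, cox_loglik_at, fit_cox, fit_weibull_aft

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionStep",
    "SelectionResult",
    "initialize_pair",
    "greedy_grow",
    "select_balance",
    "enumerate_balances",
    "exhaustive_best",
]

Model = Literal["cox", "weibull"]


@dataclass(frozen=True)
class SelectionStep:
    spec: BalanceSpec
    criterion: float  # maximized model log-likelihood
    p_gamma: float
    added_taxon: int | None = None
    added_side: str | None = None  # "plus" | "minus" | None for the seed pair


@dataclass
class SelectionResult:
    best_spec: BalanceSpec
    fit: CoxFit | AFTFit
    trace: list[SelectionStep]
    community_test: KernelTestResult | None
    caution: bool
    settings: dict = field(default_factory=dict)

    @property
    def balance_effect(self) -> float:
        return self.fit.gamma if isinstance(self.fit, CoxFit) else self.fit.gamma_prime


def _fit_model(B: np.ndarray, outcome: SurvivalOutcome, model: Model,
               ties: str = "efron") -> CoxFit | AFTFit:
    if model == "cox":
        return fit_cox(B, outcome, ties=ties)
    if model == "weibull":
        return fit_weibull_aft(B, outcome)
    raise ValidationError(f"unknown model {model!r}")


def _try_fit(spec: BalanceSpec, X: Composition | np.ndarray,
             outcome: SurvivalOutcome, model: Model, ties: str
             ) -> CoxFit | AFTFit | None:
    """Fit the model for one candidate balance; None when unusable."""
    B = compute_balance(X, spec)
    try:
        fit = _fit_model(B, outcome, model, ties)
    except (NumericalError, FloatingPointError, np.linalg.LinAlgError) as exc:
        logger.warning("candidate %s failed to fit: %s", spec, exc)
        return None
    if not fit.converged:
        logger.warning("candidate %s did not converge; skipped", spec)
        return None
    return fit


def _orient(spec: BalanceSpec, fit: CoxFit | AFTFit,
            X: Composition | np.ndarray, outcome: SurvivalOutcome,
            model: Model, ties: str) -> tuple[BalanceSpec, CoxFit | AFTFit]:
    """Canonicalize so the reported balance effect is nonnegative."""
    effect = fit.gamma if isinstance(fit, CoxFit) else fit.gamma_prime
    if effect < 0:
        spec = swap_sign(spec)
        refit = _try_fit(spec, X, outcome, model, ties)
        if refit is not None:
            fit = refit
    return spec, fit


def initialize_pair(
    X: Composition | np.ndarray,
    outcome: SurvivalOutcome,
    model: Model = "cox",
    ties: str = "efron",
) -> SelectionStep:
    """Exhaustive search over 1-vs-1 balances for the starting pair.

    The model log-likelihood of a 1-vs-1 balance is invariant to swapping
    the two sides (the balance negates, the effect sign flips), so unordered
    pairs are evaluated once and the winner is oriented to a nonnegative
    effect.  Ties break toward the lowest taxon indices.
    """
    K = (X.X if isinstance(X, Composition) else np.asarray(X)).shape[1]
    if K < 2:
        raise ValidationError("at least two taxa are required")
    best: tuple[float, BalanceSpec, CoxFit | AFTFit] | None = None
    for a in range(K):
        for b in range(a + 1, K):
            spec = BalanceSpec((a,), (b,))
            fit = _try_fit(spec, X, outcome, model, ties)
            if fit is None:
                continue
            if best is None or fit.loglik > best[0]:
                best = (fit.loglik, spec, fit)
    if best is None:
        raise NumericalError("no 1-vs-1 balance could be fitted")
    _, spec, fit = best
    spec, fit = _orient(spec, fit, X, outcome, model, ties)
    return SelectionStep(spec=spec, criterion=fit.loglik, p_gamma=fit.p_gamma)


def greedy_grow(
    X: Composition | np.ndarray,
    outcome: SurvivalOutcome,
    model: Model,
    init: SelectionStep,
    max_taxa: int = 15,
    tol: float = 2.0,
    ties: str = "efron",
) -> list[SelectionStep]:
    """Grow the balance one taxon at a time while the criterion improves.

    Every unused taxon is tried on the plus side then on the minus side; the
    single addition with the largest log-likelihood is accepted when the
    improvement exceeds ``tol``.  Returns the accepted trace including the
    initial step.
    """
    if max_taxa < 2:
        raise ValidationError("max_taxa must be at least 2")
    if tol < 0:
        raise ValidationError("tol must be nonnegative")
    K = (X.X if isinstance(X, Composition) else np.asarray(X)).shape[1]
    trace = [init]
    current = init
    while current.spec.size < min(max_taxa, K):
        used = current.spec.taxa()
        best: tuple[float, BalanceSpec, CoxFit | AFTFit, int, str] | None = None
        for side in ("plus", "minus"):
            for j in range(K):
                if j in used:
                    continue
                if side == "plus":
                    cand = BalanceSpec(current.spec.plus + (j,), current.spec.minus)
                else:
                    cand = BalanceSpec(current.spec.plus, current.spec.minus + (j,))
                fit = _try_fit(cand, X, outcome, model, ties)
                if fit is None:
                    continue
                if best is None or fit.loglik > best[0]:
                    best = (fit.loglik, cand, fit, j, side)
        if best is None:
            break
        crit, cand, fit, j, side = best
        if crit - current.criterion <= tol:
            break
        current = SelectionStep(spec=cand, criterion=crit, p_gamma=fit.p_gamma,
                                added_taxon=j, added_side=side)
        trace.append(current)
    return trace


def _cv_choose_size(
    X: Composition | np.ndarray,
    outcome: SurvivalOutcome,
    model: Model,
    max_taxa: int,
    tol: float,
    ties: str,
    full_trace: list[SelectionStep],
    cv_folds: int,
    seed: int | None,
) -> int:
    """Pick the balance size by k-fold cross-validated held-out log-likelihood.

    Each training fold reruns the full selection; the selected spec at each
    size is refit on the training fold and its log-likelihood evaluated on
    the held-out fold at the trained coefficients.  The smallest size within
    one standard error of the best mean wins.
    """
    M = X.X if isinstance(X, Composition) else np.asarray(X)
    n = M.shape[0]
    rng = np.random.default_rng(seed)
    fold_of = rng.permutation(n) % cv_folds
    sizes = [s.spec.size for s in full_trace]
    scores = np.full((cv_folds, len(sizes)), np.nan)
    for f in range(cv_folds):
        train = np.flatnonzero(fold_of != f)
        test = np.flatnonzero(fold_of == f)
        out_tr = outcome.subset(train)
        out_te = outcome.subset(test)
        if out_tr.n_events == 0 or out_te.n_events == 0:
            continue
        try:
            init = initialize_pair(M[train], out_tr, model, ties)
            trace = greedy_grow(M[train], out_tr, model, init, max_taxa, tol, ties)
        except (ValidationError, NumericalError):
            continue
        for si, size in enumerate(sizes):
            step = next((s for s in trace if s.spec.size >= size), trace[-1])
            fit = _try_fit(step.spec, M[train], out_tr, model, ties)
            if fit is None:
                continue
            B_te = compute_balance(M[test], step.spec)
            if model == "cox":
                scores[f, si] = cox_loglik_at(B_te, out_te, fit.gamma, fit.beta, ties)
            else:
                from .survival import _aft_negloglik  # evaluated, not optimized
                Z = out_te.covariates
                ones = np.ones((len(test), 1))
                Xd = np.hstack([ones, B_te[:, None]] + ([Z] if Z is not None else []))
                theta = np.concatenate((
                    [fit.intercept, fit.gamma_prime], fit.beta_prime, [np.log(fit.scale)]))
                scores[f, si] = -_aft_negloglik(theta, Xd, np.log(out_te.time),
                                                out_te.event, fit.family)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(scores, axis=0)
        se = np.nanstd(scores, axis=0, ddof=1) / np.sqrt(np.sum(~np.isnan(scores), axis=0))
    if np.all(np.isnan(mean)):
        return sizes[-1]
    best_i = int(np.nanargmax(mean))
    cutoff = mean[best_i] - (se[best_i] if np.isfinite(se[best_i]) else 0.0)
    for si, size in enumerate(sizes):
        if np.isfinite(mean[si]) and mean[si] >= cutoff:
            return size
    return sizes[best_i]


def select_balance(
    X: Composition,
    outcome: SurvivalOutcome,
    model: Model = "cox",
    counts: CountTable | None = None,
    max_taxa: int = 15,
    tol: float = 2.0,
    cv_folds: int | None = None,
    seed: int | None = None,
    ties: str = "efron",
    n_permutations: int = 999,
    alpha: float = 0.05,
) -> SelectionResult:
    """Full selection: community pre-test, pair initialization, greedy growth.

    ``counts`` (the unfiltered-of-zeros raw table) feeds the Bray-Curtis and
    Jaccard kernels of the community test; when omitted the pre-test is
    skipped and the caution flag is False by convention.
    """
    ct_result = None
    caution = False
    if counts is not None:
        ct_result, _ = community_test(counts, outcome, n_permutations=n_permutations,
                                      seed=seed)
        caution = gate_warning(ct_result, alpha)
        if caution:
            logger.warning(
                "community-level association is not significant (omnibus p=%.3g >= %.2g); "
                "advising caution when interpreting the selected balance",
                ct_result.omnibus_p, alpha)

    init = initialize_pair(X, outcome, model, ties)
    trace = greedy_grow(X, outcome, model, init, max_taxa=max_taxa, tol=tol, ties=ties)

    final_step = trace[-1]
    if cv_folds:
        size = _cv_choose_size(X, outcome, model, max_taxa, tol, ties, trace,
                               cv_folds, seed)
        final_step = next((s for s in trace if s.spec.size >= size), trace[-1])

    fit = _try_fit(final_step.spec, X, outcome, model, ties)
    if fit is None:
        raise NumericalError("final balance failed to refit")
    spec, fit = _orient(final_step.spec, fit, X, outcome, model, ties)

    return SelectionResult(
        best_spec=spec,
        fit=fit,
        trace=trace,
        community_test=ct_result,
        caution=caution,
        settings={
            "model": model, "ties": ties, "max_taxa": max_taxa, "tol": tol,
            "cv_folds": cv_folds, "seed": seed,
            "n_permutations": n_permutations, "alpha": alpha,
        },
    )


# --------------------------------------------------------------------------
# Exhaustive enumeration (test oracle and small-problem reference)
# --------------------------------------------------------------------------

def enumerate_balances(n_taxa: int, max_plus: int, max_minus: int):
    """Yield every balance with side sizes up to the given caps.

    Only one orientation per unordered pair of sets is yielded, since the
    model criterion is orientation invariant.
    """
    from itertools import combinations
    taxa = range(n_taxa)
    for kp in range(1, max_plus + 1):
        for plus in combinations(taxa, kp):
            rest = [t for t in taxa if t not in plus]
            for km in range(1, max_minus + 1):
                for minus in combinations(rest, km):
                    if (kp, plus) > (km, minus):
                        continue  # orientation dedup
                    yield BalanceSpec(plus, minus)


def exhaustive_best(
    X: Composition | np.ndarray,
    outcome: SurvivalOutcome,
    model: Model = "cox",
    max_plus: int = 2,
    max_minus: int = 2,
    ties: str = "efron",
    penalty_per_taxon: float = 0.0,
) -> tuple[BalanceSpec, float]:
    """Brute-force best balance under an optionally size-penalized criterion.

    ``penalty_per_taxon`` subtracts that many log-likelihood units per taxon
    beyond the initial pair, mirroring the greedy acceptance hurdle.
    """
    best: tuple[float, float, BalanceSpec] | None = None
    for spec in enumerate_balances(
            (X.X if isinstance(X, Composition) else np.asarray(X)).shape[1],
            max_plus, max_minus):
        fit = _try_fit(spec, X, outcome, model, ties)
        if fit is None:
            continue
        crit = fit.loglik - penalty_per_taxon * (spec.size - 2)
        if best is None or crit > best[0]:
            best = (crit, fit.loglik, spec)
    if best is None:
        raise NumericalError("no balance could be fitted")
    return best[2], best[1]
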