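"""End-to-end run: read -> filter -> close -> community test -> selection ->
fit -> artifacts on disk, plus quartile-stratified survival curves."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .balance import compute_balance, spec_with_names
from .community import community_test, gate_warning
from .errors import ValidationError
from .preprocess import close_composition, filter_taxa, read_tables
from .selection import SelectionResult, select_balance
from .survival import AFTFit, CoxFit, predict_survival_curves

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "render_curves"]


@dataclass(frozen=True)
class RunConfig:
    """Every user-settable option of a pipeline run; echoed into the report."""

    counts_path: str
    metadata_path: str
    time_col: str
    event_col: str
    out_dir: str
    covariate_cols: tuple[str, ...] = ()
    model: str = "cox"  # cox | weibull
    ties: str = "efron"
    filter_mode: str = "remove_rare"
    filter_threshold: float = 0.0001
    pseudocount: float = 0.5
    max_taxa: int = 15
    tol: float = 2.0
    cv_folds: int | None = None
    n_permutations: int = 999
    alpha: float = 0.05
    seed: int = 0
    plot: bool = False

    def __post_init__(self) -> None:
        if self.model not in ("cox", "weibull"):
            raise ValidationError("model must be 'cox' or 'weibull'")
        if self.ties not in ("efron", "breslow"):
            raise ValidationError("ties must be 'efron' or 'breslow'")
        if self.filter_mode not in ("remove_rare", "keep_common", "none"):
            raise ValidationError("filter_mode must be remove_rare, keep_common or none")
        if not 0 <= self.filter_threshold < 1:
            raise ValidationError("filter_threshold must lie in [0, 1)")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def run_pipeline(cfg: RunConfig) -> SelectionResult:
    """Execute the full analysis and write artifacts under ``cfg.out_dir``.

    Artifacts: report.json, balance.tsv, trace.tsv, distance_*.tsv,
    curves.tsv and optionally curves.png.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table, outcome = read_tables(
        cfg.counts_path, cfg.metadata_path, cfg.time_col, cfg.event_col,
        cfg.covariate_cols)
    if cfg.filter_mode != "none":
        table = filter_taxa(table, cfg.filter_mode, cfg.filter_threshold)
    composition = close_composition(table, cfg.pseudocount)

    ct_result, dists = community_test(
        table, outcome, n_permutations=cfg.n_permutations, seed=cfg.seed)
    caution = gate_warning(ct_result, cfg.alpha)
    if caution:
        logger.warning(
            "community-level association is not significant (omnibus p=%.3g); "
            "advising caution when interpreting the selected balance",
            ct_result.omnibus_p)

    result = select_balance(
        composition, outcome, model=cfg.model, counts=None,
        max_taxa=cfg.max_taxa, tol=cfg.tol, cv_folds=cfg.cv_folds,
        seed=cfg.seed, ties=cfg.ties, alpha=cfg.alpha)
    result.community_test = ct_result
    result.caution = caution
    result.settings.update(cfg.to_dict())

    balances = compute_balance(composition, result.best_spec)
    _write_tsv(
        pd.DataFrame({"sample_id": composition.sample_ids, "balance": balances}),
        out / "balance.tsv")
    for name, d in dists.items():
        frame = pd.DataFrame(d.D, index=table.sample_ids, columns=table.sample_ids)
        frame.to_csv(out / f"distance_{name}.tsv", sep="\t")
    _write_tsv(
        pd.DataFrame([
            {
                "step": i,
                "k_plus": s.spec.k_plus,
                "k_minus": s.spec.k_minus,
                "criterion": s.criterion,
                "p_gamma": s.p_gamma,
                "added_taxon": "" if s.added_taxon is None
                else table.taxon_ids[s.added_taxon],
                "added_side": s.added_side or "",
            }
            for i, s in enumerate(result.trace)
        ]),
        out / "trace.tsv")

    curves = None
    if composition.n_samples >= 4 and result.fit.converged:
        curves = render_curves(
            result.fit, balances,
            covariate_profile=(outcome.covariates.mean(axis=0)
                               if outcome.covariates is not None else None),
            out_dir=out if cfg.plot else None)
        _write_tsv(curves, out / "curves.tsv")

    report = {
        "config": cfg.to_dict(),
        "n_samples": composition.n_samples,
        "n_taxa": composition.n_taxa,
        "n_events": outcome.n_events,
        "balance": spec_with_names(result.best_spec, composition.taxon_ids),
        "fit": result.fit.summary(),
        "community_test": ct_result.summary(),
        "caution": caution,
        "trace_length": len(result.trace),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return result


def render_curves(
    fit: CoxFit | AFTFit,
    balances: np.ndarray,
    covariate_profile: np.ndarray | None = None,
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Survival curves at the first and third quartiles of the balances.

    Quartiles use the linear-interpolation convention.  When ``out_dir`` is
    given a PNG figure is written there as well.
    """
    balances = np.asarray(balances, dtype=float)
    if balances.size < 4:
        raise ValidationError("at least 4 samples are needed for quartile curves")
    q1, q3 = np.quantile(balances, [0.25, 0.75])
    curves = predict_survival_curves(fit, np.array([q1, q3]), covariate_profile)
    if out_dir is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        for level, label in ((q1, f"Q1 balance = {q1:.2f}"),
                             (q3, f"Q3 balance = {q3:.2f}")):
            sub = curves[np.isclose(curves["level"], level)]
            ax.step(sub["time"], sub["survival"], where="post", label=label)
        ax.set_xlabel("time")
        ax.set_ylabel("predicted survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(Path(out_dir) / "curves.png", dpi=150)
        plt.close(fig)
    return curves
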