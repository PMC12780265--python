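"""Clinical evaluation protocol: discrimination, calibration, utility.

Implements the full evaluation suite around the BCR models: Mann-Whitney
AUROC with patient-level bootstrap percentile intervals (10,000 resamples by
default), the Brier score, equal-width-bin calibration tables, decision-curve
net benefit, stratified 3-fold internal cross-validation, train-once
external validation, and the two cohort-characterisation tests (two-sided
Fisher's exact on 2x2 tables, Wilcoxon rank-sum on continuous variables).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import brier_score_loss, roc_auc_score
from sklearn.model_selection import StratifiedKFold, KFold

from ._seeds import child_rng, child_seed
from .prognosis import BcrModel, BcrModelConfig, MODEL_CONFIGS, build_design
from .reasoning import IntermediateScoreModel

__all__ = [
    "EvaluationReport",
    "auroc",
    "bootstrap_auroc",
    "brier",
    "calibration_curve",
    "decision_curve",
    "kfold_protocol",
    "external_protocol",
    "fisher_exact_2x2",
    "wilcoxon_rank_sum",
    "evaluate_predictions",
]

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.05, 0.601, 0.05), 10))


def _check_binary(labels) -> np.ndarray:
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if set(classes.tolist()) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("both outcome classes must be present")
    return y


def auroc(scores, labels) -> float:
    """Probability a random positive outranks a random negative (ties 1/2)."""
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return float(roc_auc_score(y, s))


def bootstrap_auroc(scores, labels, n_boot: int = 10_000, seed: int = 0,
                    ci: float = 0.95) -> tuple[float, float, float]:
    """Patient-level bootstrap percentile CI for the AUROC.

    Resamples patients with replacement; a resample missing one outcome
    class is redrawn so exactly ``n_boot`` valid resamples contribute.
    Returns ``(point, ci_low, ci_high)``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    y = _check_binary(labels)
    s = np.asarray(scores, dtype=float)
    point = auroc(s, y)
    rng = child_rng(seed, "bootstrap_auroc")
    n = len(y)
    vals = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            yb = y[idx]
            if 0 < yb.sum() < n:
                break
        vals[b] = roc_auc_score(yb, s[idx])
    alpha = (1 - ci) / 2
    lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
    return point, float(lo), float(hi)


def brier(probabilities, labels) -> float:
    """Mean squared difference between probability and binary outcome."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=int)
    return float(brier_score_loss(y, p))


def calibration_curve(probabilities, labels, n_bins: int = 10) -> pd.DataFrame:
    """Equal-width calibration table on [0, 1]; empty bins omitted.

    Columns: ``bin_mean_pred`` (mean predicted probability in the bin),
    ``bin_mean_obs`` (observed outcome fraction) and ``n``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    y = np.asarray(labels, dtype=float)
    edges = np.linspace(0, 1, n_bins + 1)
    which = np.minimum(np.digitize(p, edges[1:-1], right=False), n_bins - 1)
    rows = []
    for b in range(n_bins):
        mask = which == b
        if not mask.any():
            continue
        rows.append((float(p[mask].mean()), float(y[mask].mean()),
                     int(mask.sum())))
    return pd.DataFrame(rows, columns=["bin_mean_pred", "bin_mean_obs", "n"])


def decision_curve(probabilities, labels,
                   thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Net benefit of treating at probability >= t, vs treat-all/none.

    ``NB(t) = TP/n - FP/n * t/(1-t)``; treat-all is
    ``pi - (1-pi) * t/(1-t)`` with prevalence ``pi``; treat-none is 0.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    t_arr = np.asarray(thresholds, dtype=float)
    if np.any((t_arr <= 0) | (t_arr >= 1)):
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    pi = y.mean()
    rows = []
    for t in t_arr:
        treated = p >= t
        tp = int((treated & (y == 1)).sum())
        fp = int((treated & (y == 0)).sum())
        odds = t / (1 - t)
        nb = tp / n - fp / n * odds
        nb_all = pi - (1 - pi) * odds
        rows.append((float(t), nb, nb_all, 0.0))
    return pd.DataFrame(rows, columns=["threshold", "net_benefit",
                                       "treat_all", "treat_none"])


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the table [[a, b], [c, d]].

    Sums hypergeometric probabilities of every same-margin table no more
    likely than the observed one (the minimum-likelihood rule).
    """
    cells = [a, b, c, d]
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError("cells must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError("both margins must be positive")
    return float(stats.fisher_exact([[a, b], [c, d]]).pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided rank-sum p: exact enumeration for n <= 10, else normal.

    The exact path enumerates all assignments of the pooled midranks to the
    first group; the large-sample path is the continuity-corrected normal
    approximation of the Mann-Whitney statistic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n_total = x.size + y.size
    if n_total <= 10:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)  # midranks under ties
        obs = ranks[:x.size].sum()
        mean = x.size * (n_total + 1) / 2
        count = 0
        total = comb(n_total, x.size)
        for idx in combinations(range(n_total), x.size):
            w = ranks[list(idx)].sum()
            if abs(w - mean) >= abs(obs - mean) - 1e-12:
                count += 1
        return count / total
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


@dataclass
class EvaluationReport:
    """All metrics for one (cohort, model configuration) pair."""

    cohort: str
    config: str
    auroc: float
    ci_low: float
    ci_high: float
    n_boot: int
    brier: float
    calibration: pd.DataFrame
    net_benefit: pd.DataFrame
    n: int
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.auroc <= 1 and 0 <= self.brier <= 1):
            raise ValueError("metrics out of range")
        if not self.ci_low <= self.auroc <= self.ci_high:
            raise ValueError("bootstrap CI must bracket the point estimate")
        if int(self.calibration["n"].sum()) != self.n:
            raise ValueError("calibration bin counts must sum to n")

    def to_row(self) -> dict:
        return {
            "cohort": self.cohort, "config": self.config, "n": self.n,
            "auroc": self.auroc, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "n_boot": self.n_boot,
            "brier": self.brier, "seed": self.seed,
        }

    def to_json_dict(self) -> dict:
        d = self.to_row()
        d["calibration"] = self.calibration.to_dict(orient="records")
        d["net_benefit"] = self.net_benefit.to_dict(orient="records")
        return d


def evaluate_predictions(scores, probabilities, labels, cohort: str,
                         config: str, n_boot: int = 10_000, seed: int = 0,
                         n_bins: int = 10) -> EvaluationReport:
    """Bundle AUROC (+bootstrap CI), Brier, calibration and net benefit."""
    point, lo, hi = bootstrap_auroc(scores, labels, n_boot=n_boot, seed=seed)
    return EvaluationReport(
        cohort=cohort, config=config, auroc=point, ci_low=lo, ci_high=hi,
        n_boot=n_boot, brier=brier(probabilities, labels),
        calibration=calibration_curve(probabilities, labels, n_bins=n_bins),
        net_benefit=decision_curve(probabilities, labels),
        n=len(np.asarray(labels)), seed=seed)


def _fit_stage(cohort: pd.DataFrame, compositions: pd.DataFrame,
               config: BcrModelConfig, seed: int):
    """Fit the intermediate step (if the config needs one) plus final model."""
    intermediate = None
    if config.inputs in ("ml_gleason", "ml_reasoning", "psa_plus_ml_reasoning"):
        kind = ("gleason_grading" if config.inputs == "ml_gleason"
                else "reasoning_score")
        intermediate = IntermediateScoreModel.from_dataframe(
            compositions, cohort, target_kind=kind).fit(
                seed=child_seed(seed, "intermediate", config.inputs))
    design = build_design(config, cohort, compositions, intermediate)
    results = BcrModel(design, cohort["bcr"].to_numpy(), config).fit()
    return intermediate, results


def kfold_protocol(cohort: pd.DataFrame, compositions: pd.DataFrame,
                   configs=MODEL_CONFIGS, k: int = 3, stratified: bool = True,
                   seed: int = 0, n_boot: int = 10_000,
                   cohort_label: str | None = None) -> dict[str, EvaluationReport]:
    """Internal validation: stratified k-fold CV with pooled out-of-fold scores.

    Every stage that learns from data — the intermediate regressor, the
    final linear model and the recalibration — is refitted inside each
    training fold; the pooled out-of-fold predictions feed the bootstrap.
    Train/test patient-id disjointness is asserted per fold as a leakage
    guard.
    """
    y = _check_binary(cohort["bcr"])
    n = len(cohort)
    if n < k:
        raise ValueError("fewer samples than folds")
    label = cohort_label or str(cohort["cohort"].iloc[0])
    splitter_seed = child_seed(seed, "kfold", label)
    if stratified:
        if min(np.bincount(y)) < k:
            raise ValueError("a class is too small to stratify into k folds")
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=splitter_seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=splitter_seed)

    comp = compositions.reset_index(drop=True)
    cohort = cohort.reset_index(drop=True)
    reports = {}
    for cfg_name in configs:
        config = BcrModelConfig(inputs=cfg_name, seed=seed)
        oof_score = np.full(n, np.nan)
        oof_prob = np.full(n, np.nan)
        for tr, te in splitter.split(np.zeros(n), y):
            train_ids = set(cohort.loc[tr, "patient_id"])
            test_ids = set(cohort.loc[te, "patient_id"])
            if train_ids & test_ids:
                raise ValueError("patient-id overlap between training and "
                                 "test folds")
            intermediate, results = _fit_stage(
                cohort.iloc[tr], comp.iloc[tr], config, seed)
            test_design = build_design(config, cohort.iloc[te],
                                       comp.iloc[te], intermediate)
            pred = results.predict(test_design)
            oof_score[te] = pred["score"].to_numpy()
            oof_prob[te] = pred["probability"].to_numpy()
        assert not np.isnan(oof_score).any()
        reports[cfg_name] = evaluate_predictions(
            oof_score, oof_prob, y, cohort=label, config=cfg_name,
            n_boot=n_boot, seed=child_seed(seed, "eval", label, cfg_name))
    return reports


def external_protocol(train_cohort: pd.DataFrame,
                      train_compositions: pd.DataFrame,
                      test_cohorts: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
                      configs=MODEL_CONFIGS, seed: int = 0,
                      n_boot: int = 10_000
                      ) -> dict[str, dict[str, EvaluationReport]]:
    """External validation: train once, apply unchanged to each test cohort.

    ``test_cohorts`` maps cohort label to ``(cohort_table, compositions)``.
    Patient ids must be disjoint from the training cohort; empty test
    cohorts raise.
    """
    train_ids = set(train_cohort["patient_id"])
    for label, (tc, _) in test_cohorts.items():
        if len(tc) == 0:
            raise ValueError(f"external cohort {label!r} is empty")
        if train_ids & set(tc["patient_id"]):
            raise ValueError(f"patient ids overlap between training cohort "
                             f"and {label!r}")
    out: dict[str, dict[str, EvaluationReport]] = {lab: {}
                                                   for lab in test_cohorts}
    for cfg_name in configs:
        config = BcrModelConfig(inputs=cfg_name, seed=seed)
        intermediate, results = _fit_stage(
            train_cohort.reset_index(drop=True),
            train_compositions.reset_index(drop=True), config, seed)
        for label, (tc, tcomp) in test_cohorts.items():
            design = build_design(config, tc.reset_index(drop=True),
                                  tcomp.reset_index(drop=True), intermediate)
            pred = results.predict(design)
            out[label][cfg_name] = evaluate_predictions(
                pred["score"].to_numpy(), pred["probability"].to_numpy(),
                tc["bcr"].to_numpy(), cohort=label, config=cfg_name,
                n_boot=n_boot,
                seed=child_seed(seed, "eval", label, cfg_name))
    return out
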