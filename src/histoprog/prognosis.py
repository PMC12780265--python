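"""Final biochemical-recurrence models: five input configurations.

The 5-year BCR label is fitted by *linear* regression on one of five
designs — (1) the Gleason score alone, (2) all k composition fractions
directly, (3) the machine-predicted Gleason score, (4) the machine-predicted
reasoning-oriented score, or (5) PSA together with the predicted reasoning
score.  The raw linear score drives discrimination (AUROC); for probability
metrics (Brier, calibration, decision curves) the score is passed through a
logistic recalibration fitted on the training data ("updating" for outcome
incidence), whose maximum-likelihood fit makes the mean predicted
probability equal the training incidence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LinearRegression, Ridge

from .reasoning import IntermediateScoreResults

__all__ = [
    "MODEL_CONFIGS",
    "BcrModelConfig",
    "build_design",
    "BcrModel",
    "BcrResults",
]

MODEL_CONFIGS: tuple[str, ...] = (
    "gleason_only",
    "direct_100",
    "ml_gleason",
    "ml_reasoning",
    "psa_plus_ml_reasoning",
)

#: Ridge penalty used for the all-features design when n <= k.
_DIRECT_FALLBACK_PENALTY = 1.0


@dataclass(frozen=True)
class BcrModelConfig:
    """One of the five final-model input configurations."""

    inputs: str = "ml_reasoning"
    psa_transform: str = "raw"  # {"raw", "log"}
    recalibration: str = "slope"  # {"slope", "intercept"}
    seed: int = 0

    def __post_init__(self):
        if self.inputs not in MODEL_CONFIGS:
            raise ValueError(
                f"inputs must be one of {MODEL_CONFIGS}, got {self.inputs!r}")
        if self.psa_transform not in ("raw", "log"):
            raise ValueError("psa_transform must be 'raw' or 'log'")
        if self.recalibration not in ("slope", "intercept"):
            raise ValueError("recalibration must be 'slope' or 'intercept'")


def build_design(
    config: BcrModelConfig,
    cohort: pd.DataFrame,
    compositions: pd.DataFrame | None = None,
    intermediate: IntermediateScoreResults | None = None,
) -> pd.DataFrame:
    """Assemble the feature table for one configuration.

    ``cohort`` rows, ``compositions`` rows and the intermediate model must
    come from the same patients in the same order.  The returned design
    never contains the outcome column.
    """
    idx = cohort["patient_id"] if "patient_id" in cohort else cohort.index
    if config.inputs == "gleason_only":
        design = pd.DataFrame(
            {"gleason_score": cohort["gleason_score"].to_numpy(float)})
    elif config.inputs == "direct_100":
        if compositions is None:
            raise ValueError("direct_100 requires composition fractions")
        design = compositions.reset_index(drop=True).astype(float)
    elif config.inputs in ("ml_gleason", "ml_reasoning"):
        if compositions is None or intermediate is None:
            raise ValueError(f"{config.inputs} requires compositions and a "
                             "fitted intermediate model")
        _check_target(config.inputs, intermediate)
        pred = intermediate.predict(compositions.to_numpy(float))
        design = pd.DataFrame({"predicted_score": pred})
    elif config.inputs == "psa_plus_ml_reasoning":
        if "psa" not in cohort:
            raise ValueError("psa column required for the PSA configuration")
        if compositions is None or intermediate is None:
            raise ValueError("psa_plus_ml_reasoning requires compositions and "
                             "a fitted intermediate model")
        _check_target(config.inputs, intermediate)
        psa = cohort["psa"].to_numpy(float)
        if config.psa_transform == "log":
            psa = np.log(psa)
        pred = intermediate.predict(compositions.to_numpy(float))
        design = pd.DataFrame({"psa": psa, "predicted_score": pred})
    design.index = pd.Index(idx, name="patient_id")
    return design


def _check_target(inputs: str, intermediate: IntermediateScoreResults) -> None:
    wanted = "gleason_grading" if inputs == "ml_gleason" else "reasoning_score"
    if intermediate.target_kind != wanted:
        raise ValueError(
            f"{inputs} needs an intermediate model with target "
            f"{wanted!r}, got {intermediate.target_kind!r}")


class BcrModel:
    """Linear BCR model over a design table, with logistic recalibration.

    Parameters
    ----------
    design : DataFrame
        Feature table from :func:`build_design`; must not contain the
        outcome (a ``bcr`` column raises, as a leakage guard).
    labels : array of {0, 1}
        5-year BCR outcome, training only.
    config : BcrModelConfig
    """

    def __init__(self, design: pd.DataFrame, labels,
                 config: BcrModelConfig | None = None):
        if "bcr" in design.columns:
            raise ValueError("outcome column 'bcr' found in the design table; "
                             "the outcome may only enter as the label")
        y = np.asarray(labels, dtype=float)
        if design.shape[0] != y.shape[0]:
            raise ValueError("design and labels disagree in length")
        if set(np.unique(y)) - {0.0, 1.0}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(y)) < 2:
            raise ValueError("both outcome classes required for training")
        self.design = design
        self.endog = y
        self.config = config or BcrModelConfig()

    @property
    def incidence(self) -> float:
        return float(self.endog.mean())

    def fit(self) -> "BcrResults":
        X = self.design.to_numpy(float)
        n, p = X.shape
        constant_design = np.all(X == X[0], axis=0).all()
        if constant_design:
            # degenerate: no usable predictor; constant model at incidence
            return BcrResults(
                model=self, weights=np.zeros(p), intercept=self.incidence,
                recal_intercept=float(np.log(self.incidence
                                             / (1 - self.incidence))),
                recal_slope=0.0, degenerate=True)
        if self.config.inputs == "direct_100" and n <= p:
            reg = Ridge(alpha=_DIRECT_FALLBACK_PENALTY)
        else:
            reg = LinearRegression()
        reg.fit(X, self.endog)
        scores = reg.predict(X)
        a, b = _fit_recalibration(scores, self.endog,
                                  intercept_only=(self.config.recalibration
                                                  == "intercept"))
        return BcrResults(model=self,
                          weights=np.asarray(reg.coef_, dtype=float),
                          intercept=float(reg.intercept_),
                          recal_intercept=a, recal_slope=b)


def _fit_recalibration(scores: np.ndarray, y: np.ndarray,
                       intercept_only: bool = False) -> tuple[float, float]:
    """Logistic map score -> probability, fitted by maximum likelihood.

    Returns ``(a, b)`` for ``p = logistic(a + b * score)``.  With
    ``intercept_only`` the slope is fixed at 1 and only the intercept is
    estimated.  On perfect separation the statsmodels Newton fit fails and a
    weakly regularised fit is used instead.  Constant scores (possible when
    the least-squares slope is exactly zero) map to the incidence
    probability.
    """
    if np.ptp(scores) == 0:
        pi = float(np.mean(y))
        return float(np.log(pi / (1 - pi))), 0.0
    if intercept_only:
        offset = scores
        exog = np.ones((len(y), 1))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, exog, offset=offset).fit(disp=0)
            return float(res.params[0]), 1.0
        except Exception:
            return 0.0, 1.0
    exog = sm.add_constant(scores)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit(disp=0)
        params = np.asarray(res.params, dtype=float)
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite recalibration")
        return float(params[0]), float(params[1])
    except Exception:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, exog).fit_regularized(alpha=1e-6, disp=0)
        params = np.asarray(res.params, dtype=float)
        return float(params[0]), float(params[1])


@dataclass
class BcrResults:
    """Fitted final model: linear weights plus the recalibration map."""

    model: BcrModel
    weights: np.ndarray
    intercept: float
    recal_intercept: float
    recal_slope: float
    degenerate: bool = False

    @property
    def config(self) -> BcrModelConfig:
        return self.model.config

    @property
    def provenance(self) -> dict:
        from . import __version__
        return {
            "inputs": self.config.inputs,
            "psa_transform": self.config.psa_transform,
            "recalibration": self.config.recalibration,
            "seed": self.config.seed,
            "n_train": int(len(self.model.endog)),
            "incidence": self.model.incidence,
            "version": __version__,
        }

    @property
    def fittedvalues(self) -> pd.DataFrame:
        return self.predict(self.model.design)

    def predict(self, design: pd.DataFrame) -> pd.DataFrame:
        """Linear scores (for AUROC) and recalibrated probabilities."""
        if "bcr" in design.columns:
            raise ValueError("outcome column 'bcr' found in an inference "
                             "design; refusing to predict")
        if list(design.columns) != list(self.model.design.columns):
            raise ValueError(
                f"design columns {list(design.columns)} do not match the "
                f"fitted columns {list(self.model.design.columns)}")
        X = design.to_numpy(float)
        if self.degenerate:
            score = np.full(len(X), self.intercept)
        else:
            score = X @ self.weights + self.intercept
        z = np.clip(self.recal_intercept + self.recal_slope * score, -700, 700)
        prob = 1.0 / (1.0 + np.exp(-z))
        eps = 1e-12  # keep probabilities strictly inside (0, 1)
        prob = np.clip(prob, eps, 1 - eps)
        return pd.DataFrame({"score": score, "probability": prob},
                            index=design.index)

    def summary(self) -> str:
        cols = list(self.model.design.columns)
        lines = [
            "BCR prediction model (linear + logistic recalibration)",
            f"  configuration     : {self.config.inputs}",
            f"  n train / incidence: {len(self.model.endog)} / "
            f"{self.model.incidence:.3f}",
            f"  recalibration     : p = logistic({self.recal_intercept:.3f} "
            f"+ {self.recal_slope:.3f} * score)",
            f"  intercept         : {self.intercept:.4f}",
        ]
        if len(cols) <= 6:
            for c, w in zip(cols, self.weights):
                lines.append(f"  beta[{c}]".ljust(21) + f": {w:.4f}")
        else:
            lines.append(f"  columns           : {len(cols)} "
                         f"(|beta| max {np.abs(self.weights).max():.4f})")
        if self.degenerate:
            lines.append("  NOTE: constant design; model is the incidence")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "intercept": self.intercept,
            "weights": {c: float(w) for c, w in
                        zip(self.model.design.columns, self.weights)},
            "recalibration": {"intercept": self.recal_intercept,
                              "slope": self.recal_slope},
            "degenerate": self.degenerate,
        }
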