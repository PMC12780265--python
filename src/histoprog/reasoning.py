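"""The reasoning-oriented grading scale and the intermediate regression step.

The scale remaps the nine clinically occurring Gleason pattern combinations
onto a finer ordinal grid that separates combinations sharing a Gleason score
(e.g. 3+4 vs 4+3) and deliberately interleaves scores 8 and 9 by prognosis;
the ordering is *not* monotone in the Gleason score and must not be
"corrected".  During training each sample's base grade is shifted by +1 for a
biochemically recurrent (BCR-positive) outcome and -1 otherwise, giving an
11-point scale (1-11).  The shifted grade is a *training target only*: at
inference it is predicted from patch-composition features by a ridge
regression and the outcome label is never consulted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

__all__ = [
    "GLEASON_PAIRS",
    "REASONING_BASE_TABLE",
    "base_score",
    "adjusted_score",
    "ScoreScaler",
    "reasoning_scaler",
    "gleason_scaler",
    "scale_target",
    "IntermediateScoreModel",
    "IntermediateScoreResults",
]

# The nine pattern combinations in base-grade order (grades 2..10).
GLEASON_PAIRS: tuple[tuple[int, int], ...] = (
    (3, 3),  # Gleason <=6  -> 2
    (3, 4),  # Gleason 7    -> 3
    (4, 3),  # Gleason 7    -> 4
    (4, 4),  # Gleason 8    -> 5
    (3, 5),  # Gleason 8    -> 6
    (4, 5),  # Gleason 9    -> 7
    (5, 3),  # Gleason 8    -> 8
    (5, 4),  # Gleason 9    -> 9
    (5, 5),  # Gleason 10   -> 10
)

REASONING_BASE_TABLE: dict[tuple[int, int, int], int] = {
    (p + s, p, s): grade + 2 for grade, (p, s) in enumerate(GLEASON_PAIRS)
}


def base_score(gleason_score: int, primary: int, secondary: int) -> int:
    """Base grade (2-10) for a Gleason ``(score, primary, secondary)`` triple.

    Raises ``ValueError`` for any combination outside the nine supported
    rows (e.g. 4+2), including triples whose score does not equal
    primary + secondary.
    """
    key = (int(gleason_score), int(primary), int(secondary))
    try:
        return REASONING_BASE_TABLE[key]
    except KeyError:
        raise ValueError(
            f"unsupported Gleason pattern combination {key!r}; the reasoning "
            f"scale is defined only for {sorted(REASONING_BASE_TABLE)}"
        ) from None


def adjusted_score(base: int, bcr: int) -> int:
    """Outcome-adjusted training score: base+1 if BCR-positive else base-1.

    Only ever applied to training samples; the result lies in 1-11.
    """
    base = int(base)
    if not 2 <= base <= 10:
        raise ValueError(f"base grade {base} outside the 2-10 scale")
    if bcr not in (0, 1):
        raise ValueError(f"bcr must be 0 or 1, got {bcr!r}")
    return base + 1 if bcr == 1 else base - 1


@dataclass(frozen=True)
class ScoreScaler:
    """Affine map from a theoretical score range onto [0, 1].

    The range is theoretical (1-11 for the reasoning scale, 6-10 for the
    Gleason score), not empirical, so the map does not depend on the training
    sample and is stable under external validation.
    """

    lo: float
    hi: float

    def scale(self, scores):
        s = np.asarray(scores, dtype=float)
        if np.any(s < self.lo) or np.any(s > self.hi):
            raise ValueError(f"scores outside the [{self.lo}, {self.hi}] range")
        return (s - self.lo) / (self.hi - self.lo)

    def inverse(self, scaled):
        return np.asarray(scaled, dtype=float) * (self.hi - self.lo) + self.lo


def reasoning_scaler() -> ScoreScaler:
    return ScoreScaler(1.0, 11.0)


def gleason_scaler() -> ScoreScaler:
    return ScoreScaler(6.0, 10.0)


def scale_target(scores, kind: str = "reasoning_score"):
    """Scale integer grades to [0, 1]; returns ``(scaled, scaler)``."""
    if kind == "reasoning_score":
        scaler = reasoning_scaler()
    elif kind == "gleason_grading":
        scaler = gleason_scaler()
    else:
        raise ValueError(f"unknown target kind {kind!r}")
    return scaler.scale(scores), scaler


class IntermediateScoreModel:
    """Ridge regression of a (scaled) grading score on composition vectors.

    This is the intermediate reasoning step: it distils the k-dimensional
    patch-composition vector of a sample into a single predicted grade,
    either the reasoning-oriented score or, for comparison, the Gleason
    score.  The ridge penalty is chosen from a log-spaced grid by inner
    K-fold cross-validated mean squared error.

    Parameters
    ----------
    compositions : (n, k) array or DataFrame
        Row-normalised patch-composition fractions.
    targets : (n,) array
        Integer grades on the target scale (1-11 or 6-10); they are scaled
        internally with the theoretical-range scaler.
    target_kind : {"reasoning_score", "gleason_grading"}
    penalty_grid : sequence of nonnegative floats
    cv_folds : int
    """

    def __init__(
        self,
        compositions,
        targets,
        target_kind: str = "reasoning_score",
        penalty_grid: Sequence[float] | None = None,
        cv_folds: int = 5,
    ):
        X = np.asarray(compositions, dtype=float)
        if X.ndim != 2:
            raise ValueError("compositions must be 2-D (samples x clusters)")
        if X.shape[0] < 2:
            raise ValueError("need at least two training samples")
        y, scaler = scale_target(np.asarray(targets, dtype=float), target_kind)
        if len(y) != X.shape[0]:
            raise ValueError("compositions and targets disagree in length")
        if penalty_grid is None:
            penalty_grid = np.logspace(-3, 3, 7)
        penalty_grid = [float(a) for a in penalty_grid]
        if len(penalty_grid) == 0:
            raise ValueError("empty penalty grid")
        if any(a < 0 for a in penalty_grid):
            raise ValueError("ridge penalties must be nonnegative")
        self.exog = X
        self.endog = y
        self.target_kind = target_kind
        self.scaler = scaler
        self.penalty_grid = penalty_grid
        self.cv_folds = int(cv_folds)

    @classmethod
    def from_dataframe(cls, compositions: pd.DataFrame, cohort: pd.DataFrame,
                       target_kind: str = "reasoning_score", **kwargs):
        """Build from a composition matrix and a cohort table.

        For the reasoning target the adjusted score is computed from the
        cohort's Gleason columns and ``bcr`` label; for the Gleason target
        the ``gleason_score`` column is used directly.
        """
        if target_kind == "reasoning_score":
            targets = [
                adjusted_score(base_score(r.gleason_score, r.gleason_primary,
                                          r.gleason_secondary), r.bcr)
                for r in cohort.itertuples()
            ]
        else:
            targets = cohort["gleason_score"].to_numpy()
        return cls(compositions.to_numpy(dtype=float), targets,
                   target_kind=target_kind, **kwargs)

    def _cv_mse(self, alpha: float, seed: int) -> float:
        n = self.exog.shape[0]
        folds = KFold(n_splits=min(self.cv_folds, n), shuffle=True,
                      random_state=seed)
        errs = []
        for tr, te in folds.split(self.exog):
            model = Ridge(alpha=alpha) if alpha > 0 else Ridge(alpha=0.0)
            model.fit(self.exog[tr], self.endog[tr])
            resid = self.endog[te] - model.predict(self.exog[te])
            errs.append(float(np.mean(resid**2)))
        return float(np.mean(errs))

    def fit(self, seed: int = 0) -> "IntermediateScoreResults":
        """Select the penalty by inner CV and fit on all samples."""
        if len(self.penalty_grid) == 1 or self.exog.shape[0] < 3:
            best = self.penalty_grid[0]
        else:
            mses = [self._cv_mse(a, seed) for a in self.penalty_grid]
            # ties broken toward the smaller penalty
            best = self.penalty_grid[int(np.argmin(mses))]
        model = Ridge(alpha=best)
        model.fit(self.exog, self.endog)
        return IntermediateScoreResults(
            model=self,
            weights=np.asarray(model.coef_, dtype=float),
            intercept=float(model.intercept_),
            ridge_penalty=float(best),
            seed=int(seed),
        )


@dataclass
class IntermediateScoreResults:
    """Fitted intermediate regressor.

    ``predict`` returns values on the scaled [0, 1] axis; ``predict_score``
    additionally back-maps onto the native grade scale and provides a clipped
    copy for display (ranking uses the unclipped values).
    """

    model: IntermediateScoreModel
    weights: np.ndarray
    intercept: float
    ridge_penalty: float
    seed: int = 0

    @property
    def target_kind(self) -> str:
        return self.model.target_kind

    @property
    def scaler(self) -> ScoreScaler:
        return self.model.scaler

    def predict(self, compositions) -> np.ndarray:
        X = np.asarray(compositions, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.weights.shape[0]:
            raise ValueError(
                f"composition dimension {X.shape[1]} does not match the "
                f"fitted k={self.weights.shape[0]}"
            )
        return X @ self.weights + self.intercept

    def predict_score(self, compositions) -> pd.DataFrame:
        scaled = self.predict(compositions)
        score = self.scaler.inverse(scaled)
        clipped = np.clip(score, self.scaler.lo, self.scaler.hi)
        return pd.DataFrame(
            {"scaled": scaled, "score": score, "score_clipped": clipped}
        )

    def summary(self) -> str:
        lines = [
            "Intermediate reasoning regression (ridge)",
            f"  target            : {self.target_kind}",
            f"  clusters (k)      : {self.weights.shape[0]}",
            f"  ridge penalty     : {self.ridge_penalty:g}",
            f"  intercept         : {self.intercept:.4f}",
            f"  |w| max / mean    : {np.abs(self.weights).max():.4f} / "
            f"{np.abs(self.weights).mean():.4f}",
            f"  scale             : [{self.scaler.lo:g}, {self.scaler.hi:g}] -> [0, 1]",
        ]
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        return {
            "target_kind": self.target_kind,
            "ridge_penalty": self.ridge_penalty,
            "intercept": self.intercept,
            "scaler": {"lo": self.scaler.lo, "hi": self.scaler.hi},
            "weights": [float(w) for w in self.weights],
            "seed": self.seed,
        }
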