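"""Leave-one-out cross-validated obesity-rate regression.

With only ~50 regions, leave-one-out cross-validation (LOOCV) is the
natural resampling scheme: each region's obesity rate is predicted by a
model trained on all other regions, and the vector of held-out
predictions is scored by its Pearson correlation with the actual rates.

Four model families are supported: ordinary least squares, random
forest, radial-basis support-vector regression, and gradient-boosted
trees. Kernel and linear families are standardized with train-fold
statistics only, so no information leaks from the held-out region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .features import FeatureMatrix
from .records import ObesityTable

__all__ = [
    "MODEL_FAMILIES",
    "ModelSpec",
    "PredictionResult",
    "pearson",
    "loocv_predict",
    "evaluate_grid",
    "DEFAULT_SET_COMBINATIONS",
]

MODEL_FAMILIES = ("linear", "random_forest", "svm", "gradient_boosted_trees")

# The grid evaluated by default: each set alone, availability paired with
# each other set, and all three together.
DEFAULT_SET_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("availability",),
    ("afford_accept",),
    ("weighted_score",),
    ("availability", "afford_accept"),
    ("availability", "weighted_score"),
    ("availability", "afford_accept", "weighted_score"),
)


@dataclass(frozen=True)
class ModelSpec:
    """A model family plus hyperparameters and a base seed.

    Stochastic families are re-seeded deterministically per fold
    (``seed + fold index``), so results are reproducible and folds are
    decoupled.
    """

    family: str = "random_forest"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {MODEL_FAMILIES}"
            )


def _make_model(spec: ModelSpec, fold_seed: int):
    hp = dict(spec.hyperparameters)
    if spec.family == "linear":
        return make_pipeline(StandardScaler(), LinearRegression(**hp))
    if spec.family == "random_forest":
        hp.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=fold_seed, **hp)
    if spec.family == "svm":
        hp.setdefault("kernel", "rbf")
        return make_pipeline(StandardScaler(), SVR(**hp))
    hp.setdefault("n_estimators", 100)
    return XGBRegressor(random_state=fold_seed, n_jobs=1, **hp)


def pearson(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson product-moment correlation between two vectors."""
    a = np.asarray(actual, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(a, b)[0])


@dataclass
class PredictionResult:
    """Held-out predictions for every region plus the evaluation."""

    regions: list[str]
    actual: np.ndarray
    predicted: np.ndarray
    spec: ModelSpec
    feature_sets: tuple[str, ...]
    pearson_r: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"region": self.regions, "actual": self.actual, "predicted": self.predicted}
        )


def loocv_predict(
    matrix: FeatureMatrix, outcome: ObesityTable, spec: ModelSpec
) -> PredictionResult:
    """Predict each region from a model trained on all other regions.

    Regions are processed in sorted order so the result does not depend
    on input row order. Raises on a constant outcome (the evaluation
    correlation would be undefined).
    """
    regions = sorted(r for r in matrix.regions if r in outcome.rates)
    if len(regions) < 3:
        raise ValueError(f"need >= 3 regions with outcomes, have {len(regions)}")
    y = np.array([outcome.rates[r] for r in regions])
    if np.ptp(y) == 0:
        raise ValueError("constant outcome: correlation undefined")
    row_of = {r: i for i, r in enumerate(matrix.regions)}
    X = matrix.values[[row_of[r] for r in regions]]

    preds = np.empty(len(regions))
    for fold, _ in enumerate(regions):
        mask = np.ones(len(regions), dtype=bool)
        mask[fold] = False
        model = _make_model(spec, spec.seed + fold)
        model.fit(X[mask], y[mask])
        preds[fold] = float(model.predict(X[~mask])[0])
    return PredictionResult(
        regions=regions,
        actual=y,
        predicted=preds,
        spec=spec,
        feature_sets=tuple(sorted(set(matrix.set_tags))),
        pearson_r=pearson(y, preds),
    )


def evaluate_grid(
    matrix: FeatureMatrix,
    outcome: ObesityTable,
    families: Sequence[str] = MODEL_FAMILIES,
    set_combinations: Sequence[Sequence[str]] = DEFAULT_SET_COMBINATIONS,
    seed: int = 0,
    hyperparameters: Optional[dict[str, dict]] = None,
) -> pd.DataFrame:
    """Pearson r for every (feature-set combination, family) pair.

    The weighted score is a single column, so with that set alone only
    the linear family is fit; other families are marked not applicable
    (NaN). Returns a DataFrame indexed by the combination label with one
    column per family, plus a ``best`` flag column.
    """
    hyperparameters = hyperparameters or {}
    rows = {}
    for combo in set_combinations:
        combo = tuple(combo)
        label = "+".join(combo)
        sub = matrix.select_sets(combo)
        if sub.values.shape[1] == 0:
            raise ValueError(f"combination {label!r} selects no columns")
        single = combo == ("weighted_score",)
        cells = {}
        for fam in families:
            if single and fam != "linear":
                cells[fam] = np.nan
                continue
            spec = ModelSpec(fam, hyperparameters.get(fam, {}), seed=seed)
            cells[fam] = loocv_predict(sub, outcome, spec).pearson_r
        rows[label] = cells
    grid = pd.DataFrame.from_dict(rows, orient="index")[list(families)]
    best_combo, best_family = grid.stack().idxmax()
    grid["best"] = ""
    grid.loc[best_combo, "best"] = best_family
    return grid
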