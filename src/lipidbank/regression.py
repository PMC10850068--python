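"""Composition -> membrane property regression.

Predicts area per lipid (A^2) and bilayer thickness (nm) of a membrane from
its lipid composition.  The most abundant lipids (POPC, POPE, POPG, POPS,
cholesterol) are treated explicitly; sphingomyelins, cardiolipins and PI
lipids are grouped by headgroup irrespective of acyl chain content.  Salt,
temperature and other conditions are not features.  Linear and ridge
regression are the first-class model families (linear being preferred for
its simplicity and performance); further scikit-learn regressors can be
plugged in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import ElasticNet, Lasso, LinearRegression, Ridge
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import GridSearchCV, KFold, train_test_split
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor

from .errors import FeaturizationError, UsageError, InputError

__all__ = [
    "FEATURE_CLASSES",
    "featurize",
    "composition_from_string",
    "TrainedPropertyModel",
    "train_model",
    "predict_properties",
    "evaluate_against_reference",
    "chains_per_molecule",
]

FEATURE_CLASSES = ("POPC", "POPE", "POPG", "POPS", "CHOL", "SM", "CL", "PI")

# headgroup-based grouping of the sparse lipid classes
_CLASS_OF = {
    **{name: name for name in FEATURE_CLASSES},
    "PSM": "SM",
    "SSM": "SM",
    "NSM": "SM",
    "DPSM": "SM",
    "TOCL": "CL",
    "TMCL": "CL",
    "POPI": "PI",
    "SAPI": "PI",
}

# molecules silently ignored by featurization (not membrane components)
_IGNORED = {"SOL", "POT", "SOD", "CLA", "CAL", "LIT", "CES"}

# acyl chains per molecule for the per-chain area variant (cardiolipin has 4)
_CHAINS = {"CL": 4, "CHOL": 0}


def chains_per_molecule(feature_class: str) -> int:
    return _CHAINS.get(feature_class, 2)


def featurize(composition: Mapping[str, float]) -> np.ndarray:
    """Normalised molar fraction vector over the feature classes.

    ``composition`` maps molecule names to counts or fractions; water and
    ions are ignored, and any other molecule outside the known classes
    raises a :class:`FeaturizationError` naming it.
    """
    totals = dict.fromkeys(FEATURE_CLASSES, 0.0)
    for name, amount in composition.items():
        if name in _IGNORED:
            continue
        cls = _CLASS_OF.get(name)
        if cls is None:
            raise FeaturizationError(
                f"molecule {name!r} has no composition feature class"
            )
        if amount < 0:
            raise FeaturizationError(f"negative amount for {name!r}")
        totals[cls] += float(amount)
    total = sum(totals.values())
    if total <= 0:
        raise FeaturizationError("composition contains no membrane molecules")
    return np.array([totals[c] / total for c in FEATURE_CLASSES])


def composition_from_string(text: str) -> dict[str, float]:
    """Parse 'POPC:37,POPE:31,CL:22,...' into a composition mapping."""
    out: dict[str, float] = {}
    for token in text.split(","):
        name, _, amount = token.partition(":")
        if not amount:
            raise UsageError(f"malformed composition token {token!r}")
        out[name.strip()] = float(amount)
    return out


_FAMILIES = {
    "linear": (LinearRegression, {}),
    "ridge": (Ridge, {"alpha": np.logspace(-3, 3, 13)}),
    "lasso": (Lasso, {"alpha": np.logspace(-4, 1, 11)}),
    "elastic-net": (
        ElasticNet,
        {"alpha": np.logspace(-4, 1, 6), "l1_ratio": [0.2, 0.5, 0.8]},
    ),
    "tree": (DecisionTreeRegressor, {"max_depth": [2, 4, 8, None]}),
    "forest": (RandomForestRegressor, {"n_estimators": [50, 200]}),
    "kNN": (KNeighborsRegressor, {"n_neighbors": [3, 5, 9]}),
    "boosting": (GradientBoostingRegressor, {"n_estimators": [50, 200]}),
}


@dataclass
class TrainedPropertyModel:
    """A fitted composition -> property regressor with its training metadata."""

    family: str
    target: str  # "apl" (A^2) or "thickness" (nm)
    estimator: object
    seed: int
    cv_folds: int = 5
    best_params: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)  # test-split metrics

    def predict(self, composition: Mapping[str, float]) -> float:
        x = featurize(composition)[None, :]
        return float(self.estimator.predict(x)[0])


def train_model(
    dataset: pd.DataFrame,
    target: str,
    family: str = "linear",
    seed: int = 0,
    *,
    fit_on: str = "full",
    cv_folds: int = 5,
    test_fraction: float = 0.2,
) -> TrainedPropertyModel:
    """Train a composition -> property regressor.

    ``dataset`` must carry one column per feature class plus the target
    column.  The data are split 80/20 by ``seed``; hyperparameters are
    chosen by 5-fold cross-validated grid search on the training split, and
    test-split RMSE/R^2 are recorded.  ``fit_on`` selects whether the final
    estimator is refitted on the full dataset ("full", default) or kept as
    fitted on the training split ("train").
    """
    if family not in _FAMILIES:
        raise UsageError(
            f"unsupported model family {family!r}; available: {sorted(_FAMILIES)}"
        )
    if fit_on not in ("full", "train"):
        raise UsageError("fit_on must be 'full' or 'train'")
    missing = [c for c in FEATURE_CLASSES if c not in dataset.columns]
    if missing or target not in dataset.columns:
        raise InputError(f"dataset lacks columns: {missing + [target]}")
    if len(dataset) < 10:
        raise InputError("at least 10 rows are required to train a model")

    X = dataset[list(FEATURE_CLASSES)].to_numpy(dtype=float)
    y = dataset[target].to_numpy(dtype=float)
    X_train, X_test, y_train, y_test = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )

    cls, grid = _FAMILIES[family]
    kwargs = {"random_state": seed} if "random_state" in cls().get_params() else {}
    if grid:
        cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        search = GridSearchCV(cls(**kwargs), grid, cv=cv, scoring="neg_mean_squared_error")
        search.fit(X_train, y_train)
        estimator = search.best_estimator_
        best_params = search.best_params_
    else:
        estimator = cls(**kwargs).fit(X_train, y_train)
        best_params = {}

    y_pred = estimator.predict(X_test)
    metrics = {
        "rmse_test": float(np.sqrt(mean_squared_error(y_test, y_pred))),
        "r2_test": float(r2_score(y_test, y_pred)) if len(y_test) > 1 else np.nan,
        "n_train": len(y_train),
        "n_test": len(y_test),
    }
    if fit_on == "full":
        estimator = type(estimator)(**estimator.get_params()).fit(X, y)
    return TrainedPropertyModel(
        family=family,
        target=target,
        estimator=estimator,
        seed=seed,
        cv_folds=cv_folds,
        best_params=best_params,
        metrics=metrics,
    )


def predict_properties(
    models: Mapping[str, TrainedPropertyModel],
    composition: Mapping[str, float],
) -> dict[str, float]:
    """Point predictions for one composition from trained models.

    ``models`` maps target name ("apl", "thickness") to its model.  For
    cardiolipin-containing systems an auxiliary per-two-chain area is added:
    the predicted molecular area rescaled by 2 / (mean chains per molecule),
    since cardiolipin carries four acyl chains.
    """
    out = {target: model.predict(composition) for target, model in models.items()}
    if "apl" in out:
        frac = featurize(composition)
        mean_chains = float(
            sum(f * chains_per_molecule(c) for f, c in zip(frac, FEATURE_CLASSES))
        )
        cl_fraction = frac[FEATURE_CLASSES.index("CL")]
        if cl_fraction > 0 and mean_chains > 0:
            out["apl_per_chain_pair"] = out["apl"] * 2.0 / mean_chains
    return out


def evaluate_against_reference(
    model: TrainedPropertyModel,
    reference: pd.DataFrame,
    value_column: str = "value",
) -> dict:
    """Compare model predictions with an external reference table.

    ``reference`` needs the feature-class columns and a value column (plus
    an optional error column, passed through for plotting).  Returns per-row
    residuals, RMSE and the Pearson correlation, the quantities shown in
    prediction-versus-literature scatter plots.
    """
    X = reference[list(FEATURE_CLASSES)].to_numpy(dtype=float)
    y = reference[value_column].to_numpy(dtype=float)
    pred = model.estimator.predict(X)
    residuals = y - pred
    corr = float(np.corrcoef(pred, y)[0, 1]) if len(y) > 1 and np.std(pred) > 0 else np.nan
    return {
        "predicted": pred,
        "observed": y,
        "residuals": residuals,
        "rmse": float(np.sqrt(np.mean(residuals**2))),
        "pearson_r": corr,
    }
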