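"""Scikit-learn-style estimator for the eGL (estimated glycemic load) model.

The eGL score predicts the glycemic load of a serving from its nutrient
label alone:

    eGL = a + b*(carbohydrate - fiber) - c*fat - d*protein**2 - e*fiber**2

with all nutrients in grams per serving.  The model is linear in the
transformed features ``(carb - fiber, -fat, -protein**2, -fiber**2)``, so the
five constants ``a..e`` are recovered by ordinary least squares from any
table of foods with known (or published) glycemic-load scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["EglCoefficients", "EstimatedGlycemicLoad", "NUTRIENT_COLUMNS"]

#: Expected feature order when fitting/predicting from a plain array.
NUTRIENT_COLUMNS = ("carbohydrate_g", "fiber_g", "protein_g", "fat_g")


@dataclass(frozen=True)
class EglCoefficients:
    """The five constants of the eGL equation.

    ``a`` is the intercept in GL units; ``b`` weights available carbohydrate
    (g); ``c`` penalises fat (g); ``d`` and ``e`` are quadratic penalties on
    protein and fiber (per g**2).  ``b`` must be positive: carbohydrate is
    what raises the predicted load.
    """

    a: float
    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        vals = (self.a, self.b, self.c, self.d, self.e)
        if not all(np.isfinite(vals)):
            raise ValueError("eGL coefficients must be finite")
        if self.b <= 0:
            raise ValueError("carbohydrate weight b must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.e], dtype=float)


def _design_matrix(X: np.ndarray) -> np.ndarray:
    carb, fiber, protein, fat = (X[:, i] for i in range(4))
    return np.column_stack(
        [np.ones(len(X)), carb - fiber, -fat, -(protein**2), -(fiber**2)]
    )


def _coerce_nutrients(X) -> np.ndarray:
    """Accept a DataFrame with nutrient columns or an (n, 4) array in
    ``NUTRIENT_COLUMNS`` order."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in NUTRIENT_COLUMNS if c not in X.columns]
        if missing:
            raise ValueError(f"missing nutrient columns: {missing}")
        X = X.loc[:, list(NUTRIENT_COLUMNS)].to_numpy(dtype=float)
    return X


class EstimatedGlycemicLoad(RegressorMixin, BaseEstimator):
    """Predict glycemic load per serving from a nutrient label.

    Parameters
    ----------
    coefficients : EglCoefficients, optional
        Preset model constants.  When given, :meth:`fit` adopts them without
        estimating; when ``None`` (default) the constants are recovered by
        ordinary least squares on the training foods.

    Attributes
    ----------
    coefficients_ : EglCoefficients
        Fitted (or adopted) model constants.
    coef_ : ndarray of shape (5,)
        The same constants as a flat array ``[a, b, c, d, e]``.

    Examples
    --------
    >>> from glyload.data import load_fixture_table4
    >>> import pandas as pd
    >>> foods, summaries = zip(*load_fixture_table4())
    >>> X = pd.DataFrame({c: [getattr(f, c) for f in foods]
    ...                   for c in NUTRIENT_COLUMNS})
    >>> y = [s.egl for s in summaries]
    >>> model = EstimatedGlycemicLoad().fit(X, y)
    >>> round(float(model.predict(X.iloc[[1]])[0]))  # sponge cake
    13
    """

    def __init__(self, coefficients: EglCoefficients | None = None):
        self.coefficients = coefficients

    def fit(self, X, y=None):
        """Fit the eGL constants by OLS of ``y`` (GL scores) on the
        transformed nutrient features.

        ``X`` is (n, 4): carbohydrate, fiber, protein, fat in grams per
        serving (or a DataFrame with those columns).  Requires at least five
        foods with a full-rank design; raises ``ValueError`` otherwise.
        """
        if self.coefficients is not None:
            X = check_array(_coerce_nutrients(X), ensure_min_samples=1)
            self._check_width(X)
            self.coefficients_ = self.coefficients
            self.coef_ = self.coefficients_.as_array()
            self.n_features_in_ = 4
            return self
        if y is None:
            raise ValueError("y (glycemic-load targets) required to fit coefficients")
        X, y = check_X_y(_coerce_nutrients(X), y, y_numeric=True)
        self._check_width(X)
        D = _design_matrix(X)
        rank = np.linalg.matrix_rank(D)
        if len(X) < 5 or rank < 5:
            raise ValueError(
                f"need >= 5 foods with distinct nutrient profiles to identify "
                f"5 coefficients (n={len(X)}, design rank={rank})"
            )
        beta, *_ = np.linalg.lstsq(D, y, rcond=None)
        self.coefficients_ = EglCoefficients(*(float(b) for b in beta))
        self.coef_ = self.coefficients_.as_array()
        self.n_features_in_ = 4
        return self

    def predict(self, X) -> np.ndarray:
        """Predicted eGL for each food (same scale and units as GL)."""
        check_is_fitted(self, "coefficients_")
        X = check_array(_coerce_nutrients(X))
        self._check_width(X)
        return _design_matrix(X) @ self.coef_

    @staticmethod
    def _check_width(X: np.ndarray) -> None:
        if X.shape[1] != 4:
            raise ValueError(
                f"X must have 4 nutrient columns {NUTRIENT_COLUMNS}, got {X.shape[1]}"
            )
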