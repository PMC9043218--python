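"""Comparison classifiers: multinomial logistic regression and a decision tree.

Both expose ``category_probabilities`` over the same 5-level causality space
as the ordinal model, so all three run through the identical evaluation
path.  The multinomial baseline is a softmax-linear model with a
configurable reference category (default 4, "probable/likely"); changing the
reference reparameterizes the coefficients but leaves fitted probabilities
unchanged.  The tree is an axis-aligned CART classifier (Gini impurity, no
depth limit, minimum leaf size 1 by default) whose leaf class frequencies
serve as probabilities.
"""

from __future__ import annotations

import numpy as np
from sklearn.tree import DecisionTreeClassifier
from statsmodels.discrete.discrete_model import MNLogit

from .schema import PREDICTOR_COLUMNS, ReportTable

__all__ = ["MultinomialBaseline", "DecisionTreeBaseline", "fit_multinomial", "fit_tree"]


class _Baseline:
    kind: str

    def _expand(self, probs: np.ndarray, classes: np.ndarray) -> np.ndarray:
        """Place class-ordered probabilities into the fixed 1..5 space."""
        out = np.zeros((probs.shape[0], 5))
        out[:, classes.astype(int) - 1] = probs
        return out

    def predict_category(self, X) -> np.ndarray:
        probs = np.atleast_2d(self.category_probabilities(X))
        best = probs.max(axis=1, keepdims=True)
        return np.argmax(probs >= best - 1e-12, axis=1) + 1


class MultinomialBaseline(_Baseline):
    """Softmax-linear (multinomial logit) classifier over the 11 predictors."""

    kind = "multinomial_logit"

    def __init__(self, baseline_category: int = 4):
        self.baseline_category = int(baseline_category)
        self._fit = None
        self._classes = None

    def fit(self, data: ReportTable) -> "MultinomialBaseline":
        y = data.labels()
        classes = np.unique(y)
        if self.baseline_category not in classes:
            raise ValueError(
                f"baseline category {self.baseline_category} absent from training labels"
            )
        # reorder so the chosen reference category is the omitted first level
        order = np.concatenate(
            [[self.baseline_category], classes[classes != self.baseline_category]]
        )
        self._classes = order
        recode = {int(c): i for i, c in enumerate(order)}
        y_idx = np.array([recode[int(v)] for v in y])
        X = np.column_stack([np.ones(len(y)), data.predictors()])
        self._fit = MNLogit(y_idx, X).fit(
            method="lbfgs", maxiter=2000, maxfun=10000,
            pgtol=1e-10, factr=10.0, disp=False,
        )
        return self

    @property
    def coefficients(self) -> np.ndarray:
        """(p+1) x (k-1) coefficient matrix relative to the reference class."""
        return np.asarray(self._fit.params)

    def category_probabilities(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Xd = np.column_stack([np.ones(len(X)), X])
        probs = np.asarray(self._fit.predict(Xd))
        return self._expand(probs, self._classes)


class DecisionTreeBaseline(_Baseline):
    """CART classification tree over the Boolean predictors."""

    kind = "decision_tree"

    def __init__(self, criterion: str = "gini", max_depth: int | None = None,
                 min_samples_leaf: int = 1, seed: int = 0):
        self.hyperparameters = dict(
            criterion=criterion, max_depth=max_depth,
            min_samples_leaf=min_samples_leaf, seed=seed,
        )
        self._tree = DecisionTreeClassifier(
            criterion=criterion, max_depth=max_depth,
            min_samples_leaf=min_samples_leaf, random_state=seed,
        )

    def fit(self, data: ReportTable) -> "DecisionTreeBaseline":
        self._tree.fit(data.predictors(), data.labels())
        return self

    @property
    def depth(self) -> int:
        return int(self._tree.get_depth())

    def category_probabilities(self, X) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        probs = self._tree.predict_proba(X)
        return self._expand(probs, self._tree.classes_)


def fit_multinomial(data: ReportTable, baseline_category: int = 4) -> MultinomialBaseline:
    """Fit the multinomial-logit baseline with the given reference category."""
    return MultinomialBaseline(baseline_category).fit(data)


def fit_tree(data: ReportTable, **hyperparameters) -> DecisionTreeBaseline:
    """Fit the decision-tree baseline (deterministic given data + options)."""
    return DecisionTreeBaseline(**hyperparameters).fit(data)
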