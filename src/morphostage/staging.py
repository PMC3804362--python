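"""Normal/abnormal classification and cirrhosis stage estimation.

Two predictors operate on selected mode coefficients:

* nearest-neighbour two-class classification (normal = 0, abnormal = 1);
* epsilon-support-vector regression with a Gaussian kernel mapping the
  coefficient vector b to a continuous stage score anchored at the labels
  0 (normal), 1 (early), 2 (middle/late).

The SVR primal is

    minimize 1/2 |w|^2 + C sum_i (xi_i + xi_i*)

subject to the +-epsilon tube constraints; the kernelized dual is solved
(through libsvm) for alpha_i, alpha_i* in [0, C] with
sum_i (alpha_i - alpha_i*) = 0, and prediction follows

    f(b) = sum_i (alpha_i - alpha_i*) k(b_i, b) + a.

``StageRegression`` / ``StageRegressionResults`` follow the model/results
idiom; ``train_svr`` and ``predict_stage`` are functional wrappers.
Features are standardized on the training fold by default (recorded in
the results for test-time reuse).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

STAGE_LABELS = (0, 1, 2)


@dataclass
class SVRModel:
    """Dual-form Gaussian-kernel epsilon-SVR solution.

    ``dual_coeffs`` holds beta_i = alpha_i - alpha_i* for every training
    sample (zeros for non-support samples); ``support_inputs`` are the
    (standardized) training feature vectors.
    """

    dual_coeffs: np.ndarray
    bias: float
    gamma: float
    box_constraint: float
    tube: float
    support_inputs: np.ndarray
    targets: np.ndarray
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def kernel(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Gaussian kernel k(a, b) = exp(-gamma |a - b|^2), row-wise."""
        a = np.atleast_2d(a)
        b = np.atleast_2d(b)
        d2 = np.sum(a ** 2, axis=1)[:, None] + np.sum(b ** 2, axis=1)[None] - 2 * a @ b.T
        return np.exp(-self.gamma * np.maximum(d2, 0.0))

    def decision_function(self, features: np.ndarray) -> np.ndarray:
        """f(b) = sum_i beta_i k(b_i, b) + a on standardized features."""
        return self.kernel(np.atleast_2d(features), self.support_inputs) @ self.dual_coeffs + self.bias

    def dual_objective(self) -> float:
        """Value of the dual objective at the stored solution."""
        beta = self.dual_coeffs
        k = self.kernel(self.support_inputs, self.support_inputs)
        alpha_sum = np.abs(beta)  # alpha_i + alpha_i* (complementarity: one of them is 0)
        return float(-0.5 * beta @ k @ beta - self.tube * alpha_sum.sum() + self.targets @ beta)

    def kkt_violation(self) -> float:
        """Max violation of the dual feasibility/KKT system.

        Checks sum(beta) = 0, |beta| <= C, and the gradient conditions:
        free support vectors (0 < |beta| < C) must sit on the tube
        boundary, interior samples inside the tube, bound ones outside.
        """
        beta = self.dual_coeffs
        c = self.box_constraint
        resid = self.decision_function(self.support_inputs) - self.targets
        viol = [abs(beta.sum()), float(np.maximum(np.abs(beta) - c, 0.0).max())]
        free = (np.abs(beta) > 1e-8 * c) & (np.abs(beta) < c * (1 - 1e-8))
        if free.any():
            viol.append(float(np.abs(np.abs(resid[free]) - self.tube).max()))
        zero = np.abs(beta) <= 1e-8 * c
        if zero.any():
            viol.append(float(np.maximum(np.abs(resid[zero]) - self.tube, 0.0).max()))
        at_bound = np.abs(beta) >= c * (1 - 1e-8)
        if at_bound.any():
            viol.append(float(np.maximum(self.tube - np.abs(resid[at_bound]), 0.0).max()))
        return max(viol)


@dataclass
class StagePrediction:
    """Continuous stage score and its nearest hard label."""

    score: float
    hard_stage: int
    subject_id: str = ""


class StageRegression:
    """Epsilon-SVR stage model over selected mode coefficients.

    Parameters
    ----------
    features : (N, d) matrix of selected-mode coefficients.
    targets : stage labels in {0, 1, 2} (continuous targets accepted).
    C, epsilon : SVR box constraint and tube half-width.
    gamma : Gaussian kernel width; default 1 / (d * var(features)) on the
        standardized training matrix.
    standardize : zero-mean/unit-variance feature scaling on the training
        fold, stored for prediction.
    """

    def __init__(self, features, targets, C: float = 10.0, epsilon: float = 0.1,
                 gamma: float | None = None, standardize: bool = True):
        self.features = np.atleast_2d(np.asarray(features, dtype=float))
        self.targets = np.asarray(targets, dtype=float).ravel()
        if len(self.features) != len(self.targets):
            raise ValueError("features and targets must have equal length")
        if len(self.targets) < 2:
            raise ValueError("at least 2 training samples are required")
        if C <= 0 or epsilon < 0 or (gamma is not None and gamma <= 0):
            raise ValueError("require C > 0, epsilon >= 0, gamma > 0")
        self.C, self.epsilon, self.gamma = float(C), float(epsilon), gamma
        self.standardize = standardize

    def fit(self, tol: float = 1e-8) -> "StageRegressionResults":
        from sklearn.svm import SVR

        x = self.features
        if self.standardize:
            mean = x.mean(axis=0)
            scale = x.std(axis=0)
            scale = np.where(scale > 0, scale, 1.0)
        else:
            mean = np.zeros(x.shape[1])
            scale = np.ones(x.shape[1])
        xs = (x - mean) / scale
        var = xs.var()
        gamma = self.gamma if self.gamma is not None else 1.0 / (x.shape[1] * var) if var > 0 else 1.0
        svr = SVR(kernel="rbf", C=self.C, epsilon=self.epsilon, gamma=gamma, tol=tol,
                  max_iter=-1)
        svr.fit(xs, self.targets)
        beta = np.zeros(len(xs))
        beta[svr.support_] = svr.dual_coef_.ravel()
        model = SVRModel(dual_coeffs=beta, bias=float(svr.intercept_[0]), gamma=gamma,
                         box_constraint=self.C, tube=self.epsilon, support_inputs=xs,
                         targets=self.targets, feature_mean=mean, feature_scale=scale)
        return StageRegressionResults(model)


@dataclass
class StageRegressionResults:
    """Fitted stage regression; prediction and diagnostics."""

    model: SVRModel

    def predict_score(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != self.model.support_inputs.shape[1]:
            raise ValueError("feature length does not match training")
        xs = (features - self.model.feature_mean) / self.model.feature_scale
        return self.model.decision_function(xs)

    def predict(self, features: np.ndarray, subject_ids=None) -> list[StagePrediction]:
        scores = self.predict_score(features)
        subject_ids = subject_ids or [""] * len(scores)
        out = []
        for s, sid in zip(scores, subject_ids):
            hard = min(STAGE_LABELS, key=lambda lab: (abs(s - lab), lab))
            out.append(StagePrediction(score=float(s), hard_stage=int(hard), subject_id=sid))
        return out

    def summary(self) -> str:
        m = self.model
        n_sv = int(np.sum(np.abs(m.dual_coeffs) > 1e-12))
        return "\n".join([
            "Epsilon-SVR stage model (Gaussian kernel)",
            f"N = {len(m.dual_coeffs)} training samples, {n_sv} support vectors",
            f"C = {m.box_constraint:g}, epsilon = {m.tube:g}, gamma = {m.gamma:.6g}",
            f"bias a = {m.bias:.6g}; sum(alpha - alpha*) = {m.dual_coeffs.sum():.2e}",
            f"dual objective = {m.dual_objective():.6g}; KKT violation = {m.kkt_violation():.2e}",
        ])


def train_svr(features, targets, C: float = 10.0, epsilon: float = 0.1,
              gamma: float | None = None, standardize: bool = True) -> StageRegressionResults:
    """Fit an epsilon-SVR stage model (functional wrapper)."""
    return StageRegression(features, targets, C=C, epsilon=epsilon, gamma=gamma,
                           standardize=standardize).fit()


def predict_stage(results: StageRegressionResults, b, subject_id: str = "") -> StagePrediction:
    """Stage score and hard label for one coefficient vector."""
    return results.predict(np.atleast_2d(b), [subject_id])[0]


def classify_nn(train_features, train_labels, test_feature) -> int:
    """Label of the Euclidean-nearest training sample (ties: smallest index)."""
    train_features = np.atleast_2d(np.asarray(train_features, dtype=float))
    train_labels = np.asarray(train_labels)
    if len(train_features) == 0:
        raise ValueError("empty training set")
    if len(train_features) != len(train_labels):
        raise ValueError("features and labels must have equal length")
    d = np.linalg.norm(train_features - np.asarray(test_feature, dtype=float), axis=1)
    return int(train_labels[int(np.argmin(d))])  # argmin takes the first (smallest) index on ties
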