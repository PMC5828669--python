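"""Weighted combination forecasting for force-sensor calibration.

A pressure sensor reports five voltage channels whose relation to the true
force drifts nonlinearly with temperature and interference.  The correction
model is a two-stage ensemble: several base regressors are fitted on
voltage -> force calibration samples; each base model i receives a weight

    omega_i = (1/E_i) / Sum_k (1/E_k),

where E_i is its summed relative prediction error on the training samples;
a combiner regressor is then fitted on the weight-scaled base predictions
(omega_i * X_ij as inputs, true forces as outputs).  Base learners are
pluggable; stock choices are a polynomial ridge fit, an epsilon-SVR, and a
kernel ridge (least-squares kernel machine).  Inputs and outputs are
min-max normalized inside each stage and the scaling is inverted at predict
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.kernel_ridge import KernelRidge
from sklearn.linear_model import Ridge
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import PolynomialFeatures
from sklearn.svm import SVR

__all__ = ["GRAMS_TO_NEWTON", "base_regressor", "WeightedSumCombiner", "compute_weights",
           "EnsembleModel", "train_ensemble", "correct_forces", "error_metrics", "train_test_split_indices"]

#: grams -> Newton conversion used for reporting (g = 9.8 m/s^2).
GRAMS_TO_NEWTON = 9.8e-3


def base_regressor(name: str):
    """Stock learners by short name.

    'poly' (cubic ridge fit), 'svr' (RBF epsilon-SVR), 'kernel-ridge'
    (RBF least-squares kernel machine) serve as base models; 'svr-linear'
    is the stock second-stage combiner — the combination of base
    predictions is linear by construction, so the SVM combiner uses a
    linear kernel.
    """
    if name == "poly":
        return make_pipeline(PolynomialFeatures(degree=3), Ridge(alpha=1e-6))
    if name == "svr":
        return SVR(kernel="rbf", C=100.0, epsilon=1e-3, gamma="scale")
    if name == "svr-linear":
        return SVR(kernel="linear", C=1e3, epsilon=1e-4)
    if name == "kernel-ridge":
        return KernelRidge(kernel="rbf", alpha=1e-4, gamma=1.0)
    raise ValueError(f"unknown base regressor {name!r}")


class WeightedSumCombiner:
    """Combiner that simply sums its (already weight-scaled) inputs.

    With a single base model (weight 1) the ensemble then reproduces that
    base model exactly — the classical unweighted combination limit.
    """

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.asarray(X).sum(axis=1)


class _MinMax:
    """Column-wise min-max normalization to [0, 1], invertible."""

    def fit(self, X: np.ndarray) -> "_MinMax":
        X = np.atleast_2d(X)
        self.lo = X.min(axis=0)
        span = X.max(axis=0) - self.lo
        if np.any(span == 0):
            raise ValueError("constant column; cannot min-max normalize")
        self.span = span
        return self

    def transform(self, X):
        return (np.atleast_2d(X) - self.lo) / self.span

    def inverse(self, Xn):
        return np.atleast_2d(Xn) * self.span + self.lo


def compute_weights(base_predictions: np.ndarray, actuals: np.ndarray) -> np.ndarray:
    """Inverse-relative-error weights, one per base model.

    ``base_predictions`` is (m, n): model i's predictions of the n training
    samples.  E_i = Sum_j |(pred_ij - y_j) / y_j|; omega_i proportional to
    1/E_i, normalized to sum to 1.  A model with E_i = 0 (perfect fit) takes
    all the weight.
    """
    P = np.atleast_2d(np.asarray(base_predictions, dtype=float))
    y = np.asarray(actuals, dtype=float)
    if np.any(y == 0):
        raise ValueError("relative error undefined: some actual values are zero")
    E = np.abs((P - y[None, :]) / y[None, :]).sum(axis=1)
    if np.any(E == 0):
        import warnings

        warnings.warn("a base model fits the training data exactly; it receives full weight")
        w = (E == 0).astype(float)
        return w / w.sum()
    inv = 1.0 / E
    return inv / inv.sum()


@dataclass
class EnsembleModel:
    """Fitted two-stage weighted-combination model."""

    base_models: list
    weights: np.ndarray
    combiner: object
    in_scale: _MinMax
    out_scale: _MinMax
    comb_in_scale: _MinMax | None
    meta: dict = field(default_factory=dict)

    def _base_matrix(self, voltages: np.ndarray) -> np.ndarray:
        Xn = self.in_scale.transform(voltages)
        preds_n = np.column_stack([m.predict(Xn) for m in self.base_models])
        return self.out_scale.inverse(preds_n.T).T if preds_n.ndim == 2 else preds_n

    def predict(self, voltages: np.ndarray) -> np.ndarray:
        voltages = np.atleast_2d(np.asarray(voltages, dtype=float))
        base = self._base_matrix(voltages)                    # (n, m) in Newton
        Z = base * self.weights[None, :]
        if isinstance(self.combiner, WeightedSumCombiner):
            return self.combiner.predict(Z)
        Zn = self.comb_in_scale.transform(Z)
        out_n = self.combiner.predict(Zn)
        return self.out_scale.inverse(out_n[:, None]).ravel()


def train_ensemble(
    voltages: np.ndarray,
    forces: np.ndarray,
    base_names=("poly", "svr", "kernel-ridge"),
    combiner="svr-linear",
    seed: int = 0,
) -> EnsembleModel:
    """Fit base models, inverse-relative-error weights, and the combiner.

    ``forces`` are the reference forces in Newton.  Deterministic given the
    seed (the stock learners are themselves deterministic; the seed is kept
    for pluggable stochastic learners and recorded in ``meta``).
    """
    X = np.atleast_2d(np.asarray(voltages, dtype=float))
    y = np.asarray(forces, dtype=float)
    if X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("need >= 2 samples with matching voltage/force counts")
    if not base_names:
        raise ValueError("need at least one base model")

    in_scale = _MinMax().fit(X)
    out_scale = _MinMax().fit(y[:, None])
    Xn = in_scale.transform(X)
    yn = out_scale.transform(y[:, None]).ravel()

    models = []
    for spec in base_names:
        m = base_regressor(spec) if isinstance(spec, str) else clone(spec)
        if hasattr(m, "random_state"):
            m.random_state = seed
        models.append(m.fit(Xn, yn))

    preds_n = np.vstack([m.predict(Xn) for m in models])          # (m, n)
    preds = out_scale.inverse(preds_n.T).T                        # Newton
    weights = compute_weights(preds, y)

    comb = WeightedSumCombiner() if combiner in ("sum", "identity") else (
        base_regressor(combiner) if isinstance(combiner, str) else clone(combiner)
    )
    Z = preds.T * weights[None, :]
    comb_in_scale = None
    if isinstance(comb, WeightedSumCombiner):
        comb.fit(Z, y)
    else:
        comb_in_scale = _MinMax().fit(Z)
        comb.fit(comb_in_scale.transform(Z), yn)
    return EnsembleModel(base_models=models, weights=weights, combiner=comb,
                         in_scale=in_scale, out_scale=out_scale,
                         comb_in_scale=comb_in_scale,
                         meta={"bases": list(base_names), "combiner": str(combiner), "seed": seed})


def correct_forces(model: EnsembleModel, voltages: np.ndarray) -> np.ndarray:
    """Corrected forces (Newton) for raw sensor voltages."""
    if not getattr(model, "base_models", None):
        raise ValueError("model is not fitted")
    return model.predict(voltages)


def error_metrics(actual: np.ndarray, corrected: np.ndarray) -> tuple[float, float, float]:
    """(MAE, MSE, MAPE%): mean |err|, mean squared err, mean |relative err| x 100.

    MSE is the plain mean of squared errors.  MAPE requires nonzero actuals
    and is reported in percent.
    """
    a = np.asarray(actual, dtype=float)
    c = np.asarray(corrected, dtype=float)
    if a.shape != c.shape:
        raise ValueError("actual and corrected lengths differ")
    if np.any(a == 0):
        raise ValueError("MAPE undefined: some actual values are zero")
    err = c - a
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    mape = float(np.mean(np.abs(err / a)) * 100.0)
    return mae, mse, mape


def train_test_split_indices(n: int, n_test: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Seeded disjoint train/test index split (default protocol: 70/6)."""
    if not (0 < n_test < n):
        raise ValueError(f"need 0 < n_test < n; got n={n}, n_test={n_test}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return np.sort(perm[n_test:]), np.sort(perm[:n_test])
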