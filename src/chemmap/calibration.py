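"""MLP calibration models for per-ROI chemistry prediction.

The reference table is split into a held-out validation set (two whole
fruit per origin, all their ROIs), a calibration set (65% of all rows) and
a cross-validation set (15%) used for early stopping and model comparison.
A small multilayer perceptron (one hidden layer of four tangent-sigmoid
neurons, linear output) is trained by full-batch Levenberg-Marquardt on
z-scored inputs/targets; twenty replicate trainings per candidate
wavelength set decide which set wins.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .synthetic import COLUMN_OF

STAGES = ("calibration", "cross_validation", "validation")


# --------------------------------------------------------------------------
# partitioning
# --------------------------------------------------------------------------

@dataclass
class PartitionPlan:
    """Row assignments for the three modelling stages."""

    validation_fruit: dict[int, list[int]]        # origin -> held-out fruit ids
    assignments: dict[str, np.ndarray]            # stage -> positional row indices
    seed: int

    def rows(self, stage: str) -> np.ndarray:
        return self.assignments[stage]


def partition_dataset(ref: pd.DataFrame, seed: int = 0,
                      validation_fruit_per_origin: int = 2,
                      calibration_frac: float = 0.65,
                      cross_validation_frac: float = 0.15) -> PartitionPlan:
    """Partition a full-factorial reference table.

    Per origin, ``validation_fruit_per_origin`` fruit are drawn at random
    and all their ROIs form the validation set.  The remaining rows are
    shuffled and split into calibration (``calibration_frac`` of the
    *total* row count) and cross-validation (``cross_validation_frac`` of
    the total); at the study scale of 600 rows this gives 120/390/90.

    Raises if an origin has too few fruit or if the fractions do not
    exactly exhaust the non-validation rows.
    """
    rng = np.random.default_rng(seed)
    n_total = len(ref)
    validation_fruit: dict[int, list[int]] = {}
    val_mask = np.zeros(n_total, dtype=bool)
    for origin, grp in ref.groupby("origin"):
        fruit_ids = sorted(grp["fruit"].unique())
        if len(fruit_ids) <= validation_fruit_per_origin:
            raise ValueError(
                f"origin {origin} has {len(fruit_ids)} fruit; needs more than "
                f"{validation_fruit_per_origin} to hold some out"
            )
        held = sorted(rng.choice(fruit_ids, validation_fruit_per_origin, replace=False))
        validation_fruit[int(origin)] = [int(f) for f in held]
        val_mask |= (ref["origin"] == origin).to_numpy() & ref["fruit"].isin(held).to_numpy()

    val_idx = np.where(val_mask)[0]
    rest_idx = np.where(~val_mask)[0]
    n_cal = round(calibration_frac * n_total)
    n_cv = round(cross_validation_frac * n_total)
    if n_cal + n_cv != len(rest_idx):
        raise ValueError(
            f"fractions {calibration_frac}/{cross_validation_frac} of {n_total} rows "
            f"give {n_cal}+{n_cv} but {len(rest_idx)} rows remain after holding out "
            "validation fruit; use a design with matching proportions or pass "
            "explicit fractions"
        )
    shuffled = rng.permutation(rest_idx)
    return PartitionPlan(
        validation_fruit=validation_fruit,
        assignments={
            "validation": np.sort(val_idx),
            "calibration": np.sort(shuffled[:n_cal]),
            "cross_validation": np.sort(shuffled[n_cal:]),
        },
        seed=seed,
    )


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def regression_metrics(y_true, y_pred) -> dict:
    """R (Pearson), RMSE (target units) and MAPE (%) of predictions."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if np.any(y_true == 0):
        raise ValueError("target contains zeros; MAPE is undefined")
    err = y_pred - y_true
    rmse = float(np.sqrt(np.mean(err**2)))
    mape = float(np.mean(np.abs(err) / np.abs(y_true)) * 100.0)
    if y_true.std() == 0 or y_pred.std() == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(y_true, y_pred)[0, 1])
    return {"R": r, "RMSE": rmse, "MAPE": mape}


# --------------------------------------------------------------------------
# the MLP regressor
# --------------------------------------------------------------------------

class MLPCalibrator(BaseEstimator, RegressorMixin):
    """One-hidden-layer tanh MLP trained by full-batch Levenberg-Marquardt.

    Inputs and the target are z-scored on the training (calibration) data;
    predictions are returned in original units.  Training stops at the
    first of: training MSE (standardised) at or below ``mse_goal``,
    ``max_epochs`` accepted update steps, ``max_val_fail`` consecutive
    epochs without a new cross-validation error minimum (the
    best-cross-validation weights are restored), or the damped step failing
    to reduce the error.

    ``learning_rate`` is stored for configuration fidelity with the classic
    toolbox convention; Levenberg-Marquardt itself uses the adaptive
    damping factor ``mu``.
    """

    def __init__(self, hidden_units: int = 4, learning_rate: float = 0.3,
                 max_val_fail: int = 15, mse_goal: float = 1e-4,
                 max_epochs: int = 500, mu_init: float = 1e-3,
                 random_state: int = 0):
        self.hidden_units = hidden_units
        self.learning_rate = learning_rate
        self.max_val_fail = max_val_fail
        self.mse_goal = mse_goal
        self.max_epochs = max_epochs
        self.mu_init = mu_init
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _forward(self, theta, Xs):
        h, d = self.hidden_units, Xs.shape[1]
        W1 = theta[: h * d].reshape(h, d)
        b1 = theta[h * d : h * d + h]
        w2 = theta[h * d + h : h * d + 2 * h]
        b2 = theta[-1]
        a = np.tanh(Xs @ W1.T + b1)
        return a @ w2 + b2, a, W1, w2

    def _jacobian(self, theta, Xs):
        yhat, a, W1, w2 = self._forward(theta, Xs)
        n = Xs.shape[0]
        h = self.hidden_units
        da = (1.0 - a**2) * w2          # (n, h)
        J = np.empty((n, theta.size))
        J[:, : h * Xs.shape[1]] = (da[:, :, None] * Xs[:, None, :]).reshape(n, -1)
        J[:, h * Xs.shape[1] : h * Xs.shape[1] + h] = da
        J[:, h * Xs.shape[1] + h : h * Xs.shape[1] + 2 * h] = a
        J[:, -1] = 1.0
        return yhat, J

    def fit(self, X, y, X_val=None, y_val=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[1] < 1:
            raise ValueError("X must be 2-D with at least one input wavelength")
        n, d = X.shape

        self.x_mean_, self.x_std_ = X.mean(axis=0), X.std(axis=0)
        self.x_std_[self.x_std_ == 0] = 1.0
        self.y_mean_, self.y_std_ = y.mean(), y.std() or 1.0
        Xs = (X - self.x_mean_) / self.x_std_
        ys = (y - self.y_mean_) / self.y_std_
        if X_val is not None:
            Xvs = (np.asarray(X_val, dtype=float) - self.x_mean_) / self.x_std_
            yvs = (np.asarray(y_val, dtype=float).ravel() - self.y_mean_) / self.y_std_

        h = self.hidden_units
        rng = np.random.default_rng(self.random_state)
        theta = rng.uniform(-0.5, 0.5, size=h * d + 2 * h + 1)

        mu = self.mu_init
        yhat, _, _, _ = self._forward(theta, Xs)
        sse = float(np.sum((yhat - ys) ** 2))
        best_val, best_theta, val_fails = np.inf, theta.copy(), 0
        reason, epoch = "max_epochs", 0

        for epoch in range(1, self.max_epochs + 1):
            yhat, J = self._jacobian(theta, Xs)
            r = yhat - ys
            g = J.T @ r
            JtJ = J.T @ J
            accepted = False
            for _ in range(25):
                try:
                    step = np.linalg.solve(JtJ + mu * np.eye(theta.size), -g)
                except np.linalg.LinAlgError:
                    mu = min(mu * 10.0, 1e10)
                    continue
                cand = theta + step
                yhat_c, _, _, _ = self._forward(cand, Xs)
                sse_c = float(np.sum((yhat_c - ys) ** 2))
                if not np.isfinite(sse_c):
                    raise FloatingPointError(
                        f"non-finite training loss at epoch {epoch} "
                        f"(seed {self.random_state})"
                    )
                if sse_c < sse:
                    theta, sse = cand, sse_c
                    mu = max(mu * 0.1, 1e-12)
                    accepted = True
                    break
                mu = min(mu * 10.0, 1e10)
            if not accepted:
                reason = "step_failure"
                break

            mse = sse / n
            if X_val is not None:
                yv, _, _, _ = self._forward(theta, Xvs)
                val_mse = float(np.mean((yv - yvs) ** 2))
                if val_mse < best_val:
                    best_val, best_theta, val_fails = val_mse, theta.copy(), 0
                else:
                    val_fails += 1
                    if val_fails >= self.max_val_fail:
                        reason = "max_val_fail"
                        break
            if mse <= self.mse_goal:
                reason = "mse_goal"
                break

        if X_val is not None and np.isfinite(best_val):
            theta = best_theta
        self.theta_ = theta
        self.stopping_record_ = {
            "reason": reason,
            "epochs": epoch,
            "optimizer": "levenberg_marquardt",
            "final_mse_standardized": sse / n,
            "best_val_mse_standardized": None if X_val is None else best_val,
        }
        return self

    def predict(self, X):
        check_is_fitted(self, "theta_")
        Xs = (np.asarray(X, dtype=float) - self.x_mean_) / self.x_std_
        yhat, _, _, _ = self._forward(self.theta_, Xs)
        return yhat * self.y_std_ + self.y_mean_


# --------------------------------------------------------------------------
# replicate training and wavelength-set comparison
# --------------------------------------------------------------------------

@dataclass
class CalibrationModel:
    """A trained calibration model with its provenance and stage metrics."""

    composition: str
    wavelengths_nm: list[float]
    estimator: MLPCalibrator
    replicate_id: int
    seed: int
    metrics: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        est = self.estimator
        return json.dumps(
            {
                "composition": self.composition,
                "wavelengths_nm": self.wavelengths_nm,
                "replicate_id": self.replicate_id,
                "seed": self.seed,
                "hidden_units": est.hidden_units,
                "theta": est.theta_.tolist(),
                "x_mean": est.x_mean_.tolist(),
                "x_std": est.x_std_.tolist(),
                "y_mean": est.y_mean_,
                "y_std": est.y_std_,
                "stopping_record": est.stopping_record_,
                "metrics": self.metrics,
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "CalibrationModel":
        d = json.loads(text)
        est = MLPCalibrator(hidden_units=d["hidden_units"], random_state=d["seed"])
        est.theta_ = np.array(d["theta"])
        est.x_mean_ = np.array(d["x_mean"])
        est.x_std_ = np.array(d["x_std"])
        est.y_mean_ = d["y_mean"]
        est.y_std_ = d["y_std"]
        est.stopping_record_ = d["stopping_record"]
        return CalibrationModel(
            composition=d["composition"],
            wavelengths_nm=d["wavelengths_nm"],
            estimator=est,
            replicate_id=d["replicate_id"],
            seed=d["seed"],
            metrics=d["metrics"],
        )


def evaluate_model(model, X, y) -> dict:
    """Stage metrics {R, RMSE, MAPE} of a fitted model on (X, y)."""
    est = model.estimator if isinstance(model, CalibrationModel) else model
    return regression_metrics(y, est.predict(X))


def _replicate_seed(base_seed: int, replicate: int) -> int:
    return (base_seed * 1000003 + replicate * 7919 + 1) % (2**31 - 1)


def replicate_and_select(
    wavelength_sets: dict[str, list[float]],
    plan: PartitionPlan,
    spectra: pd.DataFrame,
    composition: str,
    grid_wavelengths=None,
    n_replicates: int = 20,
    seed: int = 0,
    hyper: dict | None = None,
):
    """Train ``n_replicates`` MLPs per candidate wavelength set and pick the winner.

    Returns ``(best_model, metrics_table)``.  The per-set table reports the
    mean and SD over replicates of R/RMSE/MAPE for the calibration and
    cross-validation stages; the winning set has the highest mean
    cross-validation R (ties: lower cross-validation RMSE, then MAPE), and
    the returned model is its best replicate by cross-validation R, with
    validation-stage metrics attached.
    """
    from .preprocess import spectra_columns

    if not wavelength_sets:
        raise ValueError("no wavelength sets to compare")
    hyper = hyper or {}
    ycol = COLUMN_OF[composition]
    y = spectra[ycol].to_numpy(dtype=float)

    rows_cal = plan.rows("calibration")
    rows_cv = plan.rows("cross_validation")
    rows_val = plan.rows("validation")

    table_rows = []
    per_set_models: dict[str, list] = {}
    for set_name, wavelengths in wavelength_sets.items():
        cols = spectra_columns(wavelengths)
        missing = [c for c in cols if c not in spectra.columns]
        if missing:
            raise KeyError(f"spectra table lacks columns {missing} for set {set_name!r}")
        X = spectra[cols].to_numpy(dtype=float)
        models = []
        stage_metrics = {s: [] for s in ("calibration", "cross_validation")}
        for rep in range(n_replicates):
            rep_seed = _replicate_seed(seed, rep)
            est = MLPCalibrator(random_state=rep_seed, **hyper)
            try:
                est.fit(X[rows_cal], y[rows_cal], X_val=X[rows_cv], y_val=y[rows_cv])
            except FloatingPointError as exc:
                warnings.warn(f"replicate {rep} of set {set_name!r} aborted: {exc}")
                continue
            m_cal = regression_metrics(y[rows_cal], est.predict(X[rows_cal]))
            m_cv = regression_metrics(y[rows_cv], est.predict(X[rows_cv]))
            stage_metrics["calibration"].append(m_cal)
            stage_metrics["cross_validation"].append(m_cv)
            models.append((rep, rep_seed, est, m_cal, m_cv))
        if not models:
            warnings.warn(f"all replicates failed for set {set_name!r}; set marked failed")
            continue
        per_set_models[set_name] = models
        row = {"set": set_name, "n_replicates": len(models),
               "wavelengths_nm": list(map(float, wavelengths))}
        for stage, tag in (("calibration", "c"), ("cross_validation", "cv")):
            for metric in ("R", "RMSE", "MAPE"):
                vals = [m[metric] for m in stage_metrics[stage]]
                row[f"{metric}_{tag}_mean"] = float(np.mean(vals))
                row[f"{metric}_{tag}_sd"] = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        table_rows.append(row)

    if not table_rows:
        raise RuntimeError("every candidate wavelength set failed to train")
    table = pd.DataFrame(table_rows)

    ranked = table.sort_values(
        by=["R_cv_mean", "RMSE_cv_mean", "MAPE_cv_mean"],
        ascending=[False, True, True],
        kind="stable",
    )
    winner = ranked.iloc[0]["set"]

    models = per_set_models[winner]
    rep, rep_seed, est, m_cal, m_cv = max(models, key=lambda t: t[4]["R"])
    cols = spectra_columns(wavelength_sets[winner])
    X = spectra[cols].to_numpy(dtype=float)
    m_val = regression_metrics(y[rows_val], est.predict(X[rows_val]))
    best = CalibrationModel(
        composition=composition,
        wavelengths_nm=list(map(float, wavelength_sets[winner])),
        estimator=est,
        replicate_id=rep,
        seed=rep_seed,
        metrics={"calibration": m_cal, "cross_validation": m_cv, "validation": m_val},
    )
    return best, table
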