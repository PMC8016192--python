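"""Frame-state classifiers: generative naive Bayes and discriminative SVM.

Two naive-Bayes variants model the per-feature class-conditional
densities — parametrically (GNB: one Gaussian per class-feature) or
nonparametrically (KNB: Gaussian kernel density over the training
values) — and classify by the posterior under independent features.
The discriminative route is a soft-margin SVM with a Gaussian radial
basis kernel exp(-||u - v||^2 / (2 sigma^2)) applied after per-feature
standardization; three named presets fix the kernel scale at 11
("coarse"), 2.8 ("medium") and 0.71 ("fine") with box constraint C = 1,
and a randomized log-uniform search tunes (sigma, C) over [1e-3, 1e3]
against 5-fold cross-validated error.

Naive-Bayes ties at posterior 0.5 resolve to the free state A, which
favors specificity.  The SVM optimization itself is delegated to
scikit-learn's libsvm binding; the fitted machine is re-expressed as
explicit support vectors, dual coefficients and bias so models serialize
to JSON and predict without scikit-learn objects.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.svm import SVC

from .featurize import FEATURE_COLUMNS, feature_array

__all__ = [
    "GNBModel", "KNBModel", "SVMModel", "SVM_PRESETS",
    "train_gnb", "train_knb", "train_svm", "predict_nb",
    "search_hyperparameters", "save_model", "load_model",
]

logger = logging.getLogger(__name__)

CLASSES = ("A", "I")
SVM_PRESETS = {"coarse": (11.0, 1.0), "medium": (2.8, 1.0),
               "fine": (0.71, 1.0)}
VARIANCE_FLOOR_REL = 1e-12  # times the squared overall feature scale


def _split_by_class(matrix: pd.DataFrame):
    if "label" not in matrix.columns:
        raise ValueError("training matrix must carry a 'label' column")
    X = feature_array(matrix)
    y = matrix["label"].to_numpy()
    present = set(np.unique(y))
    if not set(CLASSES) <= present:
        raise ValueError(f"training matrix must contain both classes "
                         f"{CLASSES}, found {sorted(present)}")
    groups = {c: X[y == c] for c in CLASSES}
    for c, Xc in groups.items():
        if len(Xc) < 2:
            raise ValueError(f"class {c} needs at least 2 training rows")
    return X, y, groups


@dataclass
class GNBModel:
    """Per-class feature means/variances + empirical class priors."""

    priors: dict[str, float]
    means: np.ndarray  # (2, 8), rows ordered as CLASSES
    variances: np.ndarray  # (2, 8)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def class_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        """(n, 2) log p(x | c), summed over independent features."""
        out = np.empty((len(X), 2))
        for ci in range(2):
            var = self.variances[ci]
            out[:, ci] = np.sum(
                -0.5 * np.log(2.0 * np.pi * var)
                - 0.5 * (X - self.means[ci]) ** 2 / var, axis=1)
        return out


@dataclass
class KNBModel:
    """Per-class per-feature Gaussian KDEs + empirical class priors."""

    priors: dict[str, float]
    train_values: dict[str, np.ndarray]  # class -> (n_c, 8)
    bandwidths: np.ndarray  # (2, 8)
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def feature_log_density(self, cls: str, j: int, x: np.ndarray
                            ) -> np.ndarray:
        """log of the KDE for one class-feature, evaluated at x."""
        ci = CLASSES.index(cls)
        v = self.train_values[cls][:, j]
        h = self.bandwidths[ci, j]
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - v[None, :]) / h
        return logsumexp(-0.5 * z * z, axis=1) \
            - np.log(len(v) * h * np.sqrt(2.0 * np.pi))

    def class_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((len(X), 2))
        for ci, cls in enumerate(CLASSES):
            for j in range(X.shape[1]):
                out[:, ci] += self.feature_log_density(cls, j, X[:, j])
        return out


def _floored_variances(groups: dict[str, np.ndarray], X: np.ndarray
                       ) -> np.ndarray:
    scale = X.std(axis=0, ddof=1)
    floor = VARIANCE_FLOOR_REL * np.maximum(scale, 1.0) ** 2
    variances = np.empty((2, X.shape[1]))
    for ci, c in enumerate(CLASSES):
        v = groups[c].var(axis=0, ddof=1)
        zero = v == 0.0
        if zero.any():
            bad = [FEATURE_COLUMNS[j] for j in np.flatnonzero(zero)]
            raise ValueError(
                f"class {c} has zero variance in features {bad}; add "
                "jitter to the inputs or drop the degenerate feature")
        low = v < floor
        if low.any():
            logger.warning("variance floor applied to class %s features %s",
                           c, np.flatnonzero(low).tolist())
            v = np.maximum(v, floor)
        variances[ci] = v
    return variances


def train_gnb(matrix: pd.DataFrame) -> GNBModel:
    """Fit per-class Gaussians by sample statistics (unbiased variance)."""
    X, y, groups = _split_by_class(matrix)
    priors = {c: float(np.mean(y == c)) for c in CLASSES}
    means = np.vstack([groups[c].mean(axis=0) for c in CLASSES])
    variances = _floored_variances(groups, X)
    return GNBModel(priors=priors, means=means, variances=variances)


def train_knb(matrix: pd.DataFrame, bandwidth_rule: str = "normal-reference",
              fixed_bandwidths: np.ndarray | None = None) -> KNBModel:
    """Fit per-class per-feature Gaussian KDEs.

    The default bandwidth is the normal-reference rule
    h = 1.06 * sd * n^(-1/5) per class-feature; ``bandwidth_rule="fixed"``
    takes an explicit (2, 8) array instead.
    """
    X, y, groups = _split_by_class(matrix)
    priors = {c: float(np.mean(y == c)) for c in CLASSES}
    if bandwidth_rule == "normal-reference":
        bw = np.empty((2, X.shape[1]))
        for ci, c in enumerate(CLASSES):
            sd = groups[c].std(axis=0, ddof=1)
            if np.any(sd == 0.0):
                bad = [FEATURE_COLUMNS[j]
                       for j in np.flatnonzero(sd == 0.0)]
                raise ValueError(
                    f"class {c} has zero spread in features {bad}; add "
                    "jitter to the inputs or drop the degenerate feature")
            bw[ci] = 1.06 * sd * len(groups[c]) ** (-0.2)
    elif bandwidth_rule == "fixed":
        if fixed_bandwidths is None:
            raise ValueError("fixed bandwidth rule needs fixed_bandwidths")
        bw = np.asarray(fixed_bandwidths, dtype=float)
        if bw.shape != (2, X.shape[1]) or np.any(bw <= 0):
            raise ValueError("fixed_bandwidths must be positive with "
                             f"shape (2, {X.shape[1]})")
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    return KNBModel(priors=priors,
                    train_values={c: groups[c].copy() for c in CLASSES},
                    bandwidths=bw)


def predict_nb(model: GNBModel | KNBModel, matrix: pd.DataFrame
               ) -> pd.DataFrame:
    """Posterior classification under the naive factorization.

    Returns a DataFrame with ``predicted`` labels and ``posterior_I``;
    posteriors are computed in log space and a tie at exactly 0.5 goes
    to A.
    """
    X = feature_array(matrix)
    if X.shape[1] != len(model.feature_names):
        raise ValueError("feature count does not match the trained schema")
    log_prior = np.log([model.priors[c] for c in CLASSES])
    log_joint = model.class_log_likelihood(X) + log_prior
    log_norm = logsumexp(log_joint, axis=1)
    posterior_i = np.exp(log_joint[:, 1] - log_norm)
    predicted = np.where(log_joint[:, 1] > log_joint[:, 0], "I", "A")
    return pd.DataFrame({"predicted": predicted, "posterior_I": posterior_i},
                        index=matrix.index)


@dataclass
class SVMModel:
    """RBF-kernel SVM in explicit form, after internal standardization."""

    sigma: float
    C: float
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    support_vectors: np.ndarray  # standardized coordinates
    dual_coef: np.ndarray  # alpha_i * y_i, y in {-1 (A), +1 (I)}
    intercept: float
    feature_names: tuple[str, ...] = FEATURE_COLUMNS
    kernel_definition: str = "exp(-||u-v||^2 / (2*sigma^2))"

    def decision_function(self, matrix: pd.DataFrame | np.ndarray
                          ) -> np.ndarray:
        X = matrix if isinstance(matrix, np.ndarray) else feature_array(matrix)
        Z = (X - self.scaler_mean) / self.scaler_sd
        d2 = (np.sum(Z * Z, axis=1)[:, None]
              + np.sum(self.support_vectors ** 2, axis=1)[None, :]
              - 2.0 * Z @ self.support_vectors.T)
        K = np.exp(-np.clip(d2, 0.0, None) / (2.0 * self.sigma ** 2))
        return K @ self.dual_coef + self.intercept

    def predict(self, matrix: pd.DataFrame | np.ndarray) -> pd.DataFrame:
        decision = self.decision_function(matrix)
        predicted = np.where(decision > 0.0, "I", "A")
        index = (matrix.index if isinstance(matrix, pd.DataFrame)
                 else pd.RangeIndex(len(decision)))
        return pd.DataFrame({"predicted": predicted, "decision": decision},
                            index=index)


def train_svm(matrix: pd.DataFrame, sigma: float | None = None,
              C: float | None = None, preset: str | None = None,
              tol: float = 1e-6, max_iter: int = -1) -> SVMModel:
    """Train the Gaussian-RBF SVM at a (sigma, C) pair or named preset."""
    if preset is not None:
        if preset not in SVM_PRESETS:
            raise ValueError(f"unknown preset {preset!r}; "
                             f"choose from {sorted(SVM_PRESETS)}")
        sigma, C = SVM_PRESETS[preset]
    if sigma is None or C is None:
        raise ValueError("provide either a preset or both sigma and C")
    if sigma <= 0 or C <= 0:
        raise ValueError("sigma and C must be positive")
    X, y, _ = _split_by_class(matrix)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    Z = (X - mean) / sd
    y_signed = np.where(y == "I", 1, -1)
    svc = SVC(kernel="rbf", gamma=1.0 / (2.0 * sigma ** 2), C=C,
              tol=tol, max_iter=max_iter, shrinking=True)
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=UserWarning)
        try:
            svc.fit(Z, y_signed)
        except UserWarning as exc:  # libsvm convergence warning
            raise RuntimeError(
                f"SVM failed to converge within the iteration cap "
                f"(sigma={sigma}, C={C}): {exc}") from exc
    return SVMModel(
        sigma=float(sigma), C=float(C), scaler_mean=mean, scaler_sd=sd,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=svc.dual_coef_.ravel().copy(),
        intercept=float(svc.intercept_[0]))


def search_hyperparameters(matrix: pd.DataFrame, n_iter: int = 15,
                           search_range: tuple[float, float] = (1e-3, 1e3),
                           k: int = 5, rng_seed: int = 0
                           ) -> tuple[float, float, pd.DataFrame]:
    """Randomized log-uniform search for (sigma, C) by 5-fold CV error.

    Returns the best pair and the full trajectory of evaluated candidates
    with their CV errors; deterministic under the seed.
    """
    from .validation import cross_validate  # local import avoids a cycle

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    lo, hi = search_range
    if not 0 < lo < hi:
        raise ValueError("search range must satisfy 0 < lo < hi")
    rng = np.random.default_rng(rng_seed)
    log_lo, log_hi = np.log10(lo), np.log10(hi)
    candidates = 10.0 ** rng.uniform(log_lo, log_hi, size=(n_iter, 2))
    records = []
    for sigma, C in candidates:
        report = cross_validate(
            matrix, lambda df: train_svm(df, sigma=sigma, C=C),
            lambda model, df: model.predict(df), k=k, rng_seed=rng_seed)
        records.append({"sigma": sigma, "C": C,
                        "cv_error": 1.0 - report.mean_q})
    trajectory = pd.DataFrame(records)
    best = trajectory["cv_error"].idxmin()
    return (float(trajectory.loc[best, "sigma"]),
            float(trajectory.loc[best, "C"]), trajectory)


# ---------------------------------------------------------------------------
# JSON serialization
# ---------------------------------------------------------------------------

def save_model(model: GNBModel | KNBModel | SVMModel, path: str | Path
               ) -> None:
    if isinstance(model, GNBModel):
        payload = {"kind": "gnb", "priors": model.priors,
                   "means": model.means.tolist(),
                   "variances": model.variances.tolist(),
                   "feature_names": list(model.feature_names)}
    elif isinstance(model, KNBModel):
        payload = {"kind": "knb", "priors": model.priors,
                   "train_values": {c: v.tolist()
                                    for c, v in model.train_values.items()},
                   "bandwidths": model.bandwidths.tolist(),
                   "feature_names": list(model.feature_names)}
    elif isinstance(model, SVMModel):
        payload = {"kind": "svm", "sigma": model.sigma, "C": model.C,
                   "scaler_mean": model.scaler_mean.tolist(),
                   "scaler_sd": model.scaler_sd.tolist(),
                   "support_vectors": model.support_vectors.tolist(),
                   "dual_coef": model.dual_coef.tolist(),
                   "intercept": model.intercept,
                   "feature_names": list(model.feature_names),
                   "kernel_definition": model.kernel_definition}
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path):
    payload = json.loads(Path(path).read_text())
    kind = payload.get("kind")
    names = tuple(payload["feature_names"])
    if kind == "gnb":
        return GNBModel(priors=payload["priors"],
                        means=np.asarray(payload["means"]),
                        variances=np.asarray(payload["variances"]),
                        feature_names=names)
    if kind == "knb":
        return KNBModel(priors=payload["priors"],
                        train_values={c: np.asarray(v) for c, v in
                                      payload["train_values"].items()},
                        bandwidths=np.asarray(payload["bandwidths"]),
                        feature_names=names)
    if kind == "svm":
        return SVMModel(sigma=payload["sigma"], C=payload["C"],
                        scaler_mean=np.asarray(payload["scaler_mean"]),
                        scaler_sd=np.asarray(payload["scaler_sd"]),
                        support_vectors=np.asarray(
                            payload["support_vectors"]),
                        dual_coef=np.asarray(payload["dual_coef"]),
                        intercept=payload["intercept"],
                        feature_names=names,
                        kernel_definition=payload["kernel_definition"])
    raise ValueError(f"unknown model kind {kind!r}")
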