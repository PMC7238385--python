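"""10-10-1 neural network trained by Levenberg–Marquardt; jack-knife metrics.

The classifier is a single-hidden-layer perceptron: ten inputs (the feature
vector), ten tanh hidden units, one linear output. Weights are fitted by
damped Gauss–Newton (Levenberg–Marquardt) on the mean-squared error between
the network output and the 0/1 class target, the standard choice for small
dense networks. Evaluation is leave-one-out (jack-knife): each recording is
scored by the one network that never saw it, and the held-out scores are
thresholded at 0.5 and aggregated into accuracy, sensitivity and
specificity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

N_FEATURES = 10
N_HIDDEN = 10


@dataclass
class MLPModel:
    """Network weights: W1 (10x10), Bias1 (10), W2 (1x10), Bias2 (1)."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=np.float64).reshape(N_HIDDEN, N_FEATURES)
        self.b1 = np.asarray(self.b1, dtype=np.float64).reshape(N_HIDDEN)
        self.w2 = np.asarray(self.w2, dtype=np.float64).reshape(1, N_HIDDEN)
        self.b2 = np.asarray(self.b2, dtype=np.float64).reshape(1)
        for arr in (self.w1, self.b1, self.w2, self.b2):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model weights must be finite")

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Scores for one 10-vector or an (n, 10) matrix."""
        x = np.atleast_2d(np.asarray(x, dtype=np.float64))
        hidden = np.tanh(x @ self.w1.T + self.b1)
        return hidden @ self.w2.ravel() + self.b2[0]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "architecture": [N_FEATURES, N_HIDDEN, 1],
            "hidden_activation": "tanh",
            "output_activation": "linear",
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "MLPModel":
        payload = json.loads(Path(path).read_text())
        if payload.get("architecture") != [N_FEATURES, N_HIDDEN, 1]:
            raise ValueError("unexpected architecture in model file")
        return cls(payload["w1"], payload["b1"], payload["w2"], payload["b2"])


@dataclass(frozen=True)
class TrainConfig:
    """Levenberg–Marquardt settings: initial damping 0.01, 1000 iterations,
    target MSE 1e-6, seeded initialization."""

    initial_damping: float = 0.01
    max_iterations: int = 1000
    goal_mse: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_damping <= 0 or self.max_iterations <= 0 or self.goal_mse <= 0:
            raise ValueError("TrainConfig values must be positive")


@dataclass
class TrainingTrace:
    mse_history: list[float] = field(default_factory=list)
    status: str = "running"
    n_iterations: int = 0
    single_class_fold: bool = False

    @property
    def final_mse(self) -> float:
        return self.mse_history[-1] if self.mse_history else float("nan")


@dataclass
class FeatureScaler:
    """Per-feature linear map of the training range onto [-1, 1].

    Fitted on training rows only; applied to held-out rows with the same
    affine map, which may legitimately land outside +/-1. Constant columns
    map to 0 with a warning.
    """

    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def fit(self, x: np.ndarray) -> "FeatureScaler":
        x = np.asarray(x, dtype=np.float64)
        self.mins = x.min(axis=0)
        self.maxs = x.max(axis=0)
        if np.any(self.maxs == self.mins):
            warnings.warn("constant feature column mapped to 0", stacklevel=2)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if self.mins is None or self.maxs is None:
            raise RuntimeError("scaler not fitted")
        x = np.asarray(x, dtype=np.float64)
        span = self.maxs - self.mins
        out = np.zeros_like(x)
        ok = span != 0
        out[:, ok] = 2.0 * (x[:, ok] - self.mins[ok]) / span[ok] - 1.0
        return out


def normalize_features(
    train_matrix: np.ndarray, apply_matrix: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, FeatureScaler]:
    """Fit the +/-1 scaling on *train_matrix* and apply it to both matrices."""
    scaler = FeatureScaler().fit(train_matrix)
    train_scaled = scaler.transform(np.atleast_2d(train_matrix))
    apply_scaled = (
        scaler.transform(np.atleast_2d(apply_matrix))
        if apply_matrix is not None
        else None
    )
    return train_scaled, apply_scaled, scaler


def init_model(seed: int) -> MLPModel:
    """Seeded uniform weights in [-0.5, 0.5]; equal seeds give equal models."""
    rng = np.random.default_rng(seed)
    return MLPModel(
        w1=rng.uniform(-0.5, 0.5, (N_HIDDEN, N_FEATURES)),
        b1=rng.uniform(-0.5, 0.5, N_HIDDEN),
        w2=rng.uniform(-0.5, 0.5, (1, N_HIDDEN)),
        b2=rng.uniform(-0.5, 0.5, 1),
    )


def _pack(model: MLPModel) -> np.ndarray:
    return np.concatenate(
        [model.w1.ravel(), model.b1, model.w2.ravel(), model.b2]
    )


def _unpack(theta: np.ndarray) -> MLPModel:
    i = N_HIDDEN * N_FEATURES
    return MLPModel(
        theta[:i], theta[i : i + N_HIDDEN],
        theta[i + N_HIDDEN : i + 2 * N_HIDDEN], theta[i + 2 * N_HIDDEN :],
    )


def _forward_jacobian(theta: np.ndarray, x: np.ndarray):
    """Network outputs and the Jacobian d(output)/d(theta), row per sample."""
    i = N_HIDDEN * N_FEATURES
    w1 = theta[:i].reshape(N_HIDDEN, N_FEATURES)
    b1 = theta[i : i + N_HIDDEN]
    w2 = theta[i + N_HIDDEN : i + 2 * N_HIDDEN]
    b2 = theta[i + 2 * N_HIDDEN]
    hidden = np.tanh(x @ w1.T + b1)              # (n, H)
    out = hidden @ w2 + b2                       # (n,)
    dz = (1.0 - hidden**2) * w2                  # (n, H): d out / d z_h
    jac = np.concatenate(
        [
            (dz[:, :, None] * x[:, None, :]).reshape(x.shape[0], -1),  # w1
            dz,                                                        # b1
            hidden,                                                    # w2
            np.ones((x.shape[0], 1)),                                  # b2
        ],
        axis=1,
    )
    return out, jac


_MAX_DAMPING = 1e10


def train_levenberg_marquardt(
    model: MLPModel,
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
) -> tuple[MLPModel, TrainingTrace]:
    """Fit the network to 0/1 targets by damped Gauss–Newton on the MSE.

    Each iteration solves ``(J'J + mu I) delta = J' r`` for the parameter
    step; a step that lowers the MSE is accepted and mu shrinks tenfold,
    otherwise mu grows tenfold and the step is retried. Stops at the MSE
    goal, the iteration cap, or when mu overflows (a local minimum under
    machine precision).
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.asarray(y, dtype=np.float64).ravel()
    if x.shape[0] != y.size:
        raise ValueError("X and y row counts differ")
    if x.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    theta = _pack(model)
    mu = config.initial_damping
    trace = TrainingTrace()
    n_params = theta.size
    out, jac = _forward_jacobian(theta, x)
    residual = y - out
    mse = float(residual @ residual) / y.size
    trace.mse_history.append(mse)
    for iteration in range(config.max_iterations):
        trace.n_iterations = iteration + 1
        if mse <= config.goal_mse:
            trace.status = "goal_reached"
            return _unpack(theta), trace
        jtj = jac.T @ jac
        jtr = jac.T @ residual
        accepted = False
        while mu <= _MAX_DAMPING:
            try:
                delta = np.linalg.solve(jtj + mu * np.eye(n_params), jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            candidate = theta + delta
            c_out, c_jac = _forward_jacobian(candidate, x)
            c_residual = y - c_out
            c_mse = float(c_residual @ c_residual) / y.size
            if np.isfinite(c_mse) and c_mse < mse:
                theta, out, jac, residual, mse = (
                    candidate, c_out, c_jac, c_residual, c_mse,
                )
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        trace.mse_history.append(mse)
        if not accepted:
            trace.status = "damping_overflow"
            return _unpack(theta), trace
    trace.status = "goal_reached" if mse <= config.goal_mse else "max_iterations"
    return _unpack(theta), trace


def predict_score(model: MLPModel, x: np.ndarray) -> float:
    """Raw network output for one scaled 10-vector."""
    x = np.asarray(x, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite feature vector")
    return float(model.forward(x)[0])


def predict_label(model: MLPModel, x: np.ndarray, threshold: float = 0.5) -> int:
    """Class label: 0 (normal) for scores <= threshold, 1 (murmur) above."""
    return int(predict_score(model, x) > threshold)


@dataclass(frozen=True)
class Metrics:
    """Confusion-matrix metrics in percent; NaN where a denominator is 0."""

    accuracy: float
    sensitivity: float
    specificity: float
    undefined: tuple[str, ...] = ()


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> Metrics:
    """Accuracy, sensitivity and specificity (percent) from confusion counts.

    Acc = (TP+TN)/(TP+FP+TN+FN), Se = TP/(TP+FN), Sp = TN/(TN+FP). A zero
    denominator yields NaN and is named in ``undefined`` rather than being
    silently reported as 0.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    undefined = []
    total = tp + fp + tn + fn
    if total > 0:
        acc = 100.0 * (tp + tn) / total
    else:
        acc, undefined = float("nan"), undefined + ["accuracy"]
    if tp + fn > 0:
        se = 100.0 * tp / (tp + fn)
    else:
        se, undefined = float("nan"), undefined + ["sensitivity"]
    if tn + fp > 0:
        sp = 100.0 * tn / (tn + fp)
    else:
        sp, undefined = float("nan"), undefined + ["specificity"]
    return Metrics(acc, se, sp, tuple(undefined))


@dataclass
class EvaluationReport:
    """Held-out scores and labels from the jack-knife plus summary metrics."""

    scores: np.ndarray
    predicted: np.ndarray
    truth: np.ndarray
    tp: int
    fp: int
    tn: int
    fn: int
    metrics: Metrics
    n_models: int
    single_class_folds: list[int] = field(default_factory=list)

    def summary(self) -> str:
        m = self.metrics
        return (
            f"jack-knife over {self.n_models} networks: "
            f"TP={self.tp} FP={self.fp} TN={self.tn} FN={self.fn} | "
            f"Acc={m.accuracy:.1f}% Se={m.sensitivity:.1f}% Sp={m.specificity:.1f}%"
        )


def _fold_seed(seed: int, fold: int) -> int:
    return (seed * 100_003 + fold) % (2**31 - 1)


def jackknife_evaluate(
    x: np.ndarray,
    y: np.ndarray,
    config: TrainConfig | None = None,
    global_scaling: bool = False,
) -> EvaluationReport:
    """Leave-one-out evaluation: n samples, n trained networks.

    For each fold the feature scaling is fitted on the n-1 training rows
    (unless *global_scaling*, which reproduces a scaling fitted once on all
    rows) and a freshly initialized network is trained on them; the left-out
    sample is scored by that network. The n held-out labels form the
    confusion counts and the accuracy/sensitivity/specificity report.
    """
    config = config or TrainConfig()
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    y = np.asarray(y).astype(int).ravel()
    n = x.shape[0]
    if n < 3:
        raise ValueError("jack-knife needs at least 3 samples")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    global_scaler = FeatureScaler().fit(x) if global_scaling else None
    scores = np.empty(n)
    single_class_folds: list[int] = []
    for fold in range(n):
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        x_train, y_train = x[mask], y[mask]
        if len(np.unique(y_train)) < 2:
            single_class_folds.append(fold)
        scaler = global_scaler or FeatureScaler().fit(x_train)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-column warning per fold
            x_train_s = scaler.transform(x_train)
            x_test_s = scaler.transform(x[fold : fold + 1])
        model = init_model(_fold_seed(config.seed, fold))
        model, _ = train_levenberg_marquardt(model, x_train_s, y_train, config)
        scores[fold] = model.forward(x_test_s)[0]
    predicted = (scores > 0.5).astype(int)
    tp = int(np.sum((predicted == 1) & (y == 1)))
    fp = int(np.sum((predicted == 1) & (y == 0)))
    tn = int(np.sum((predicted == 0) & (y == 0)))
    fn = int(np.sum((predicted == 0) & (y == 1)))
    return EvaluationReport(
        scores=scores,
        predicted=predicted,
        truth=y,
        tp=tp, fp=fp, tn=tn, fn=fn,
        metrics=compute_metrics(tp, fp, tn, fn),
        n_models=n,
        single_class_folds=single_class_folds,
    )
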