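"""Feed-forward perceptron surrogate and its Levenberg-Marquardt trainer.

The surrogate is a three-layer network mapping a scaled 4-vector of
excipient levels to a scaled 6-vector of % released at the sampling times:
a single hidden layer with logistic-sigmoid activation

    h = 1 / (1 + exp(-(W_in x + b_in)))

followed by a linear output layer ``y = W_out h + b_out``.  Inputs and
targets are min-max scaled to [-1, +1]; predictions are mapped back to
percent units with the exact inverse.

Training minimizes the mean squared error of the scaled targets with
damped Gauss-Newton (Levenberg-Marquardt) steps: solve
``(J'J + mu I) d = -J'e`` on the residual Jacobian, accept the step and
relax the damping if the error drops, otherwise raise the damping and
retry.  A validation partition is monitored every epoch and the weights at
the epoch of minimum validation error are restored at the end.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import DissolutionProfile, Formulation, FormulationDataset
from .scaling import ScalerParams, apply_scaler, fit_scaler, invert_scaler

__all__ = [
    "MLPSurrogate",
    "TrainingHistory",
    "TrainingLimits",
    "SplitSpec",
    "forward",
    "forward_batch",
    "split_dataset",
    "train",
    "retrain_full",
    "evaluate_r2",
    "node_sweep",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class MLPSurrogate:
    """A trained composition -> dissolution-profile predictor."""

    input_weights: np.ndarray   # H x 4
    input_biases: np.ndarray    # H
    output_weights: np.ndarray  # T x H
    output_biases: np.ndarray   # T
    input_scaler: ScalerParams
    target_scaler: ScalerParams
    times_h: tuple[float, ...]

    def __post_init__(self) -> None:
        W1 = np.asarray(self.input_weights, float)
        b1 = np.asarray(self.input_biases, float)
        W2 = np.asarray(self.output_weights, float)
        b2 = np.asarray(self.output_biases, float)
        H = W1.shape[0]
        if H < 1:
            raise ValueError("need at least one hidden node")
        if W1.shape != (H, self.input_scaler.n_dims):
            raise ValueError("input_weights shape mismatch")
        if b1.shape != (H,):
            raise ValueError("input_biases shape mismatch")
        nt = len(self.times_h)
        if W2.shape != (nt, H) or b2.shape != (nt,):
            raise ValueError("output layer shape mismatch")
        if self.target_scaler.n_dims != nt:
            raise ValueError("target scaler dimension mismatch")
        for a in (W1, b1, W2, b2):
            if not np.isfinite(a).all():
                raise ValueError("non-finite network parameters")
        object.__setattr__(self, "input_weights", W1)
        object.__setattr__(self, "input_biases", b1)
        object.__setattr__(self, "output_weights", W2)
        object.__setattr__(self, "output_biases", b2)

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]


@dataclass(frozen=True)
class TrainingLimits:
    """Stopping rules and damping schedule for the trainer.

    ``max_epochs`` / ``max_validation_failures`` follow the study protocol
    (800 epochs, 200 consecutive epochs without a validation improvement).
    The damping (mu) schedule and gradient tolerance are conventional
    Levenberg-Marquardt settings.
    """

    max_epochs: int = 800
    max_validation_failures: int = 200
    mu0: float = 1e-3
    mu_increase: float = 10.0
    mu_decrease: float = 10.0
    mu_max: float = 1e10
    gradient_tol: float = 1e-7


@dataclass(frozen=True)
class SplitSpec:
    """Formulation-level train/validation/test partition fractions.

    67% of records train; of the remaining test pool, 67% is used for
    validation (early-stopping monitor) and the rest as the test set.
    Splitting is by record so a formulation's six time points never
    straddle partitions.
    """

    train_fraction: float = 0.67
    validation_fraction_of_test: float = 0.67
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.train_fraction, self.validation_fraction_of_test):
            if not (0.0 < f < 1.0):
                raise ValueError(f"fractions must lie in (0, 1), got {f}")


@dataclass
class TrainingHistory:
    """Per-epoch errors (scaled units squared) and the stopping outcome."""

    train_mse: list[float]
    validation_mse: list[float]
    test_mse: list[float]
    stop_reason: str  # max_epochs | validation_failures | gradient_converged
    best_epoch: int
    best_validation_mse: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_scaled(W1, b1, W2, b2, Xs: np.ndarray) -> np.ndarray:
    A = _sigmoid(Xs @ W1.T + b1)
    return A @ W2.T + b2


def forward_batch(net: MLPSurrogate, X: np.ndarray) -> np.ndarray:
    """Predict profiles for an N x 4 matrix of compositions (original units).

    Compositions outside the fitted scaler range are evaluated as-is
    (extrapolation); predictions are NOT clipped to [0, 100].
    """
    Xs = apply_scaler(net.input_scaler, np.atleast_2d(np.asarray(X, float)))
    Ys = _forward_scaled(
        net.input_weights, net.input_biases, net.output_weights, net.output_biases, Xs
    )
    return invert_scaler(net.target_scaler, Ys)


def forward(net: MLPSurrogate, formulation: Formulation) -> DissolutionProfile:
    """Predict the dissolution profile of one composition."""
    y = forward_batch(net, formulation.as_array()[None, :])[0]
    return DissolutionProfile(net.times_h, y.tolist())


def split_dataset(
    dataset: FormulationDataset, spec: SplitSpec
) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...]]:
    """Deterministic record-level partition into (train, validation, test).

    Sizes are the rounded (half-up) fractions; every partition must be
    non-empty.  30 records at the defaults give 20 / 7 / 3.
    """
    n = len(dataset)
    if n < 3:
        raise ValueError("need at least 3 records to split")
    n_train = int(math.floor(spec.train_fraction * n + 0.5))
    n_pool = n - n_train
    n_val = int(math.floor(spec.validation_fraction_of_test * n_pool + 0.5))
    n_test = n_pool - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(
            f"empty partition from n={n} with fractions "
            f"{spec.train_fraction}/{spec.validation_fraction_of_test}"
        )
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    train = tuple(sorted(int(i) for i in order[:n_train]))
    val = tuple(sorted(int(i) for i in order[n_train:n_train + n_val]))
    test = tuple(sorted(int(i) for i in order[n_train + n_val:]))
    return train, val, test


# ---------------------------------------------------------------------------
# Levenberg-Marquardt core


def _init_params(n_hidden: int, n_in: int, n_out: int, rng) -> np.ndarray:
    """Uniform [-0.5, 0.5] weights scaled by 1/sqrt(fan-in), seeded."""
    W1 = rng.uniform(-0.5, 0.5, (n_hidden, n_in)) / math.sqrt(n_in)
    b1 = rng.uniform(-0.5, 0.5, n_hidden) / math.sqrt(n_in)
    W2 = rng.uniform(-0.5, 0.5, (n_out, n_hidden)) / math.sqrt(n_hidden)
    b2 = rng.uniform(-0.5, 0.5, n_out) / math.sqrt(n_hidden)
    return _pack(W1, b1, W2, b2)


def _pack(W1, b1, W2, b2) -> np.ndarray:
    return np.concatenate([W1.ravel(), b1, W2.ravel(), b2])


def _unpack(p: np.ndarray, H: int, n_in: int, n_out: int):
    i = 0
    W1 = p[i:i + H * n_in].reshape(H, n_in); i += H * n_in
    b1 = p[i:i + H]; i += H
    W2 = p[i:i + n_out * H].reshape(n_out, H); i += n_out * H
    b2 = p[i:i + n_out]
    return W1, b1, W2, b2


def _residuals(p, H, Xs, Ts):
    n_in, n_out = Xs.shape[1], Ts.shape[1]
    W1, b1, W2, b2 = _unpack(p, H, n_in, n_out)
    return (_forward_scaled(W1, b1, W2, b2, Xs) - Ts).ravel()


def _jacobian(p, H, Xs, Ts):
    """d residual(s,o) / d params, shape (N*n_out, P), by analytic rules."""
    N, n_in = Xs.shape
    n_out = Ts.shape[1]
    W1, b1, W2, b2 = _unpack(p, H, n_in, n_out)
    A = _sigmoid(Xs @ W1.T + b1)          # N x H
    Ap = A * (1.0 - A)                    # N x H, sigmoid derivative
    P = p.size
    J = np.zeros((N, n_out, P))
    i = 0
    # dW1[h, k]: W2[o, h] * Ap[s, h] * Xs[s, k]
    dW1 = np.einsum("oh,sh,sk->sohk", W2, Ap, Xs)
    J[:, :, i:i + H * n_in] = dW1.reshape(N, n_out, H * n_in); i += H * n_in
    # db1[h]: W2[o, h] * Ap[s, h]
    J[:, :, i:i + H] = np.einsum("oh,sh->soh", W2, Ap); i += H
    # dW2[o, h]: A[s, h] on the matching output row only
    dW2 = np.zeros((N, n_out, n_out, H))
    idx = np.arange(n_out)
    dW2[:, idx, idx, :] = A[:, None, :]
    J[:, :, i:i + n_out * H] = dW2.reshape(N, n_out, n_out * H); i += n_out * H
    # db2[o]: 1 on the matching output row
    db2 = np.zeros((N, n_out, n_out))
    db2[:, idx, idx] = 1.0
    J[:, :, i:i + n_out] = db2
    return J.reshape(N * n_out, P)


def _mse(p, H, Xs, Ts) -> float:
    r = _residuals(p, H, Xs, Ts)
    return float(np.mean(r * r))


def _lm_loop(
    Xs: np.ndarray,
    Ts: np.ndarray,
    n_hidden: int,
    limits: TrainingLimits,
    seed: int,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    test: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, TrainingHistory]:
    rng = np.random.default_rng(seed)
    H = n_hidden
    p = _init_params(H, Xs.shape[1], Ts.shape[1], rng)
    mu = limits.mu0
    current = _mse(p, H, Xs, Ts)

    hist_train: list[float] = []
    hist_val: list[float] = []
    hist_test: list[float] = []
    best_p = p.copy()
    best_val = math.inf
    best_epoch = -1
    failures = 0
    stop = "max_epochs"

    for epoch in range(limits.max_epochs):
        r = _residuals(p, H, Xs, Ts)
        J = _jacobian(p, H, Xs, Ts)
        g = J.T @ r
        if float(np.max(np.abs(g))) < limits.gradient_tol:
            stop = "gradient_converged"
            break
        JtJ = J.T @ J
        accepted = False
        while mu <= limits.mu_max:
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(p.size), -g)
            except np.linalg.LinAlgError:
                mu *= limits.mu_increase
                continue
            trial = p + delta
            trial_mse = _mse(trial, H, Xs, Ts)
            if math.isfinite(trial_mse) and trial_mse < current:
                p = trial
                current = trial_mse
                mu = max(mu / limits.mu_decrease, 1e-20)
                accepted = True
                break
            mu *= limits.mu_increase
        if not accepted:
            # damping exhausted: no descent direction left at mu ceiling
            stop = "gradient_converged"
            break

        hist_train.append(current)
        if val is not None:
            vm = _mse(p, H, *val)
            hist_val.append(vm)
            if vm < best_val:
                best_val = vm
                best_epoch = epoch
                best_p = p.copy()
                failures = 0
            else:
                failures += 1
                if failures >= limits.max_validation_failures:
                    stop = "validation_failures"
                    hist_test.append(
                        _mse(p, H, *test) if test is not None else math.nan
                    )
                    break
        else:
            hist_val.append(math.nan)
        hist_test.append(_mse(p, H, *test) if test is not None else math.nan)

    if val is not None and best_epoch >= 0:
        p = best_p
    else:
        best_val = math.nan
        best_epoch = len(hist_train) - 1

    history = TrainingHistory(
        train_mse=hist_train,
        validation_mse=hist_val,
        test_mse=hist_test,
        stop_reason=stop,
        best_epoch=best_epoch,
        best_validation_mse=best_val,
    )
    return p, history


def _build_net(
    p: np.ndarray,
    n_hidden: int,
    in_scaler: ScalerParams,
    tgt_scaler: ScalerParams,
    times: tuple[float, ...],
) -> MLPSurrogate:
    W1, b1, W2, b2 = _unpack(p, n_hidden, in_scaler.n_dims, tgt_scaler.n_dims)
    return MLPSurrogate(W1, b1, W2, b2, in_scaler, tgt_scaler, times)


def train(
    dataset: FormulationDataset,
    n_hidden: int,
    split: SplitSpec | None = None,
    limits: TrainingLimits | None = None,
    seed: int = 0,
) -> tuple[MLPSurrogate, TrainingHistory]:
    """Train a surrogate with early stopping on a validation partition.

    Scalers are fitted on the full dataset (the deployment convention:
    the network is only ever queried inside the experimental domain the
    corpus spans).  Weights are returned at the epoch of minimum
    validation error.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    split = split if split is not None else SplitSpec(seed=seed)
    limits = limits if limits is not None else TrainingLimits()
    idx_train, idx_val, idx_test = split_dataset(dataset, split)

    in_scaler = fit_scaler(dataset.inputs())
    tgt_scaler = fit_scaler(dataset.targets())
    Xs = apply_scaler(in_scaler, dataset.inputs())
    Ts = apply_scaler(tgt_scaler, dataset.targets())

    p, history = _lm_loop(
        Xs[list(idx_train)], Ts[list(idx_train)], n_hidden, limits, seed,
        val=(Xs[list(idx_val)], Ts[list(idx_val)]),
        test=(Xs[list(idx_test)], Ts[list(idx_test)]),
    )
    net = _build_net(p, n_hidden, in_scaler, tgt_scaler, dataset.times_h)
    return net, history


def retrain_full(
    dataset: FormulationDataset,
    n_hidden: int,
    limits: TrainingLimits | None = None,
    seed: int = 0,
) -> MLPSurrogate:
    """Retrain on the entire corpus (no held-out partitions).

    Used once the architecture is chosen, to produce the network driving
    formulation optimization; stops on max_epochs or gradient convergence.
    """
    if n_hidden < 1:
        raise ValueError("n_hidden must be >= 1")
    limits = limits if limits is not None else TrainingLimits()
    in_scaler = fit_scaler(dataset.inputs())
    tgt_scaler = fit_scaler(dataset.targets())
    Xs = apply_scaler(in_scaler, dataset.inputs())
    Ts = apply_scaler(tgt_scaler, dataset.targets())
    p, _ = _lm_loop(Xs, Ts, n_hidden, limits, seed)
    return _build_net(p, n_hidden, in_scaler, tgt_scaler, dataset.times_h)


def evaluate_r2(net: MLPSurrogate, subset: FormulationDataset) -> np.ndarray:
    """Squared Pearson correlation, predicted vs observed, per time point.

    Zero variance in the observed values makes R² undefined and is
    reported as NaN; constant predictions are reported as 0 with a
    warning so sweep tables stay total.
    """
    if len(subset) == 0:
        raise ValueError("empty evaluation subset")
    pred = forward_batch(net, subset.inputs())
    obs = subset.targets()
    out = np.empty(obs.shape[1])
    for j in range(obs.shape[1]):
        so = float(np.std(obs[:, j]))
        sp = float(np.std(pred[:, j]))
        if so == 0.0:
            out[j] = math.nan
        elif sp == 0.0:
            warnings.warn(
                f"constant predictions at time point {j}; reporting R²=0",
                stacklevel=2,
            )
            out[j] = 0.0
        else:
            c = float(np.corrcoef(obs[:, j], pred[:, j])[0, 1])
            out[j] = c * c
    return out


def _derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def node_sweep(
    dataset: FormulationDataset,
    candidate_nodes=range(3, 11),
    repeats: int = 3,
    seed: int = 0,
    limits: TrainingLimits | None = None,
    split: SplitSpec | None = None,
) -> tuple[pd.DataFrame, int]:
    """Trial-and-error selection of the hidden-layer size.

    For each candidate node count, ``repeats`` networks are trained with
    distinct derived seeds (both weight initialization and partition) and
    their held-out R² (validation and test records pooled) recorded per
    time point.  The candidate maximizing the mean over time points of the
    mean R² is selected; ties go to the smaller network.  Returns
    (per-candidate summary table, selected count).  A ``split`` argument
    supplies the partition fractions; its seed is re-derived per repeat.
    """
    candidates = sorted(set(int(c) for c in candidate_nodes))
    if not candidates:
        raise ValueError("empty candidate list")
    if any(c < 1 or c > 64 for c in candidates):
        raise ValueError("candidate node counts must lie in [1, 64]")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    limits = limits if limits is not None else TrainingLimits()

    seeds = _derive_seeds(seed, len(candidates) * repeats)
    times = dataset.times_h
    rows = []
    failures: dict[int, list[str]] = {}
    for ci, c in enumerate(candidates):
        r2s = []
        for rep in range(repeats):
            s = seeds[ci * repeats + rep]
            spec = (
                dataclasses.replace(split, seed=s)
                if split is not None
                else SplitSpec(seed=s)
            )
            try:
                net, _ = train(dataset, c, split=spec, limits=limits, seed=s)
                _, idx_val, idx_test = split_dataset(dataset, spec)
                held = dataset.subset(list(idx_val) + list(idx_test))
                r2s.append(evaluate_r2(net, held))
            except (ValueError, np.linalg.LinAlgError) as e:
                failures.setdefault(c, []).append(str(e))
        if not r2s:
            continue  # candidate dropped: every repeat failed
        mean_r2 = np.nanmean(np.vstack(r2s), axis=0)
        row = {"n_hidden": c, "n_repeats_ok": len(r2s)}
        for t, v in zip(times, mean_r2):
            row[f"r2_t{t:g}h"] = float(v)
        row["mean_r2"] = float(np.nanmean(mean_r2))
        rows.append(row)
    if not rows:
        raise ValueError(f"all candidates failed: {failures}")
    table = pd.DataFrame(rows)
    best = table.loc[table["mean_r2"].idxmax()]
    # idxmax takes the first maximum; candidates are sorted ascending, so
    # ties already resolve to the smaller network
    selected = int(best["n_hidden"])
    return table, selected


# ---------------------------------------------------------------------------
# Serialization: versioned JSON text, exact decimal round trip


def save_model(net: MLPSurrogate, path: str | Path) -> None:
    doc = {
        "format": "dissopt-mlp",
        "version": MODEL_FORMAT_VERSION,
        "times_h": list(net.times_h),
        "input_scaler": {
            "min": list(net.input_scaler.minimum),
            "max": list(net.input_scaler.maximum),
        },
        "target_scaler": {
            "min": list(net.target_scaler.minimum),
            "max": list(net.target_scaler.maximum),
        },
        "input_weights": net.input_weights.tolist(),
        "input_biases": net.input_biases.tolist(),
        "output_weights": net.output_weights.tolist(),
        "output_biases": net.output_biases.tolist(),
    }
    Path(path).write_text(json.dumps(doc, indent=1), encoding="utf-8")


def load_model(path: str | Path) -> MLPSurrogate:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format") != "dissopt-mlp":
        raise ValueError(f"not a surrogate model file: {path}")
    if doc.get("version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {doc.get('version')}")
    return MLPSurrogate(
        np.array(doc["input_weights"], float),
        np.array(doc["input_biases"], float),
        np.array(doc["output_weights"], float),
        np.array(doc["output_biases"], float),
        ScalerParams(
            tuple(doc["input_scaler"]["min"]), tuple(doc["input_scaler"]["max"])
        ),
        ScalerParams(
            tuple(doc["target_scaler"]["min"]), tuple(doc["target_scaler"]["max"])
        ),
        tuple(float(t) for t in doc["times_h"]),
    )
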