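"""Feed-forward surrogate of (spacing, pruning) → (duration, yield, quality).

A small 2→12→8→3 multilayer perceptron (tanh hidden layers, identity
output) regresses the three cultivation objectives — total growth period
(days), yield (t·hm⁻²) and comprehensive quality closeness C_i — on the two
encoded design factors.  Training is full-batch damped Gauss–Newton
(Levenberg–Marquardt): at each epoch the update solves

    (JᵀJ + μI) δ = −Jᵀr

with the damping μ decreased after an accepted step and increased after a
rejected one, exactly the regime used for desk-scale regression networks.
Several restarts from different seeded initializations are trained and the
one with the lowest validation error is kept.

Inputs are min-max scaled to [−1, 1] over the feasible design bounds
(spacing 30–80 cm; pruning code 1–4 treated ordinally), and each output is
min-max scaled to [−1, 1] over the training targets; predictions are
returned descaled to physical units.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .entropy_topsis import goodness_of_fit
from .trial_data import (
    SPACING_MAX_CM,
    SPACING_MIN_CM,
    TreatmentSpec,
    TrialDataset,
)

__all__ = [
    "RESPONSE_COLUMNS",
    "SurrogateConfig",
    "SurrogateModel",
    "FitReport",
    "Prediction",
    "encode_design",
    "train_surrogate",
    "predict",
    "predict_batch",
]

#: Response columns, in network-output order.
RESPONSE_COLUMNS: tuple[str, ...] = ("duration_days", "yield_t_hm2", "ci")

_PRUNING_MIN, _PRUNING_MAX = 1, 4


@dataclass(frozen=True)
class SurrogateConfig:
    """Training contract for the surrogate network.

    ``learning_rate`` is the initial Levenberg–Marquardt damping factor μ
    (the role the parameter plays under this training regime); ``mse_target``
    is the stop-early goal on the training MSE in scaled space.
    ``validation`` is ``"split"`` (random train/val/test split by seed) or
    ``"loo"`` (leave-one-out validation error used for restart selection,
    final model refit on all rows — the sensible mode for very small trials).
    """

    hidden_sizes: tuple[int, int] = (12, 8)
    max_epochs: int = 2000
    learning_rate: float = 0.05
    mse_target: float = 1e-8
    restarts: int = 10
    split_fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    validation: str = "split"
    patience: int = 6
    mu_max: float = 1e10

    def __post_init__(self):
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        f = self.split_fractions
        if len(f) != 3 or any(x < 0 for x in f) or f[0] <= 0:
            raise ValueError("split fractions must be non-negative with train > 0")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.validation not in ("split", "loo"):
            raise ValueError("validation must be 'split' or 'loo'")


@dataclass
class FitReport:
    """Per-split fit diagnostics for the kept restart.

    ``r`` entries are Pearson goodness-of-fit values between flattened
    predictions and targets; None flags an undefined correlation (constant
    targets) rather than raising.
    """

    mse: dict[str, float | None]
    r: dict[str, float | None]
    best_val_epoch: int | None
    epochs_run: int
    restart_kept: int
    selection_mse: float
    notes: list[str] = field(default_factory=list)


@dataclass
class SurrogateModel:
    """Trained network weights plus the scaling metadata to invert them."""

    weights: list[np.ndarray]  # [W1, b1, W2, b2, W3, b3]
    hidden_sizes: tuple[int, int]
    out_min: np.ndarray  # per-output training-target minima
    out_range: np.ndarray  # per-output (max - min), 0 kept as-is
    train_labels: list[str]
    seed: int
    epochs_run: int = 0
    final_train_mse: float = float("nan")

    # -- scaling ---------------------------------------------------------
    def scale_targets(self, y: np.ndarray) -> np.ndarray:
        rng = np.where(self.out_range == 0, 1.0, self.out_range)
        return np.where(
            self.out_range == 0, 0.0, -1.0 + 2.0 * (y - self.out_min) / rng
        )

    def descale_outputs(self, s: np.ndarray) -> np.ndarray:
        return np.where(
            self.out_range == 0,
            self.out_min,
            self.out_min + (s + 1.0) * self.out_range / 2.0,
        )

    # -- forward pass ----------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Scaled-space outputs for encoded inputs x of shape (n, 2)."""
        w1, b1, w2, b2, w3, b3 = self.weights
        a1 = np.tanh(x @ w1.T + b1)
        a2 = np.tanh(a1 @ w2.T + b2)
        return a2 @ w3.T + b3

    # -- serialization ---------------------------------------------------
    def to_json_dict(self) -> dict:
        return {
            "topology": [2, *self.hidden_sizes, 3],
            "weights": [w.tolist() for w in self.weights],
            "out_min": self.out_min.tolist(),
            "out_range": self.out_range.tolist(),
            "train_labels": self.train_labels,
            "seed": self.seed,
            "epochs_run": self.epochs_run,
            "final_train_mse": self.final_train_mse,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "SurrogateModel":
        return cls(
            weights=[np.asarray(w, dtype=float) for w in d["weights"]],
            hidden_sizes=tuple(d["topology"][1:-1]),
            out_min=np.asarray(d["out_min"], dtype=float),
            out_range=np.asarray(d["out_range"], dtype=float),
            train_labels=list(d["train_labels"]),
            seed=int(d["seed"]),
            epochs_run=int(d["epochs_run"]),
            final_train_mse=float(d["final_train_mse"]),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "SurrogateModel":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass(frozen=True)
class Prediction:
    duration_days: float
    yield_t_hm2: float
    ci: float
    ci_clamped: bool


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def _minmax(v: float, lo: float, hi: float) -> float:
    return -1.0 + 2.0 * (v - lo) / (hi - lo)


def encode_design(t: TreatmentSpec) -> np.ndarray:
    """Encode one design as a length-2 vector scaled to [-1, 1].

    Spacing maps linearly from [30, 80] cm; the pruning code (1..4, ordinal)
    maps with the same min-max rule over its own range.
    """
    if not SPACING_MIN_CM <= t.spacing_cm <= SPACING_MAX_CM:
        raise ValueError(
            f"spacing {t.spacing_cm} outside [{SPACING_MIN_CM}, {SPACING_MAX_CM}]"
        )
    if not _PRUNING_MIN <= t.pruning_code <= _PRUNING_MAX:
        raise ValueError(f"pruning code {t.pruning_code} outside 1..4")
    return np.array(
        [
            _minmax(t.spacing_cm, SPACING_MIN_CM, SPACING_MAX_CM),
            _minmax(t.pruning_code, _PRUNING_MIN, _PRUNING_MAX),
        ]
    )


def _encode_many(specs: Sequence[TreatmentSpec]) -> np.ndarray:
    return np.stack([encode_design(t) for t in specs])


# ---------------------------------------------------------------------------
# Levenberg–Marquardt training
# ---------------------------------------------------------------------------


def _init_weights(hidden: tuple[int, int], rng: np.random.Generator):
    sizes = [2, hidden[0], hidden[1], 3]
    ws = []
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        ws.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        ws.append(np.zeros(fan_out))
    return ws


def _pack(ws) -> np.ndarray:
    return np.concatenate([w.ravel() for w in ws])


def _unpack(theta: np.ndarray, hidden: tuple[int, int]):
    sizes = [2, hidden[0], hidden[1], 3]
    ws, pos = [], 0
    for fan_in, fan_out in zip(sizes, sizes[1:]):
        n = fan_out * fan_in
        ws.append(theta[pos : pos + n].reshape(fan_out, fan_in))
        pos += n
        ws.append(theta[pos : pos + fan_out].copy())
        pos += fan_out
    return ws


def _forward_cache(ws, x):
    w1, b1, w2, b2, w3, b3 = ws
    a1 = np.tanh(x @ w1.T + b1)
    a2 = np.tanh(a1 @ w2.T + b2)
    y = a2 @ w3.T + b3
    return a1, a2, y


def _jacobian(ws, x, a1, a2):
    """Jacobian of the flattened outputs (n·3) w.r.t. the packed weights,
    by reverse-mode accumulation per output unit."""
    w1, b1, w2, b2, w3, b3 = ws
    n = x.shape[0]
    n_out = w3.shape[0]
    d1 = 1.0 - a1**2  # tanh'
    d2 = 1.0 - a2**2
    cols = sum(w.size for w in ws)
    jac = np.zeros((n * n_out, cols))
    # packed layout offsets
    off_w1 = 0
    off_b1 = off_w1 + w1.size
    off_w2 = off_b1 + b1.size
    off_b2 = off_w2 + w2.size
    off_w3 = off_b2 + b2.size
    off_b3 = off_w3 + w3.size
    for k in range(n_out):
        rows = slice(k, n * n_out, n_out)  # residuals ordered sample-major
        g2 = w3[k] * d2  # (n, h2): dy_k/dz2
        g1 = (g2 @ w2) * d1  # (n, h1): dy_k/dz1
        jac[rows, off_w1:off_b1] = (g1[:, :, None] * x[:, None, :]).reshape(n, -1)
        jac[rows, off_b1:off_w2] = g1
        jac[rows, off_w2:off_b2] = (g2[:, :, None] * a1[:, None, :]).reshape(n, -1)
        jac[rows, off_b2:off_w3] = g2
        jac[rows, off_w3 + k * a2.shape[1] : off_w3 + (k + 1) * a2.shape[1]] = a2
        jac[rows, off_b3 + k] = 1.0
    return jac


def _train_once(
    x: np.ndarray,
    y_scaled: np.ndarray,
    cfg: SurrogateConfig,
    init_rng: np.random.Generator,
    x_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
):
    """Train one network full-batch by damped Gauss–Newton.

    Returns (weights, epochs_run, final_train_mse, best_val_epoch,
    best_val_mse).  When a validation set is given, the weights at the
    epoch of minimum validation MSE are restored (early stopping with
    ``cfg.patience`` consecutive failures to improve).
    """
    ws = _init_weights(cfg.hidden_sizes, init_rng)
    theta = _pack(ws)
    mu = cfg.learning_rate
    n_res = y_scaled.size

    def mse_of(th):
        w = _unpack(th, cfg.hidden_sizes)
        _, _, pred = _forward_cache(w, x)
        return float(((pred - y_scaled) ** 2).mean())

    def val_mse_of(th):
        if x_val is None or len(x_val) == 0:
            return None
        w = _unpack(th, cfg.hidden_sizes)
        _, _, pred = _forward_cache(w, x_val)
        return float(((pred - y_val) ** 2).mean())

    train_mse = mse_of(theta)
    best_val = val_mse_of(theta)
    best_val_theta = theta.copy()
    best_val_epoch = 0 if best_val is not None else None
    fails = 0
    epoch = 0
    eye = np.eye(theta.size)
    while epoch < cfg.max_epochs and train_mse > cfg.mse_target:
        epoch += 1
        ws = _unpack(theta, cfg.hidden_sizes)
        a1, a2, pred = _forward_cache(ws, x)
        r = (pred - y_scaled).ravel()
        jac = _jacobian(ws, x, a1, a2)
        jtj = jac.T @ jac
        jtr = jac.T @ r
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(jtj + mu * eye, -jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            cand = theta + delta
            cand_mse = mse_of(cand)
            if not np.isfinite(cand_mse):
                raise FloatingPointError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            if cand_mse < train_mse:
                theta, train_mse = cand, cand_mse
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            break  # damping exhausted: converged as far as LM will go
        vm = val_mse_of(theta)
        if vm is not None:
            if best_val is None or vm < best_val:
                best_val, best_val_theta, best_val_epoch = vm, theta.copy(), epoch
                fails = 0
            else:
                fails += 1
                if fails >= cfg.patience:
                    break
    if best_val is not None:
        theta = best_val_theta
        train_mse = mse_of(theta)
    return (
        _unpack(theta, cfg.hidden_sizes),
        epoch,
        train_mse,
        best_val_epoch,
        best_val,
    )


def _split_indices(n: int, fractions, rng: np.random.Generator):
    perm = rng.permutation(n)
    n_train = max(1, int(round(fractions[0] * n)))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return (
        perm[:n_train],
        perm[n_train : n_train + n_val],
        perm[n_train + n_val :],
    )


def _complete_rows(ds: TrialDataset):
    resp = ds.responses
    if resp is None:
        raise ValueError("dataset has no response table; nothing to train on")
    labels, missing = [], []
    for t in ds.treatments:
        if t.label not in resp.index:
            missing.append(t.label)
            continue
        row = resp.loc[t.label, list(RESPONSE_COLUMNS)]
        if row.isna().any():
            missing.append(t.label)
        else:
            labels.append(t.label)
    return labels, missing


def train_surrogate(
    ds: TrialDataset, cfg: SurrogateConfig | None = None
) -> tuple[SurrogateModel, FitReport]:
    """Fit the surrogate to a trial dataset's complete response rows.

    Trains ``cfg.restarts`` networks from different seeded initializations
    and keeps the one with the lowest validation error (split or
    leave-one-out per ``cfg.validation``).  Raises when fewer than six
    treatments have all three responses, naming the incomplete ones.
    """
    cfg = cfg or SurrogateConfig()
    labels, missing = _complete_rows(ds)
    if len(labels) < 6:
        raise ValueError(
            "need complete (duration, yield, ci) responses for >= 6 treatments; "
            f"incomplete: {missing or 'none'} (complete: {len(labels)})"
        )
    specs = [ds.treatment(lab) for lab in labels]
    x = _encode_many(specs)
    y = ds.responses.loc[labels, list(RESPONSE_COLUMNS)].to_numpy(dtype=float)

    out_min = y.min(axis=0)
    out_range = y.max(axis=0) - out_min
    proto = SurrogateModel(
        weights=[],
        hidden_sizes=cfg.hidden_sizes,
        out_min=out_min,
        out_range=out_range,
        train_labels=labels,
        seed=cfg.seed,
    )
    ys = proto.scale_targets(y)
    n = len(labels)

    split_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 977]))
    if cfg.validation == "split":
        idx_train, idx_val, idx_test = _split_indices(n, cfg.split_fractions, split_rng)
    else:
        idx_train = np.arange(n)
        idx_val = np.array([], dtype=int)
        idx_test = np.array([], dtype=int)

    best = None  # (selection_mse, restart, weights, epochs, train_mse, val_epoch)
    for restart in range(cfg.restarts):
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, restart]))
        if cfg.validation == "loo":
            # selection score: mean squared leave-one-out prediction error
            errs = []
            for i in range(n):
                keep = np.delete(np.arange(n), i)
                rng_i = np.random.default_rng(
                    np.random.SeedSequence([cfg.seed, restart, 7])
                )
                ws_i, *_ = _train_once(x[keep], ys[keep], cfg, rng_i)
                _, _, pred = _forward_cache(ws_i, x[i : i + 1])
                errs.append(float(((pred - ys[i : i + 1]) ** 2).mean()))
            sel = float(np.mean(errs))
            ws, epochs, train_mse, val_epoch, _ = _train_once(x, ys, cfg, rng)
        else:
            xv = x[idx_val] if idx_val.size else None
            yv = ys[idx_val] if idx_val.size else None
            ws, epochs, train_mse, val_epoch, val_mse = _train_once(
                x[idx_train], ys[idx_train], cfg, rng, xv, yv
            )
            sel = val_mse if val_mse is not None else train_mse
        if best is None or sel < best[0]:
            best = (sel, restart, ws, epochs, train_mse, val_epoch)

    sel, restart, ws, epochs, train_mse, val_epoch = best
    model = SurrogateModel(
        weights=ws,
        hidden_sizes=cfg.hidden_sizes,
        out_min=out_min,
        out_range=out_range,
        train_labels=labels,
        seed=cfg.seed,
        epochs_run=epochs,
        final_train_mse=train_mse,
    )

    report = FitReport(
        mse={},
        r={},
        best_val_epoch=val_epoch,
        epochs_run=epochs,
        restart_kept=restart,
        selection_mse=sel,
    )
    splits = (
        {"train": idx_train, "val": idx_val, "test": idx_test}
        if cfg.validation == "split"
        else {"train": np.arange(n)}
    )
    for name, idx in splits.items():
        if idx.size == 0:
            report.mse[name] = None
            report.r[name] = None
            continue
        pred = model.forward(x[idx])
        report.mse[name] = float(((pred - ys[idx]) ** 2).mean())
        try:
            report.r[name] = goodness_of_fit(pred.ravel(), ys[idx].ravel())
        except ValueError:
            report.r[name] = None
            report.notes.append(f"goodness of fit undefined on {name} split")
    if cfg.validation == "loo":
        report.notes.append("selection by leave-one-out prediction error")
    return model, report


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------


def predict_batch(model: SurrogateModel, specs: Sequence[TreatmentSpec]) -> np.ndarray:
    """Physical-unit (duration, yield, ci) rows for many designs; the ci
    column is clamped to [0, 1]."""
    if not model.weights:
        raise RuntimeError("surrogate model is untrained")
    out = model.descale_outputs(model.forward(_encode_many(specs)))
    out[:, 2] = np.clip(out[:, 2], 0.0, 1.0)
    return out


def predict(model: SurrogateModel, t: TreatmentSpec) -> Prediction:
    """Deterministic forward pass for one design, descaled to physical
    units; quality closeness is clamped to [0, 1] with a flag."""
    if not model.weights:
        raise RuntimeError("surrogate model is untrained")
    raw = model.descale_outputs(model.forward(_encode_many([t])))[0]
    ci = float(raw[2])
    clamped = not 0.0 <= ci <= 1.0
    return Prediction(
        duration_days=float(raw[0]),
        yield_t_hm2=float(raw[1]),
        ci=float(np.clip(ci, 0.0, 1.0)),
        ci_clamped=clamped,
    )
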