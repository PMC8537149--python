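"""The p × M × 1 sigmoid feed-forward network behind the LogBB regression.

Architecture (no bias terms by default):

    H_i = sgm(Σ_k w_ki I_k),   O = sgm(Σ_i w_i H_i),   sgm(t) = 1/(1+e^(−t))

with M = 3 hidden neurons.  Targets are min-max normalized to [0, 1] (the
sigmoid's range); inputs are min-max scaled the same way.  Training
minimizes the sum of squared errors F = Σ_j (D_j − O_j)² by full-batch
gradient descent with Armijo backtracking, stopping at F ≤ 1e-4.

Because the output sigmoid maps into (0, 1), denormalized predictions are
confined to the open training range (lo, hi) — a documented limitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def sigmoid(t: np.ndarray) -> np.ndarray:
    out = np.empty_like(t, dtype=float)
    pos = t >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass(frozen=True)
class Normalizer:
    """Affine map of the training label range [lo, hi] onto [0, 1]."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.hi > self.lo:
            raise ValueError("normalizer needs hi > lo (nonconstant labels)")

    def transform(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.lo) / (self.hi - self.lo)

    def inverse(self, y_norm: np.ndarray) -> np.ndarray:
        return np.asarray(y_norm, dtype=float) * (self.hi - self.lo) + self.lo


@dataclass(frozen=True)
class TrainConfig:
    """Training control.

    ``optimizer`` selects the gradient-based minimizer of F:
    ``lm`` (default) is Levenberg-Marquardt on the residual vector with
    seeded random restarts at escalating initialization scales — the
    saturating [0, 1]-normalized targets make the error surface too flat
    for plain descent; ``gd`` is full-batch gradient descent with Armijo
    backtracking.  ``max_epochs`` caps gd epochs / per-restart LM residual
    evaluations.
    """

    f_tol: float = 1e-4
    max_epochs: int = 20000
    learning_rate: float = 0.5
    seed: int = 0
    optimizer: str = "lm"
    n_restarts: int = 20

    def __post_init__(self) -> None:
        if self.f_tol <= 0:
            raise ValueError("f_tol must be positive")
        if self.optimizer not in {"lm", "gd"}:
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class ANNModel:
    w_in: np.ndarray              # p × M
    w_out: np.ndarray             # M
    normalizer: Normalizer | None = None
    x_lo: np.ndarray | None = None
    x_hi: np.ndarray | None = None
    b_hidden: np.ndarray | None = None
    b_out: float = 0.0
    use_bias: bool = False
    seed: int = 0
    trace: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.w_in = np.asarray(self.w_in, dtype=float)
        self.w_out = np.asarray(self.w_out, dtype=float)
        if self.w_in.ndim != 2 or self.w_out.ndim != 1:
            raise ValueError("w_in must be p×M and w_out length M")
        if self.w_in.shape[1] != self.w_out.shape[0]:
            raise ValueError("hidden-layer sizes of w_in and w_out disagree")
        if self.w_in.shape[1] < 1:
            raise ValueError("need at least one hidden neuron")
        if not (np.all(np.isfinite(self.w_in)) and np.all(np.isfinite(self.w_out))):
            raise ValueError("weights must be finite")
        if self.use_bias and self.b_hidden is None:
            self.b_hidden = np.zeros(self.w_in.shape[1])

    @property
    def n_inputs(self) -> int:
        return self.w_in.shape[0]

    @property
    def m_hidden(self) -> int:
        return self.w_in.shape[1]

    def scale_inputs(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.x_lo is None:
            return X
        span = np.where(self.x_hi > self.x_lo, self.x_hi - self.x_lo, 1.0)
        return (X - self.x_lo) / span


def forward(model: ANNModel, x: np.ndarray) -> float:
    """Normalized network output for one already-scaled input vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ValueError(
            f"input length {x.shape} != expected ({model.n_inputs},)")
    return float(_forward_batch(model, x[None, :])[0][0])


def _forward_batch(model: ANNModel, X: np.ndarray):
    pre_h = X @ model.w_in
    if model.use_bias:
        pre_h = pre_h + model.b_hidden
    H = sigmoid(pre_h)
    pre_o = H @ model.w_out
    if model.use_bias:
        pre_o = pre_o + model.b_out
    return sigmoid(pre_o), H


def loss(model: ANNModel, X: np.ndarray, y_norm: np.ndarray) -> float:
    """F = Σ_j (D_j − O_j)² in normalized space (X already scaled)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_norm = np.asarray(y_norm, dtype=float)
    if np.any(~np.isfinite(X)) or np.any(~np.isfinite(y_norm)):
        raise ValueError("inputs contain NaN or inf")
    out, _ = _forward_batch(model, X)
    return float(np.sum((y_norm - out) ** 2))


def gradient(model: ANNModel, X: np.ndarray, y_norm: np.ndarray):
    """Analytic ∂F/∂w for both layers (and biases when enabled)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_norm = np.asarray(y_norm, dtype=float)
    out, H = _forward_batch(model, X)
    # dF/d(pre_o) = -2 (D - O) O (1 - O)
    delta_o = -2.0 * (y_norm - out) * out * (1.0 - out)
    g_out = H.T @ delta_o
    delta_h = np.outer(delta_o, model.w_out) * H * (1.0 - H)
    g_in = X.T @ delta_h
    if model.use_bias:
        return g_in, g_out, delta_h.sum(axis=0), float(delta_o.sum())
    return g_in, g_out


def train(
    X_train: np.ndarray,
    y_logbb: np.ndarray,
    cfg: TrainConfig = TrainConfig(),
    m_hidden: int = 3,
    use_bias: bool = False,
) -> ANNModel:
    """Fit the network to LogBB labels.

    The label normalizer and per-feature input scaling are fitted on the
    training data; weights start uniform(−0.5, 0.5) from ``cfg.seed``.
    Full-batch gradient descent with Armijo backtracking runs until
    F ≤ ``cfg.f_tol`` or ``cfg.max_epochs``; the accepted-loss trace is
    recorded on the returned model.
    """
    X_train = np.atleast_2d(np.asarray(X_train, dtype=float))
    y_logbb = np.asarray(y_logbb, dtype=float)
    if len(X_train) != len(y_logbb):
        raise ValueError("X and y length mismatch")
    if len(y_logbb) < 2:
        raise ValueError("need at least two training samples")
    if np.ptp(y_logbb) == 0.0:
        raise ValueError("labels are constant: normalizer is degenerate")

    norm = Normalizer(float(y_logbb.min()), float(y_logbb.max()))
    y_norm = norm.transform(y_logbb)
    x_lo = X_train.min(axis=0)
    x_hi = X_train.max(axis=0)

    rng = np.random.default_rng(cfg.seed)
    p = X_train.shape[1]
    model = ANNModel(
        w_in=rng.uniform(-0.5, 0.5, size=(p, m_hidden)),
        w_out=rng.uniform(-0.5, 0.5, size=m_hidden),
        normalizer=norm,
        x_lo=x_lo,
        x_hi=x_hi,
        use_bias=use_bias,
        seed=cfg.seed,
    )
    if use_bias:
        model.b_hidden = rng.uniform(-0.5, 0.5, size=m_hidden)
        model.b_out = float(rng.uniform(-0.5, 0.5))
    Xs = model.scale_inputs(X_train)

    if cfg.optimizer == "lm":
        return _train_lm(model, Xs, y_norm, cfg, m_hidden, use_bias, rng)

    step = cfg.learning_rate
    f = loss(model, Xs, y_norm)
    model.trace = [f]
    for _ in range(cfg.max_epochs):
        if f <= cfg.f_tol:
            break
        grads = gradient(model, Xs, y_norm)
        g_in, g_out = grads[0], grads[1]
        gnorm2 = float(np.sum(g_in**2) + np.sum(g_out**2))
        if use_bias:
            gnorm2 += float(np.sum(grads[2] ** 2) + grads[3] ** 2)
        if gnorm2 == 0.0:
            break
        accepted = False
        trial = step
        for _halving in range(40):
            cand = ANNModel(
                w_in=model.w_in - trial * g_in,
                w_out=model.w_out - trial * g_out,
                normalizer=norm, x_lo=x_lo, x_hi=x_hi,
                b_hidden=(model.b_hidden - trial * grads[2]) if use_bias else None,
                b_out=(model.b_out - trial * grads[3]) if use_bias else 0.0,
                use_bias=use_bias, seed=cfg.seed,
            )
            f_new = loss(cand, Xs, y_norm)
            if f_new <= f - 1e-4 * trial * gnorm2:
                accepted = True
                break
            trial *= 0.5
        if not accepted:
            break
        model.w_in, model.w_out = cand.w_in, cand.w_out
        if use_bias:
            model.b_hidden, model.b_out = cand.b_hidden, cand.b_out
        f = f_new
        model.trace.append(f)
        # grow the step again after a clean accept
        step = trial * (1.3 if trial == step else 2.0)
    return model


def _train_lm(
    model: ANNModel,
    Xs: np.ndarray,
    y_norm: np.ndarray,
    cfg: TrainConfig,
    m_hidden: int,
    use_bias: bool,
    rng: np.random.Generator,
) -> ANNModel:
    """Levenberg-Marquardt minimization of the residual vector D − O with
    the analytic Jacobian, restarted from seeded random initializations of
    growing scale until F ≤ f_tol or the restart budget is spent.

    The first restart begins at the weights already drawn on ``model`` so
    the seed fully determines the outcome.  ``model.trace`` records the
    best F after each restart (non-increasing by construction).
    """
    from scipy.optimize import least_squares

    n, p = Xs.shape
    M = m_hidden
    n_weights = p * M + M + (M + 1 if use_bias else 0)

    def unpack(w):
        w_in = w[: p * M].reshape(p, M)
        w_out = w[p * M: p * M + M]
        b_h = w[p * M + M: p * M + 2 * M] if use_bias else None
        b_o = float(w[-1]) if use_bias else 0.0
        return w_in, w_out, b_h, b_o

    def residual(w):
        w_in, w_out, b_h, b_o = unpack(w)
        pre_h = Xs @ w_in + (b_h if use_bias else 0.0)
        H = sigmoid(pre_h)
        O = sigmoid(H @ w_out + b_o)
        return O - y_norm

    def jacobian(w):
        w_in, w_out, b_h, b_o = unpack(w)
        H = sigmoid(Xs @ w_in + (b_h if use_bias else 0.0))
        O = sigmoid(H @ w_out + b_o)
        d_o = (O * (1.0 - O))[:, None]
        j_out = d_o * H
        d_h = d_o * w_out[None, :] * H * (1.0 - H)
        j_in = (d_h[:, None, :] * Xs[:, :, None]).reshape(n, p * M)
        cols = [j_in, j_out]
        if use_bias:
            cols += [d_h, d_o]
        return np.hstack(cols)

    w0 = np.concatenate([
        model.w_in.ravel(), model.w_out,
        *( [model.b_hidden, [model.b_out]] if use_bias else [] ),
    ])
    scales = (0.5, 1.0, 2.0, 4.0, 8.0)
    best_w, best_f = w0, float(np.sum(residual(w0) ** 2))
    trace = [best_f]
    for restart in range(cfg.n_restarts):
        start = w0 if restart == 0 else rng.uniform(
            -scales[restart % len(scales)], scales[restart % len(scales)],
            size=n_weights)
        # MINPACK LM needs at least as many residuals as parameters;
        # trust-region-reflective handles the underdetermined case.
        method = "lm" if n >= n_weights else "trf"
        result = least_squares(
            residual, start, jac=jacobian, method=method,
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
            max_nfev=max(100, cfg.max_epochs // cfg.n_restarts))
        f = 2.0 * result.cost
        if f < best_f:
            best_f, best_w = f, result.x
        trace.append(best_f)
        if best_f <= cfg.f_tol:
            break
    w_in, w_out, b_h, b_o = unpack(best_w)
    model.w_in, model.w_out = w_in, w_out
    if use_bias:
        model.b_hidden, model.b_out = b_h, b_o
    model.trace = trace
    return model


def predict(model: ANNModel, X: np.ndarray) -> np.ndarray:
    """Denormalized LogBB predictions."""
    if model.normalizer is None:
        raise ValueError("model is untrained: no fitted normalizer")
    Xs = model.scale_inputs(X)
    out, _ = _forward_batch(model, Xs)
    return model.normalizer.inverse(out)


def to_json(model: ANNModel) -> str:
    import json

    return json.dumps({
        "w_in": model.w_in.tolist(),
        "w_out": model.w_out.tolist(),
        "b_hidden": None if model.b_hidden is None else model.b_hidden.tolist(),
        "b_out": model.b_out,
        "use_bias": model.use_bias,
        "normalizer": None if model.normalizer is None
        else [model.normalizer.lo, model.normalizer.hi],
        "x_lo": None if model.x_lo is None else model.x_lo.tolist(),
        "x_hi": None if model.x_hi is None else model.x_hi.tolist(),
        "seed": model.seed,
        "trace": list(model.trace),
    })


def from_json(text: str) -> ANNModel:
    import json

    d = json.loads(text)
    return ANNModel(
        w_in=np.array(d["w_in"]),
        w_out=np.array(d["w_out"]),
        normalizer=None if d["normalizer"] is None
        else Normalizer(*d["normalizer"]),
        x_lo=None if d["x_lo"] is None else np.array(d["x_lo"]),
        x_hi=None if d["x_hi"] is None else np.array(d["x_hi"]),
        b_hidden=None if d["b_hidden"] is None else np.array(d["b_hidden"]),
        b_out=d["b_out"],
        use_bias=d["use_bias"],
        seed=d["seed"],
        trace=list(d["trace"]),
    )
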