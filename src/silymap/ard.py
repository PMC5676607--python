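"""One-hidden-layer MLP with Automatic Relevance Determination (ARD).

The classifier is the nonlinear map

    y(x) = sigmoid( v . tanh(u x + b1) + b2 )            y in (0, 1)

interpreted as p(t = 1 | x). Training minimizes the regularized objective

    F(w) = G + sum_k alpha_k * E_w(k),      E_w(k) = 1/2 sum_{j in W(k)} w_j^2

where G is the Bernoulli cross-entropy of the binary targets and the weight
vector w is partitioned into k = 1..n+3 groups W(k): one group per input
feature (that feature's connections to all hidden units), the hidden biases,
the hidden-to-output weights, and the output bias.

The decay hyperparameters alpha_k are re-estimated between optimization
rounds with MacKay's evidence framework: with A the Hessian of F at the
current minimum,

    gamma_k = |W(k)| - alpha_k * trace_k(A^-1)       (well-determined count)
    alpha_k <- gamma_k / (2 * E_w(k))

so weight groups the data does not determine are driven to large alpha
(suppressed weights) while informative groups keep small alpha — a soft
feature selection read directly off the final alphas.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg, optimize

from .features import PixelDataset, StandardizationParams

__all__ = [
    "MLPARDModel",
    "WeightGroups",
    "HyperparameterSet",
    "TrainConfig",
    "TrainingError",
    "forward",
    "cross_entropy",
    "group_penalty",
    "objective",
    "objective_gradient",
    "objective_hessian",
    "gauss_newton_hessian",
    "train_inner",
    "reestimate_alphas",
    "fit",
    "save_model",
    "load_model",
]

EPS_CLIP = 1e-12  # prediction clipping inside logarithms

_STREAM_INIT = 301


class TrainingError(RuntimeError):
    """Raised when optimization produces a non-finite objective."""


# ---------------------------------------------------------------------------
# model container and the weight-vector layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MLPARDModel:
    """Weights of the 4-H-1 network (n arbitrary; n = 4 in this analysis).

    ``u``: first-layer weights (hidden_count x n); ``b1``: hidden biases;
    ``v``: hidden-to-output weights; ``b2``: output bias. The flat weight
    vector w orders them [u row-major, b1, v, b2].
    """

    u: np.ndarray
    b1: np.ndarray
    v: np.ndarray
    b2: float

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        b1 = np.asarray(self.b1, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.ndim != 2 or b1.shape != (u.shape[0],) or v.shape != (u.shape[0],):
            raise ValueError("inconsistent layer shapes")
        if not (np.isfinite(u).all() and np.isfinite(b1).all() and np.isfinite(v).all() and np.isfinite(self.b2)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "v", v)
        object.__setattr__(self, "b2", float(self.b2))

    @property
    def n(self) -> int:
        return self.u.shape[1]

    @property
    def hidden_count(self) -> int:
        return self.u.shape[0]

    @property
    def n_params(self) -> int:
        return self.u.size + 2 * self.hidden_count + 1

    def to_vector(self) -> np.ndarray:
        return np.concatenate([self.u.ravel(), self.b1, self.v, [self.b2]])

    @classmethod
    def from_vector(cls, w: np.ndarray, n: int, hidden_count: int) -> "MLPARDModel":
        w = np.asarray(w, dtype=float)
        h = hidden_count
        if w.size != h * n + 2 * h + 1:
            raise ValueError("weight vector length does not match dimensions")
        u = w[: h * n].reshape(h, n)
        b1 = w[h * n : h * n + h]
        v = w[h * n + h : h * n + 2 * h]
        return cls(u=u, b1=b1, v=v, b2=float(w[-1]))


@dataclass(frozen=True)
class WeightGroups:
    """Partition of the flat weight vector into the n+3 ARD groups.

    Groups 0..n-1 hold feature k's connections to every hidden unit; group n
    the hidden biases; group n+1 the hidden-to-output weights; group n+2 the
    output bias. (The three extra groups follow the evidence-framework
    convention for a one-hidden-layer binary classifier.)
    """

    indices: tuple[np.ndarray, ...]
    n: int
    hidden_count: int

    @classmethod
    def for_network(cls, n: int, hidden_count: int) -> "WeightGroups":
        h = hidden_count
        groups = [np.arange(k, h * n, n) for k in range(n)]  # u[:, k] in row-major ravel
        groups.append(np.arange(h * n, h * n + h))  # hidden biases
        groups.append(np.arange(h * n + h, h * n + 2 * h))  # hidden -> output
        groups.append(np.array([h * n + 2 * h]))  # output bias
        return cls(indices=tuple(groups), n=n, hidden_count=h)

    def __len__(self) -> int:
        return len(self.indices)

    def sizes(self) -> np.ndarray:
        return np.array([len(g) for g in self.indices])

    def alpha_per_weight(self, alphas: np.ndarray) -> np.ndarray:
        """Expand per-group alphas to one decay coefficient per weight."""
        n_params = self.hidden_count * self.n + 2 * self.hidden_count + 1
        out = np.empty(n_params)
        for a, idx in zip(alphas, self.indices):
            out[idx] = a
        return out


@dataclass(frozen=True)
class HyperparameterSet:
    """Per-group decay hyperparameters alpha_k and well-determined counts gamma_k."""

    alphas: np.ndarray
    gammas: np.ndarray

    def __post_init__(self) -> None:
        alphas = np.asarray(self.alphas, dtype=float)
        gammas = np.asarray(self.gammas, dtype=float)
        if alphas.shape != gammas.shape or alphas.ndim != 1:
            raise ValueError("alphas and gammas must be equal-length vectors")
        if (alphas <= 0).any():
            raise ValueError("alphas must be positive")
        object.__setattr__(self, "alphas", alphas)
        object.__setattr__(self, "gammas", gammas)


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of the alternating optimization.

    ``inner_iters`` bounds each L-BFGS round; ``outer_cycles`` bounds the
    number of alpha re-estimations; the outer loop stops early when the
    largest relative alpha change drops below ``alpha_tol``.
    """

    hidden_count: int = 8
    inner_iters: int = 200
    outer_cycles: int = 20
    alpha_tol: float = 1e-3
    alpha_init: float = 0.01
    alpha_max: float = 1e6
    alpha_min: float = 0.1
    init_scale: float | None = None  # None -> 1/sqrt(fan-in) per layer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_count < 1 or self.inner_iters < 1 or self.outer_cycles < 1:
            raise ValueError("budgets must be >= 1")
        if self.alpha_tol <= 0 or self.alpha_init <= 0 or self.alpha_max <= 0:
            raise ValueError("tolerances and alpha bounds must be positive")


def initialize_model(n: int, config: TrainConfig) -> MLPARDModel:
    """Zero biases; weights uniform(-r, r) with r = 1/sqrt(fan-in), seeded."""
    rng = np.random.default_rng([config.seed, _STREAM_INIT])
    h = config.hidden_count
    r_u = config.init_scale if config.init_scale is not None else 1.0 / np.sqrt(n)
    r_v = config.init_scale if config.init_scale is not None else 1.0 / np.sqrt(h)
    u = rng.uniform(-r_u, r_u, size=(h, n))
    v = rng.uniform(-r_v, r_v, size=h)
    return MLPARDModel(u=u, b1=np.zeros(h), v=v, b2=0.0)


# ---------------------------------------------------------------------------
# forward pass and objective
# ---------------------------------------------------------------------------


def _sigmoid(a: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(a, dtype=float)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    return out


def forward(model: MLPARDModel, x: np.ndarray) -> np.ndarray | float:
    """Network output p(t=1|x) for one sample (n,) or a batch (N, n)."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = np.atleast_2d(x)
    if X.shape[1] != model.n:
        raise ValueError(f"expected {model.n} features, got {X.shape[1]}")
    h = np.tanh(X @ model.u.T + model.b1)
    y = _sigmoid(h @ model.v + model.b2)
    return float(y[0]) if single else y


def cross_entropy(model: MLPARDModel, dataset: PixelDataset) -> float:
    """Negative Bernoulli log-likelihood G with predictions clipped in logs."""
    y = np.clip(forward(model, dataset.features), EPS_CLIP, 1.0 - EPS_CLIP)
    t = dataset.labels.astype(float)
    return float(-np.sum(t * np.log(y) + (1.0 - t) * np.log(1.0 - y)))


def group_penalty(model: MLPARDModel, groups: WeightGroups, k: int) -> float:
    """E_w(k): half the sum of squared weights in group k."""
    if not (0 <= k < len(groups)):
        raise IndexError(f"group index {k} out of range (0..{len(groups) - 1})")
    w = model.to_vector()
    return float(0.5 * np.sum(w[groups.indices[k]] ** 2))


def objective(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    dataset: PixelDataset,
    *,
    allow_zero_alphas: bool = False,
) -> float:
    """F = G + sum_k alpha_k E_w(k)."""
    alphas = np.asarray(alphas, dtype=float)
    if (alphas < 0).any() or (not allow_zero_alphas and (alphas == 0).any()):
        raise ValueError("alphas must be positive")
    g = cross_entropy(model, dataset)
    penalty = sum(a * group_penalty(model, groups, k) for k, a in enumerate(alphas))
    return g + float(penalty)


def objective_gradient(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    dataset: PixelDataset,
) -> np.ndarray:
    """Analytic gradient of F over the flat weight vector (backpropagation)."""
    X = dataset.features
    t = dataset.labels.astype(float)
    h = np.tanh(X @ model.u.T + model.b1)  # (N, H)
    y = _sigmoid(h @ model.v + model.b2)
    r = y - t  # dG/da for logistic output + cross-entropy
    g_v = r @ h
    g_b2 = r.sum()
    delta = (r[:, None] * model.v[None, :]) * (1.0 - h * h)  # (N, H)
    g_u = delta.T @ X
    g_b1 = delta.sum(axis=0)
    grad = np.concatenate([g_u.ravel(), g_b1, g_v, [g_b2]])
    grad += groups.alpha_per_weight(np.asarray(alphas, dtype=float)) * model.to_vector()
    return grad


# ---------------------------------------------------------------------------
# Hessian of F (exact, with a Gauss-Newton variant)
# ---------------------------------------------------------------------------


def _network_jacobian(model: MLPARDModel, X: np.ndarray):
    """da/dw per sample plus the intermediate quantities the Hessian reuses."""
    N = X.shape[0]
    H = model.hidden_count
    n = model.n
    hid = np.tanh(X @ model.u.T + model.b1)  # (N, H)
    q = 1.0 - hid * hid  # tanh'
    vq = model.v[None, :] * q  # (N, H)
    J = np.empty((N, model.n_params))
    J[:, : H * n] = (vq[:, :, None] * X[:, None, :]).reshape(N, H * n)
    J[:, H * n : H * n + H] = vq
    J[:, H * n + H : H * n + 2 * H] = hid
    J[:, -1] = 1.0
    return J, hid, q


def gauss_newton_hessian(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    dataset: PixelDataset,
) -> np.ndarray:
    """Outer-product approximation J^T diag(y(1-y)) J + diag(alpha); positive definite."""
    X = dataset.features
    J, hid, _ = _network_jacobian(model, X)
    y = _sigmoid(hid @ model.v + model.b2)
    s = y * (1.0 - y)
    A = (J * s[:, None]).T @ J
    A[np.diag_indices_from(A)] += groups.alpha_per_weight(np.asarray(alphas, dtype=float))
    return A


def objective_hessian(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    dataset: PixelDataset,
) -> np.ndarray:
    """Exact Hessian of F: Gauss-Newton term plus the network-curvature term.

    With a = v.tanh(u x + b1) + b2 and residual r = y - t,

        d2F = sum_i [ y_i(1-y_i) J_i J_i^T + r_i d2a_i ] + diag(alpha)

    where d2a couples, per hidden unit j, the block (u_j, b1_j) with itself
    (through tanh curvature) and with v_j (through tanh').
    """
    X = dataset.features
    t = dataset.labels.astype(float)
    N, n = X.shape
    H = model.hidden_count
    J, hid, q = _network_jacobian(model, X)
    y = _sigmoid(hid @ model.v + model.b2)
    s = y * (1.0 - y)
    r = y - t
    A = (J * s[:, None]).T @ J

    p = -2.0 * hid * q  # tanh''
    Xt = np.hstack([X, np.ones((N, 1))])  # x with a 1 appended for the bias
    idx_b1 = H * n + np.arange(H)
    idx_v = H * n + H + np.arange(H)
    for j in range(H):
        wj = np.concatenate([np.arange(j * n, (j + 1) * n), [idx_b1[j]]])
        block = model.v[j] * ((r * p[:, j])[:, None] * Xt).T @ Xt  # (n+1, n+1)
        A[np.ix_(wj, wj)] += block
        cross = (r * q[:, j]) @ Xt  # (n+1,)
        A[wj, idx_v[j]] += cross
        A[idx_v[j], wj] += cross
    A[np.diag_indices_from(A)] += groups.alpha_per_weight(np.asarray(alphas, dtype=float))
    return A


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def train_inner(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    train_set: PixelDataset,
    config: TrainConfig,
) -> tuple[MLPARDModel, list[float]]:
    """Minimize F over the weights at fixed alphas (deterministic batch L-BFGS).

    Returns the updated model and the trace of F at the accepted iterates
    (starting value included). The returned weights never have a larger F
    than the starting ones.
    """
    n, h = model.n, model.hidden_count
    w0 = model.to_vector()
    alphas = np.asarray(alphas, dtype=float)

    def fun(w: np.ndarray) -> tuple[float, np.ndarray]:
        m = MLPARDModel.from_vector(w, n, h)
        f = objective(m, groups, alphas, train_set)
        g = objective_gradient(m, groups, alphas, train_set)
        if not np.isfinite(f) or not np.isfinite(g).all():
            raise TrainingError(
                f"non-finite objective during optimization (F={f!r}, |w|={np.abs(w).max():.3g})"
            )
        return f, g

    trace = [fun(w0)[0]]

    def callback(w: np.ndarray) -> None:
        trace.append(fun(w)[0])

    res = optimize.minimize(
        fun,
        w0,
        jac=True,
        method="L-BFGS-B",
        callback=callback,
        options={"maxiter": config.inner_iters, "ftol": 1e-12, "gtol": 1e-8},
    )
    if np.isfinite(res.fun) and res.fun <= trace[0]:
        w_final, f_final = res.x, float(res.fun)
    else:  # line search failed immediately; keep the incoming weights
        w_final, f_final = w0, trace[0]
    trace.append(f_final)
    return MLPARDModel.from_vector(w_final, n, h), trace


def reestimate_alphas(
    model: MLPARDModel,
    groups: WeightGroups,
    alphas: np.ndarray,
    train_set: PixelDataset,
    *,
    alpha_max: float = 1e6,
    alpha_min: float = 0.1,
    hessian: str = "exact",
) -> HyperparameterSet:
    """Evidence-framework update of the decay hyperparameters.

    gamma_k = |W(k)| - alpha_k trace_k(A^-1), alpha_k <- gamma_k / (2 E_w(k)),
    with A the (exact) Hessian of F at the current weights. If A is not
    positive definite the Gauss-Newton approximation is used instead (it is
    positive definite whenever all alphas are positive). gamma is clamped to
    [0, |W(k)|] and alpha to [alpha_min, alpha_max]; a group whose penalty
    has collapsed to zero gets alpha_max (its weights are fully suppressed).
    """
    alphas = np.asarray(alphas, dtype=float)
    sizes = groups.sizes().astype(float)

    def _trace_gammas(A: np.ndarray) -> np.ndarray | None:
        """Raw gamma_k from A via Cholesky solves; None if A is not PD."""
        try:
            cho = linalg.cho_factor(A)
        except linalg.LinAlgError:
            return None
        a_inv_diag = np.diag(linalg.cho_solve(cho, np.eye(A.shape[0])))
        return np.array(
            [sizes[k] - alphas[k] * float(a_inv_diag[idx].sum()) for k, idx in enumerate(groups.indices)]
        )

    raw = None
    if hessian == "exact":
        raw = _trace_gammas(objective_hessian(model, groups, alphas, train_set))
        if raw is not None and (raw < 0).any():
            # negative well-determined counts mean the Laplace curvature is
            # not valid at these weights (optimizer stopped short of the
            # minimum); the outer-product form keeps gamma in [0, |W(k)|]
            raw = None
        if raw is None:
            warnings.warn(
                "exact Hessian unusable at these weights; using Gauss-Newton curvature",
                RuntimeWarning,
                stacklevel=2,
            )
    elif hessian != "gauss-newton":
        raise ValueError("hessian must be 'exact' or 'gauss-newton'")
    if raw is None:
        raw = _trace_gammas(gauss_newton_hessian(model, groups, alphas, train_set))
        if raw is None:
            raise TrainingError("Gauss-Newton curvature not positive definite")

    new_alphas = np.empty(len(groups))
    gammas = np.empty(len(groups))
    for k, idx in enumerate(groups.indices):
        gamma = float(np.clip(raw[k], 0.0, sizes[k]))
        gammas[k] = gamma
        e_w = group_penalty(model, groups, k)
        if gamma <= 0.0 or e_w <= 1e-300:
            # no well-determined parameters (or fully collapsed weights):
            # the prior takes over and the group is suppressed outright
            new_alphas[k] = alpha_max
        else:
            new_alphas[k] = float(np.clip(gamma / (2.0 * e_w), alpha_min, alpha_max))
    return HyperparameterSet(alphas=new_alphas, gammas=gammas)


@dataclass(frozen=True)
class FitResult:
    model: MLPARDModel
    hyperparameters: HyperparameterSet
    groups: WeightGroups
    trace: list[dict] = field(repr=False)
    converged: bool = False


def fit(train_set: PixelDataset, config: TrainConfig | None = None) -> FitResult:
    """Alternate weight optimization and alpha re-estimation.

    Runs up to ``config.outer_cycles`` rounds of (L-BFGS at fixed alphas,
    evidence update of alphas), stopping early when the alphas settle. The
    trace records G, F, per-group alpha, gamma and E_w after every cycle.
    Deterministic for a fixed config seed.
    """
    if config is None:
        config = TrainConfig()
    pos, neg = train_set.class_counts()
    if pos == 0 or neg == 0:
        raise ValueError("training set must contain both classes")
    n = train_set.n_features
    groups = WeightGroups.for_network(n, config.hidden_count)
    model = initialize_model(n, config)
    alphas = np.full(len(groups), config.alpha_init)
    gammas = np.full(len(groups), np.nan)
    trace: list[dict] = []
    converged = False
    for cycle in range(config.outer_cycles):
        model, _ = train_inner(model, groups, alphas, train_set, config)
        hp = reestimate_alphas(
            model,
            groups,
            alphas,
            train_set,
            alpha_max=config.alpha_max,
            alpha_min=config.alpha_min,
        )
        rel_change = np.max(np.abs(hp.alphas - alphas) / alphas)
        row = {
            "cycle": cycle,
            "G": cross_entropy(model, train_set),
            "F": objective(model, groups, hp.alphas, train_set),
            "max_rel_alpha_change": float(rel_change),
        }
        for k in range(len(groups)):
            row[f"alpha_{k}"] = float(hp.alphas[k])
            row[f"gamma_{k}"] = float(hp.gammas[k])
            row[f"E_w_{k}"] = group_penalty(model, groups, k)
        trace.append(row)
        alphas, gammas = hp.alphas, hp.gammas
        if rel_change < config.alpha_tol:
            converged = True
            break
    # final polish of the weights at the settled alphas
    model, _ = train_inner(model, groups, alphas, train_set, config)
    return FitResult(
        model=model,
        hyperparameters=HyperparameterSet(alphas=alphas, gammas=gammas),
        groups=groups,
        trace=trace,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


def save_model(
    path: str | Path,
    model: MLPARDModel,
    hyperparameters: HyperparameterSet,
    standardization: StandardizationParams | None = None,
    config: TrainConfig | None = None,
) -> None:
    """Write the model as JSON. Floats survive the round trip bit-exactly
    (json uses repr, the shortest exact decimal representation)."""
    groups = WeightGroups.for_network(model.n, model.hidden_count)
    payload = {
        "format": "silymap-mlp-ard-1",
        "n_features": model.n,
        "hidden_count": model.hidden_count,
        "u": model.u.tolist(),
        "b1": model.b1.tolist(),
        "v": model.v.tolist(),
        "b2": model.b2,
        "groups": [g.tolist() for g in groups.indices],
        "alphas": hyperparameters.alphas.tolist(),
        "gammas": [None if np.isnan(g) else g for g in hyperparameters.gammas],
        "standardization": None
        if standardization is None
        else {"location": standardization.location.tolist(), "scale": standardization.scale.tolist()},
        "config": None if config is None else vars(config).copy(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path: str | Path):
    """Read a saved model; returns (model, hyperparameters, standardization, config)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "silymap-mlp-ard-1":
        raise ValueError("unrecognized model file format")
    model = MLPARDModel(
        u=np.array(payload["u"], dtype=float),
        b1=np.array(payload["b1"], dtype=float),
        v=np.array(payload["v"], dtype=float),
        b2=payload["b2"],
    )
    gammas = np.array([np.nan if g is None else g for g in payload["gammas"]], dtype=float)
    hp = HyperparameterSet(alphas=np.array(payload["alphas"], dtype=float), gammas=gammas)
    std = None
    if payload["standardization"] is not None:
        std = StandardizationParams(
            location=np.array(payload["standardization"]["location"], dtype=float),
            scale=np.array(payload["standardization"]["scale"], dtype=float),
        )
    config = None if payload["config"] is None else TrainConfig(**payload["config"])
    return model, hp, std, config
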