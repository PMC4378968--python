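"""Fuzzy standard additive model (SAM) with sinc rule sets.

A SAM approximator F: R^p -> R holds m if-then rules. Rule j has a
factorable if-part set with sinc set functions centered at m_jk with
width d_jk, and a then-part set summarized by its centroid c_j and volume
V_j, plus a rule weight w_j. Inference is the convex combination

    F(x) = sum_j w_j a_j(x) V_j c_j / sum_j w_j a_j(x) V_j

Structure comes from fuzzy c-means clustering of the joint input-output
observations; parameters are then tuned by incremental gradient descent
with momentum on the squared prediction error. Sinc side lobes make
a_j(x) (and the denominator) possibly negative; the raw values are kept,
with a guarded fallback when the denominator vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FuzzyRule",
    "FSAMModel",
    "TrainConfig",
    "sinc",
    "sinc_derivative",
    "joint_firing",
    "fsam_output",
    "fuzzy_c_means",
    "fcm_initialize",
    "gradient_step",
    "train_supervised",
    "classify",
]

WIDTH_FLOOR_FRACTION = 1e-3  # of the per-dimension data range
DENOMINATOR_GUARD = 1e-12
POSITIVE_FLOOR = 1e-6  # for volumes and weights after updates


def sinc(u):
    """sin(u)/u with the removable singularity sinc(0) = 1."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-8
    safe = np.where(small, 1.0, u)
    out = np.where(small, 1.0 - u * u / 6.0, np.sin(safe) / safe)
    return out if out.ndim else float(out)


def sinc_derivative(u):
    """d/du [sin(u)/u] = cos(u)/u - sin(u)/u^2; series near 0: -u/3."""
    u = np.asarray(u, dtype=float)
    small = np.abs(u) < 1e-6
    safe = np.where(small, 1.0, u)
    out = np.where(
        small,
        -u / 3.0 + u**3 / 30.0,
        np.cos(safe) / safe - np.sin(safe) / safe**2,
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FuzzyRule:
    """One SAM rule: if-part sinc centers/widths, then-part (c, V), weight."""

    centers: np.ndarray
    widths: np.ndarray
    centroid: float
    volume: float = 1.0
    weight: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "centers", np.asarray(self.centers, float))
        object.__setattr__(self, "widths", np.asarray(self.widths, float))
        if self.centers.shape != self.widths.shape:
            raise ValueError("centers and widths must have equal shape")
        if (self.widths <= 0).any():
            raise ValueError("widths must be positive")
        if self.volume <= 0 or self.weight <= 0:
            raise ValueError("volume and weight must be positive")


@dataclass(frozen=True)
class FSAMModel:
    """Ordered rule list plus the classification threshold."""

    rules: tuple[FuzzyRule, ...]
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "rules", tuple(self.rules))
        if not self.rules:
            raise ValueError("model needs at least one rule")
        p = self.rules[0].centers.size
        if any(r.centers.size != p for r in self.rules):
            raise ValueError("all rules must share the input dimension")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @property
    def input_dim(self) -> int:
        return self.rules[0].centers.size

    # --- flat parameter views used by training -------------------------
    def as_arrays(self):
        m = np.stack([r.centers for r in self.rules])
        d = np.stack([r.widths for r in self.rules])
        c = np.array([r.centroid for r in self.rules])
        v = np.array([r.volume for r in self.rules])
        w = np.array([r.weight for r in self.rules])
        return m, d, c, v, w

    @staticmethod
    def from_arrays(m, d, c, v, w, threshold=0.5, metadata=None):
        rules = tuple(
            FuzzyRule(m[j], d[j], float(c[j]), float(v[j]), float(w[j]))
            for j in range(len(c))
        )
        return FSAMModel(rules, threshold, metadata or {})

    def to_dict(self) -> dict:
        """JSON-serializable description (versioned schema)."""
        return {
            "schema": "fsam-rules/1",
            "threshold": self.threshold,
            "rules": [
                {
                    "centers": r.centers.tolist(),
                    "widths": r.widths.tolist(),
                    "centroid": r.centroid,
                    "volume": r.volume,
                    "weight": r.weight,
                }
                for r in self.rules
            ],
            "metadata": self.metadata,
        }

    @staticmethod
    def from_dict(doc: dict) -> "FSAMModel":
        if doc.get("schema") != "fsam-rules/1":
            raise ValueError(f"unsupported model schema {doc.get('schema')!r}")
        rules = [
            FuzzyRule(
                np.asarray(r["centers"]), np.asarray(r["widths"]),
                r["centroid"], r["volume"], r["weight"],
            )
            for r in doc["rules"]
        ]
        return FSAMModel(tuple(rules), doc["threshold"], doc.get("metadata", {}))


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent hyperparameters for supervised tuning."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    epochs: int = 200
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0 <= self.momentum < 1):
            raise ValueError("momentum must be in [0, 1)")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def joint_firing(rule: FuzzyRule, x) -> float:
    """Factored firing a_j(x) = prod_k sinc((x_k - m_jk)/d_jk); raw value."""
    x = np.asarray(x, dtype=float)
    if x.shape != rule.centers.shape:
        raise ValueError(
            f"input dim {x.shape} != rule dim {rule.centers.shape}"
        )
    return float(np.prod(sinc((x - rule.centers) / rule.widths)))


def _firing_matrix(m, d, X):
    """a[i, j] for samples i and rules j; X shape (N, p)."""
    u = (X[:, None, :] - m[None, :, :]) / d[None, :, :]
    return np.prod(sinc(u), axis=2)


def fsam_output(model: FSAMModel, x, return_weights: bool = False):
    """SAM inference F(x), optionally with the convex weights p_j(x).

    Near-zero denominators (side-lobe cancellation) fall back to the mean
    of the rule centroids.
    """
    x = np.asarray(x, dtype=float)
    m, d, c, v, w = model.as_arrays()
    a = _firing_matrix(m, d, x[None, :])[0]
    g = w * a * v
    den = g.sum()
    if abs(den) < DENOMINATOR_GUARD:
        f = float(c.mean())
        p = np.full(c.size, 1.0 / c.size)
    else:
        p = g / den
        f = float(p @ c)
    return (f, p) if return_weights else f


def predict_batch(model: FSAMModel, X) -> np.ndarray:
    """Vectorized F(x) over the rows of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    m, d, c, v, w = model.as_arrays()
    a = _firing_matrix(m, d, X)
    g = a * (w * v)[None, :]
    den = g.sum(axis=1)
    num = g @ c
    out = np.where(np.abs(den) < DENOMINATOR_GUARD, c.mean(), num / np.where(
        np.abs(den) < DENOMINATOR_GUARD, 1.0, den))
    return out


# ----------------------------------------------------------------------
# Unsupervised structure learning: fuzzy c-means on (input, output) pairs
# ----------------------------------------------------------------------

def fuzzy_c_means(
    data: np.ndarray,
    n_clusters: int,
    fuzzifier: float = 2.0,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
):
    """Bezdek fuzzy c-means.

    Returns (centers, memberships) where memberships U has shape
    (N, C) with rows summing to 1. Iterates the alternating update of
    centers and memberships until the largest center shift is below
    ``tol`` or ``max_iter`` is reached. Fully seeded.
    """
    data = np.asarray(data, dtype=float)
    n, _ = data.shape
    if not 1 <= n_clusters <= n:
        raise ValueError(
            f"cluster count {n_clusters} must be in [1, {n}]"
        )
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    rng = np.random.default_rng(seed)
    u = rng.random((n, n_clusters)) + 1e-3
    u /= u.sum(axis=1, keepdims=True)
    power = 2.0 / (fuzzifier - 1.0)
    centers = np.zeros((n_clusters, data.shape[1]))
    for _ in range(max_iter):
        um = u**fuzzifier
        new_centers = (um.T @ data) / um.sum(axis=0)[:, None]
        d2 = ((data[:, None, :] - new_centers[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-power / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break
    return centers, u


def fcm_initialize(
    X,
    y,
    n_clusters: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    threshold: float = 0.5,
) -> FSAMModel:
    """Build an initial rule base by clustering joint (x, y) observations.

    Each cluster becomes a rule: the input part of the cluster center is
    the sinc center vector, the output part the then-part centroid, and
    the widths are the membership-weighted standard deviation of the
    members per dimension (floored at 1e-3 of the dimension's range).
    Volumes and weights start at 1. Clusters that attract essentially no
    membership are dropped.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    joint = np.column_stack([X, y])
    centers, u = fuzzy_c_means(joint, n_clusters, fuzzifier, seed=seed)

    p = X.shape[1]
    ranges = np.ptp(X, axis=0)
    floor = WIDTH_FLOOR_FRACTION * np.where(ranges > 0, ranges, 1.0)

    rules = []
    um = u**fuzzifier
    mass = um.sum(axis=0)
    for j in range(centers.shape[0]):
        if mass[j] < 1e-9:  # empty cluster
            continue
        mj = centers[j, :p]
        cj = float(centers[j, p])
        var = (um[:, j][:, None] * (X - mj) ** 2).sum(axis=0) / mass[j]
        dj = np.maximum(np.sqrt(var), floor)
        rules.append(FuzzyRule(mj, dj, cj))
    if not rules:
        raise ValueError("fuzzy c-means produced no populated clusters")
    return FSAMModel(
        tuple(rules),
        threshold=threshold,
        metadata={"init": "fcm", "seed": int(seed), "fuzzifier": fuzzifier},
    )


# ----------------------------------------------------------------------
# Supervised parameter tuning: incremental gradient descent + momentum
# ----------------------------------------------------------------------

_PARAM_KEYS = ("m", "d", "c", "v", "w")


def _zero_velocity(model: FSAMModel) -> dict[str, np.ndarray]:
    m, d, c, v, w = model.as_arrays()
    return {
        "m": np.zeros_like(m),
        "d": np.zeros_like(d),
        "c": np.zeros_like(c),
        "v": np.zeros_like(v),
        "w": np.zeros_like(w),
    }


def _gradients(m, d, c, v, w, x, y):
    """Analytic partials of E = 1/2 (y - F(x))^2 w.r.t. all parameters.

    Chain rule through the SAM quotient: with g_j = w_j a_j V_j and
    D = sum g_j, dF/dg_j = (c_j - F)/D, dE/dF = F - y.
    Returns None when the denominator is inside the guard band (the
    fallback output is piecewise constant there, gradient undefined).
    """
    u = (x[None, :] - m) / d
    s = sinc(u)
    a = np.prod(s, axis=1)
    g = w * a * v
    den = g.sum()
    if abs(den) < DENOMINATOR_GUARD:
        return None
    f = (g @ c) / den
    err = f - y
    df_dg = (c - f) / den

    # partial of a_j w.r.t. u_jk: derivative of one sinc factor times the rest
    with np.errstate(divide="ignore", invalid="ignore"):
        others = np.where(np.abs(s) > 1e-300, a[:, None] / s, 0.0)
    # recompute exactly where a factor is ~0 (product of the others)
    bad = np.abs(s) <= 1e-300
    if bad.any():
        for j, k in zip(*np.nonzero(bad)):
            others[j, k] = np.prod(np.delete(s[j], k))
    da_du = sinc_derivative(u) * others

    dg_da = w * v
    # du/dm = -1/d ; du/dd = -u/d  (elementwise per (j, k))
    grad_m = (err * df_dg * dg_da)[:, None] * da_du * (-1.0 / d)
    grad_d = (err * df_dg * dg_da)[:, None] * da_du * (-u / d)
    grad_c = err * g / den
    grad_v = err * df_dg * w * a
    grad_w = err * df_dg * a * v
    return {"m": grad_m, "d": grad_d, "c": grad_c, "v": grad_v, "w": grad_w}


def gradient_step(
    model: FSAMModel,
    x,
    y: float,
    cfg: TrainConfig,
    velocity: dict[str, np.ndarray] | None = None,
    data_ranges: np.ndarray | None = None,
):
    """One incremental momentum update on a single (x, y) sample.

    ξ(t+1) = ξ(t) − μ ∂E/∂ξ + ε Δξ(t). Non-finite gradients (near a
    sinc-zero denominator) skip the affected parameter for this sample.
    Widths, volumes and weights are re-floored after the update.
    """
    x = np.asarray(x, dtype=float)
    if velocity is None:
        velocity = _zero_velocity(model)
    m, d, c, v, w = (arr.copy() for arr in model.as_arrays())
    grads = _gradients(m, d, c, v, w, x, float(y))
    if grads is None:
        return model, velocity
    params = {"m": m, "d": d, "c": c, "v": v, "w": w}
    for key in _PARAM_KEYS:
        grad = grads[key]
        ok = np.isfinite(grad)
        delta = np.where(ok, -cfg.learning_rate * grad, 0.0) \
            + cfg.momentum * velocity[key]
        params[key] = params[key] + delta
        velocity[key] = delta

    if data_ranges is None:
        data_ranges = np.ones(model.input_dim)
    floor = WIDTH_FLOOR_FRACTION * np.where(data_ranges > 0, data_ranges, 1.0)
    params["d"] = np.maximum(params["d"], floor)
    params["v"] = np.maximum(params["v"], POSITIVE_FLOOR)
    params["w"] = np.maximum(params["w"], POSITIVE_FLOOR)
    new_model = FSAMModel.from_arrays(
        params["m"], params["d"], params["c"], params["v"], params["w"],
        threshold=model.threshold, metadata=model.metadata,
    )
    return new_model, velocity


def train_supervised(model: FSAMModel, X, y, cfg: TrainConfig):
    """Tune all rule parameters by per-sample gradient descent.

    Samples are reshuffled every epoch (seeded); the model with the lowest
    epoch-mean squared error ever seen is returned together with the
    per-epoch error trace.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    ranges = np.ptp(X, axis=0)
    velocity = _zero_velocity(model)
    best_model, best_err = model, float(np.mean((predict_batch(model, X) - y) ** 2))
    trace = []
    current = model
    for _ in range(cfg.epochs):
        order = rng.permutation(len(y))
        for i in order:
            current, velocity = gradient_step(
                current, X[i], y[i], cfg, velocity, ranges
            )
        err = float(np.mean((predict_batch(current, X) - y) ** 2))
        trace.append(err)
        if err < best_err:
            best_model, best_err = current, err
    meta = dict(best_model.metadata)
    meta.update({"epochs": cfg.epochs, "train_seed": int(cfg.seed),
                 "train_mse": best_err})
    return replace(best_model, metadata=meta), trace


def classify(model: FSAMModel, x) -> tuple[int, float]:
    """Threshold F(x) into a 0/1 label; the boundary goes to class 1."""
    score = fsam_output(model, x)
    return (1 if score >= model.threshold else 0), score
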