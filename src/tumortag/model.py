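"""The feature-extraction + classification network and its decision rule.

The network is deliberately simple: three fully connected layers with no
nonlinear activations between them — FC1 (input -> hidden1, hidden1 defaulting
to the input width), a dropout layer, FC2 (hidden1 -> 512 bottleneck), and a
classification layer (bottleneck -> c classes, c = 2 for malignant vs
non-malignant). A softmax value computed from the two class scores,

    softmax = exp(g_malignant) / sum_i exp(g_i),

is thresholded (strictly greater than, default 0.5) to call a cell or spot
malignant. Because there are no activations the composed map is affine, which
makes inference a single matrix product chain and makes gradient-based
interpretability exact.

Implemented in numpy: forward passes, and an analytic backward pass used by
the training loop and the saliency module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MALIGNANT = 1  # class index / label convention: 1 = malignant
NON_MALIGNANT = 0

CALL_MALIGNANT = "malignant"
CALL_NON_MALIGNANT = "non_malignant"


@dataclass
class ModelSpec:
    """Architecture hyper-parameters.

    hidden1_dim defaults to input_dim (first layer keeps one neuron per
    selected gene); bottleneck_dim defaults to 512; dropout (p = 0.5) sits
    between FC1 and FC2 and is active only in train mode.
    """

    input_dim: int
    hidden1_dim: int | None = None
    bottleneck_dim: int = 512
    n_classes: int = 2
    dropout_p: float = 0.5

    def __post_init__(self) -> None:
        if self.hidden1_dim is None:
            self.hidden1_dim = self.input_dim
        for name in ("input_dim", "hidden1_dim", "bottleneck_dim", "n_classes"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden1_dim": self.hidden1_dim,
            "bottleneck_dim": self.bottleneck_dim,
            "n_classes": self.n_classes,
            "dropout_p": self.dropout_p,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)


@dataclass
class ModelState:
    """Trained (or initialized) parameters plus everything inference needs:
    the ordered feature list, the preprocessing config to replay, and the
    decision threshold."""

    spec: ModelSpec
    params: dict[str, np.ndarray]
    feature_list: list[str] | None = None
    preprocess: dict = field(default_factory=dict)
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def validate_shapes(self) -> None:
        s = self.spec
        expected = {
            "W1": (s.input_dim, s.hidden1_dim),
            "b1": (s.hidden1_dim,),
            "W2": (s.hidden1_dim, s.bottleneck_dim),
            "b2": (s.bottleneck_dim,),
            "W3": (s.bottleneck_dim, s.n_classes),
            "b3": (s.n_classes,),
        }
        for k, shape in expected.items():
            if self.params[k].shape != shape:
                raise ValueError(
                    f"parameter {k} has shape {self.params[k].shape}, expected {shape}"
                )

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def n_parameters(self) -> int:
        return sum(v.size for v in self.params.values())


INIT_SCALE = 0.1


def init_model(spec: ModelSpec, seed: int) -> ModelState:
    """Initialize the three affine layers with a scaled-uniform fan-in scheme:
    each layer's weights and biases are drawn
    U(-0.1/sqrt(fan_in), 0.1/sqrt(fan_in)). Fully determined by ``seed``.

    The small scale is deliberate: the composed network is affine, so no
    symmetry breaking is needed, and keeping the random component of the
    effective input->score map small means the trained map — and hence the
    saliency attribution — is dominated by what was learned from data rather
    than by initialization noise.
    """
    rng = np.random.default_rng(seed)
    dims = [
        (spec.input_dim, spec.hidden1_dim),
        (spec.hidden1_dim, spec.bottleneck_dim),
        (spec.bottleneck_dim, spec.n_classes),
    ]
    params: dict[str, np.ndarray] = {}
    for i, (fan_in, fan_out) in enumerate(dims, start=1):
        bound = INIT_SCALE / np.sqrt(fan_in)
        params[f"W{i}"] = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        params[f"b{i}"] = rng.uniform(-bound, bound, size=fan_out)
    state = ModelState(spec=spec, params=params, metadata={"init_seed": int(seed)})
    state.validate_shapes()
    return state


# ---------------------------------------------------------------------------
# forward / backward
# ---------------------------------------------------------------------------

def _forward(params, X, dropout_p=0.0, rng=None):
    """Forward pass returning (scores, cache). Dropout (inverted: survivors
    rescaled by 1/(1-p) at train time) is applied only when ``rng`` is given
    and p > 0."""
    h1 = X @ params["W1"] + params["b1"]
    if rng is not None and dropout_p > 0.0:
        mask = (rng.random(h1.shape) >= dropout_p) / (1.0 - dropout_p)
    else:
        mask = None
    h1d = h1 if mask is None else h1 * mask
    h2 = h1d @ params["W2"] + params["b2"]
    g = h2 @ params["W3"] + params["b3"]
    cache = {"X": X, "mask": mask, "h1d": h1d, "h2": h2}
    return g, cache


def _backward(params, cache, dg):
    """Backpropagate d(loss)/d(scores) through the cached forward pass.
    Returns (gradients-by-parameter, d(loss)/d(input))."""
    grads: dict[str, np.ndarray] = {}
    grads["W3"] = cache["h2"].T @ dg
    grads["b3"] = dg.sum(axis=0)
    dh2 = dg @ params["W3"].T
    grads["W2"] = cache["h1d"].T @ dh2
    grads["b2"] = dh2.sum(axis=0)
    dh1d = dh2 @ params["W2"].T
    dh1 = dh1d if cache["mask"] is None else dh1d * cache["mask"]
    grads["W1"] = cache["X"].T @ dh1
    grads["b1"] = dh1.sum(axis=0)
    dX = dh1 @ params["W1"].T
    return grads, dX


def forward_scores(model: ModelState, X, mode: str = "infer", rng=None) -> np.ndarray:
    """Class scores g for a batch (cells x features).

    ``infer`` mode disables dropout and is deterministic; ``train`` mode drops
    each hidden1 unit independently with probability dropout_p and rescales
    survivors by 1/(1-p) (so inference needs no scaling). ``X`` columns must
    already be in the model's feature order.
    """
    X = _as_matrix(X)
    if X.shape[1] != model.spec.input_dim:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.spec.input_dim}"
        )
    if mode == "infer":
        g, _ = _forward(model.params, X)
    elif mode == "train":
        if rng is None and model.spec.dropout_p > 0:
            raise ValueError("train mode with dropout requires an rng")
        g, _ = _forward(model.params, X, model.spec.dropout_p, rng)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return g


def _as_matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=np.float64)


# ---------------------------------------------------------------------------
# softmax decision rule
# ---------------------------------------------------------------------------

def softmax_matrix(G: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    G = np.asarray(G, dtype=np.float64)
    if not np.isfinite(G).all():
        raise ValueError("non-finite score encountered")
    shifted = G - G.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_score(g, malignant_index: int = MALIGNANT) -> float:
    """The malignant-class softmax value exp(g_mal) / sum_i exp(g_i) for one
    score vector; shift-invariant and overflow-safe."""
    g = np.asarray(g, dtype=np.float64)
    if g.ndim != 1:
        raise ValueError("softmax_score expects a single score vector")
    return float(softmax_matrix(g[None, :])[0, malignant_index])


def classify(softmax_value: float, threshold: float = 0.5) -> str:
    """Call malignant iff the softmax value is strictly greater than the
    threshold (a value of exactly 0.5 is non-malignant at the default)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    if not (0.0 <= softmax_value <= 1.0):
        raise ValueError("softmax value outside [0, 1]")
    return CALL_MALIGNANT if softmax_value > threshold else CALL_NON_MALIGNANT


def predict(model: ModelState, X, threshold: float | None = None):
    """Convenience inference: scores -> softmax values -> calls.

    Returns (scores, softmax_values, calls-as-int-array) with 1 = malignant.
    """
    g = forward_scores(model, X, mode="infer")
    sm = softmax_matrix(g)[:, MALIGNANT]
    thr = model.threshold if threshold is None else threshold
    if not (0.0 < thr < 1.0):
        raise ValueError("threshold must lie strictly inside (0, 1)")
    calls = (sm > thr).astype(np.int64)
    return g, sm, calls
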