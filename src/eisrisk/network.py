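"""The Model_xl_yc_z classifier family.

Small feed-forward networks over the 28-feature impedance vector, optionally
preceded by two 1-D convolutional layers that act along the 14-frequency
axis with the real and reactive parts as two input channels — convolution
couples impedance values at adjacent frequencies, which is where the
physical information (dispersion shape) lives.

The family is indexed by the notation ``Model_<x>l_<y>c_<z>``:

* ``x`` — number of fully connected hidden layers (2 or 3),
* ``y`` — number of 1-D convolutional layers (0 or 2),
* ``z`` — neurons per hidden layer, mapped 1 -> 125, 2 -> 250.

Training minimises a class-weighted cross-entropy with an explicit L2
penalty over every weight and bias,

    Obj = - sum_c W_c y_c log(p_c) + (lambda/2) * sum_i w_i**2,

implemented inside the loss (not as optimizer weight decay) so the reported
objective value is auditable.  Optimisation is Adam with mini-batches and
optional early stopping on a validation set.  Everything is plain numpy;
the networks are small enough (tens of thousands of parameters) that a CPU
trains one in seconds.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from ._exceptions import FormatError, InvalidArgumentError

__all__ = [
    "ModelSpec",
    "ScoreSet",
    "parse_model_spec",
    "build_network",
    "weighted_loss",
    "ImpedanceNetClassifier",
    "train",
    "predict_scores",
    "MODEL_GRID",
]

_EPS = 1e-12  # log(0) guard: probabilities clamped to [1e-12, 1]
_NEURON_MAP = {1: 125, 2: 250}

#: The 8 architectures of the study's hyperparameter grid.
MODEL_GRID = tuple(
    f"Model_{x}l_{y}c_{z}" for x in (2, 3) for y in (0, 2) for z in (1, 2)
)


@dataclass(frozen=True)
class ModelSpec:
    """Parsed architecture descriptor plus loss hyperparameters."""

    name: str
    n_hidden_layers: int
    n_conv_layers: int
    n_neurons: int
    n_classes: int = 2
    class_weights: tuple[float, ...] | None = None
    l2_lambda: float = 0.01

    def __post_init__(self) -> None:
        if self.class_weights is not None:
            if len(self.class_weights) != self.n_classes:
                raise InvalidArgumentError(
                    "class_weights length must equal n_classes"
                )
            if any(w <= 0 for w in self.class_weights):
                raise InvalidArgumentError("class weights must be positive")
        if self.l2_lambda < 0:
            raise InvalidArgumentError("l2_lambda must be non-negative")

    @property
    def condition(self) -> str:
        """The 'W1:W2[:W3] lambda' condition tag used in report tables."""
        w = self.class_weights or (1.0,) * self.n_classes
        wtag = ":".join(f"{x:g}" for x in w)
        return f"{wtag} {self.l2_lambda:g}"


_NAME_RE = re.compile(r"^Model_(\d+)l_(\d+)c_(\d+)$")


def parse_model_spec(
    name: str,
    class_weights: tuple[float, ...] | None = None,
    l2_lambda: float = 0.01,
    n_classes: int = 2,
) -> ModelSpec:
    """Parse a ``Model_<x>l_<y>c_<z>`` notation string into a :class:`ModelSpec`.

    ``x`` and ``y`` are read literally; ``z`` maps 1 -> 125 and 2 -> 250
    neurons per hidden layer.  Values outside the family grid (x in {2,3},
    y in {0,2}, z in {1,2}) are a parse error.
    """
    m = _NAME_RE.match(re.sub(r"\s+", "", name))
    if m is None:
        raise InvalidArgumentError(f"malformed model name {name!r}")
    x, y, z = (int(g) for g in m.groups())
    if x not in (2, 3) or y not in (0, 2) or z not in _NEURON_MAP:
        raise InvalidArgumentError(
            f"model name {name!r} outside the family grid (x in 2/3, y in 0/2, z in 1/2)"
        )
    return ModelSpec(
        name=f"Model_{x}l_{y}c_{z}",
        n_hidden_layers=x,
        n_conv_layers=y,
        n_neurons=_NEURON_MAP[z],
        n_classes=n_classes,
        class_weights=tuple(class_weights) if class_weights is not None else None,
        l2_lambda=l2_lambda,
    )


# ---------------------------------------------------------------------------
# Layers (forward + backward), kept deliberately minimal.
# ---------------------------------------------------------------------------


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, scale: float):
        self.W = rng.standard_normal((d_in, d_out)) * scale
        self.b = np.zeros(d_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _Conv1d:
    """1-D convolution, stride 1, same (zero) padding, via im2col."""

    def __init__(
        self, c_in: int, c_out: int, k: int, rng: np.random.Generator
    ):
        scale = np.sqrt(2.0 / (c_in * k))  # He init for the ReLU that follows
        self.W = rng.standard_normal((c_in * k, c_out)) * scale
        self.b = np.zeros(c_out)
        self.c_in, self.c_out, self.k = c_in, c_out, k
        self.pad = (k - 1) // 2

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        # x: (B, C, L) -> (B, L, C*k)
        B, C, L = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        cols = np.stack([xp[:, :, j : j + L] for j in range(self.k)], axis=-1)
        # cols: (B, C, L, k) -> (B, L, C*k)
        return cols.transpose(0, 2, 1, 3).reshape(B, L, C * self.k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        self._cols = self._im2col(x)
        out = self._cols @ self.W + self.b  # (B, L, C_out)
        return out.transpose(0, 2, 1)  # (B, C_out, L)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, C, L = self._shape
        dy2 = dy.transpose(0, 2, 1)  # (B, L, C_out)
        self.dW = self._cols.reshape(-1, self.c_in * self.k).T @ dy2.reshape(
            -1, self.c_out
        )
        self.db = dy2.sum(axis=(0, 1))
        dcols = dy2 @ self.W.T  # (B, L, C*k)
        dcols = dcols.reshape(B, L, self.c_in, self.k).transpose(0, 2, 1, 3)
        dxp = np.zeros((B, C, L + 2 * self.pad))
        for j in range(self.k):
            dxp[:, :, j : j + L] += dcols[:, :, :, j]
        return dxp[:, :, self.pad : self.pad + L]

    def params(self):
        return [("W", self.W, "dW"), ("b", self.b, "db")]


class _ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask

    def params(self):
        return []


class _Reshape2ch:
    """(B, 28) -> (B, 2, 14): channel 0 real parts, channel 1 reactive parts."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._B = x.shape[0]
        return x.reshape(self._B, 2, 14)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._B, 28)

    def params(self):
        return []


class _Flatten:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def params(self):
        return []


class _Net:
    """A layer stack with softmax output and flat parameter access."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def param_arrays(self) -> list[np.ndarray]:
        return [arr for layer in self.layers for _, arr, _ in layer.params()]

    def grad_arrays(self) -> list[np.ndarray]:
        return [
            getattr(layer, gname)
            for layer in self.layers
            for _, _, gname in layer.params()
        ]

    def n_parameters(self) -> int:
        return int(sum(a.size for a in self.param_arrays()))

    def flat_parameters(self) -> np.ndarray:
        return np.concatenate([a.ravel() for a in self.param_arrays()])

    def set_flat_parameters(self, flat: np.ndarray) -> None:
        offset = 0
        for a in self.param_arrays():
            a[...] = flat[offset : offset + a.size].reshape(a.shape)
            offset += a.size

    def l2_penalty(self, lam: float) -> float:
        return 0.5 * lam * float(sum((a**2).sum() for a in self.param_arrays()))


def build_network(
    spec: ModelSpec,
    n_features: int = 28,
    random_state: int | np.random.Generator = 0,
    conv_channels: tuple[int, int] = (8, 16),
    kernel_size: int = 3,
) -> _Net:
    """Construct an untrained network for a spec; same seed -> identical init.

    With no convolutional layers the stack is
    input(28) -> x dense+ReLU hidden layers -> output(M, softmax).
    With two, the 28-vector is viewed as 2 channels (real, reactive) x 14
    frequencies, passed through two same-padded stride-1 convolutions with
    ReLU, flattened, and fed to the same dense stack.
    """
    rng = (
        random_state
        if isinstance(random_state, np.random.Generator)
        else np.random.default_rng(random_state)
    )
    layers: list = []
    d = n_features
    if spec.n_conv_layers:
        if n_features != 28:
            raise InvalidArgumentError("convolutional variants require 28 features")
        layers.append(_Reshape2ch())
        c_in = 2
        for c_out in conv_channels[: spec.n_conv_layers]:
            layers.append(_Conv1d(c_in, c_out, kernel_size, rng))
            layers.append(_ReLU())
            c_in = c_out
        layers.append(_Flatten())
        d = c_in * 14
    for _ in range(spec.n_hidden_layers):
        layers.append(_Dense(d, spec.n_neurons, rng, scale=np.sqrt(2.0 / d)))
        layers.append(_ReLU())
        d = spec.n_neurons
    layers.append(_Dense(d, spec.n_classes, rng, scale=np.sqrt(1.0 / d)))
    return _Net(layers)


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def weighted_loss(
    probs: np.ndarray,
    true_class: int,
    class_weights: tuple[float, ...] | None = None,
    l2_lambda: float = 0.0,
    parameters: np.ndarray | None = None,
) -> float:
    """Weighted cross-entropy plus L2 penalty for a single prediction.

    With all weights 1 and lambda 0 this is the standard cross-entropy
    -log(p_true).  The true-class probability is clamped below at 1e-12.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 1 or np.any(probs < -1e-9) or abs(probs.sum() - 1.0) > 1e-6:
        raise InvalidArgumentError("probs must be a probability vector")
    if not (0 <= true_class < probs.size):
        raise InvalidArgumentError("true_class out of range")
    w = 1.0 if class_weights is None else float(class_weights[true_class])
    ce = -w * np.log(np.clip(probs[true_class], _EPS, 1.0))
    pen = 0.0
    if l2_lambda and parameters is not None:
        pen = 0.5 * l2_lambda * float(np.sum(np.square(np.asarray(parameters, float))))
    return float(ce + pen)


@dataclass
class ScoreSet:
    """Per-reading class-probability vectors with their true labels."""

    probs: np.ndarray  # (n, M)
    y_true: np.ndarray  # (n,) string labels drawn from `classes`
    classes: tuple[str, ...]
    subject_ids: np.ndarray | None = None
    reading_ids: np.ndarray | None = None
    who_grades: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.y_true = np.asarray(self.y_true)
        if self.probs.ndim != 2 or self.probs.shape[1] != len(self.classes):
            raise InvalidArgumentError("probs must be (n, n_classes)")
        if self.probs.shape[0] != self.y_true.shape[0]:
            raise InvalidArgumentError("probs and y_true length mismatch")
        if np.any(self.probs < -1e-9) or np.any(
            np.abs(self.probs.sum(axis=1) - 1.0) > 1e-6
        ):
            raise InvalidArgumentError("rows of probs must sum to 1")

    def __len__(self) -> int:
        return int(self.probs.shape[0])

    def y_index(self) -> np.ndarray:
        """Integer-coded labels in `classes` order."""
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[c] for c in self.y_true])

    def column(self, class_label: str) -> np.ndarray:
        return self.probs[:, self.classes.index(class_label)]


class ImpedanceNetClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn estimator for the Model_xl_yc_z network family.

    Parameters
    ----------
    model_name : str
        Architecture in ``Model_<x>l_<y>c_<z>`` notation.
    class_weights : sequence of float, dict, or None
        Per-class loss weights W_c, ordered like ``classes_`` (sorted label
        order) or keyed by label.  None means all ones.
    l2_lambda : float
        L2 penalty factor lambda, applied to every weight and bias inside
        the loss.
    learning_rate, batch_size, max_epochs : Adam settings.
    patience : int
        Early-stopping patience in epochs, used only when a validation set
        is passed to :meth:`fit`.
    standardize : bool
        Per-feature z-scoring fitted on the training data only (impedance
        magnitudes span decades across frequency).
    random_state : int or None
        Seeds initialisation and batch shuffling; fixed seed gives
        bit-identical training runs.
    """

    def __init__(
        self,
        model_name: str = "Model_2l_2c_1",
        class_weights=None,
        l2_lambda: float = 0.01,
        learning_rate: float = 1e-3,
        batch_size: int = 16,
        max_epochs: int = 300,
        patience: int = 30,
        standardize: bool = True,
        conv_channels: tuple[int, int] = (8, 16),
        kernel_size: int = 3,
        random_state: int | None = None,
    ):
        self.model_name = model_name
        self.class_weights = class_weights
        self.l2_lambda = l2_lambda
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.standardize = standardize
        self.conv_channels = conv_channels
        self.kernel_size = kernel_size
        self.random_state = random_state

    # -- internals ---------------------------------------------------------

    def _resolve_weights(self) -> np.ndarray:
        if self.class_weights is None:
            return np.ones(len(self.classes_))
        if isinstance(self.class_weights, dict):
            try:
                w = np.array([float(self.class_weights[c]) for c in self.classes_])
            except KeyError as exc:
                raise InvalidArgumentError(f"class_weights missing class {exc}") from exc
        else:
            w = np.asarray(self.class_weights, dtype=float)
            if w.shape != (len(self.classes_),):
                raise InvalidArgumentError(
                    f"class_weights must have length {len(self.classes_)}"
                )
        if np.any(w <= 0):
            raise InvalidArgumentError("class weights must be positive")
        return w

    def _objective(self, X: np.ndarray, y_idx: np.ndarray, w: np.ndarray) -> float:
        probs = _softmax(self._net.forward(X))
        ce = -np.mean(
            w[y_idx] * np.log(np.clip(probs[np.arange(len(y_idx)), y_idx], _EPS, 1.0))
        )
        return float(ce + self._net.l2_penalty(self.l2_lambda))

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        """Train the network; fits the feature scaler on X only.

        When ``X_val``/``y_val`` are given, training stops early once the
        validation cross-entropy has not improved for ``patience`` epochs,
        restoring the best parameters seen.
        """
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise InvalidArgumentError("training data contains a single class")
        self.n_features_in_ = X.shape[1]
        spec = parse_model_spec(
            self.model_name, l2_lambda=self.l2_lambda, n_classes=len(self.classes_)
        )
        w = self._resolve_weights()
        self.spec_ = ModelSpec(
            name=spec.name,
            n_hidden_layers=spec.n_hidden_layers,
            n_conv_layers=spec.n_conv_layers,
            n_neurons=spec.n_neurons,
            n_classes=len(self.classes_),
            class_weights=tuple(w),
            l2_lambda=self.l2_lambda,
        )
        lookup = {c: i for i, c in enumerate(self.classes_)}
        y_idx = np.array([lookup[v] for v in y])

        if self.standardize:
            self.scaler_ = StandardScaler().fit(X)
            Xs = self.scaler_.transform(X)
        else:
            self.scaler_ = None
            Xs = X
        if X_val is not None:
            Xv = check_array(X_val, dtype=float)
            if Xv.shape[1] != self.n_features_in_:
                raise FormatError("validation feature width mismatch")
            Xv = self.scaler_.transform(Xv) if self.scaler_ is not None else Xv
            yv_idx = np.array([lookup[v] for v in np.asarray(y_val)])

        rng = np.random.default_rng(self.random_state)
        self._net = build_network(
            self.spec_,
            n_features=self.n_features_in_,
            random_state=rng,
            conv_channels=self.conv_channels,
            kernel_size=self.kernel_size,
        )
        self.n_parameters_ = self._net.n_parameters()

        params = self._net.param_arrays()
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        t = 0
        b1, b2, eps = 0.9, 0.999, 1e-8
        n = Xs.shape[0]
        best_val = np.inf
        best_flat = None
        stall = 0
        self.loss_curve_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = Xs[idx], y_idx[idx]
                probs = _softmax(self._net.forward(xb))
                onehot = np.zeros_like(probs)
                onehot[np.arange(len(yb)), yb] = 1.0
                dlogits = (w[yb][:, None] * (probs - onehot)) / len(yb)
                self._net.backward(dlogits)
                grads = self._net.grad_arrays()
                t += 1
                for p, g, mi, vi in zip(params, grads, m, v):
                    g = g + self.l2_lambda * p
                    mi[...] = b1 * mi + (1 - b1) * g
                    vi[...] = b2 * vi + (1 - b2) * g * g
                    mhat = mi / (1 - b1**t)
                    vhat = vi / (1 - b2**t)
                    p -= self.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_curve_.append(self._objective(Xs, y_idx, w))
            if X_val is not None:
                probs_v = _softmax(self._net.forward(Xv))
                val_ce = -np.mean(
                    w[yv_idx]
                    * np.log(np.clip(probs_v[np.arange(len(yv_idx)), yv_idx], _EPS, 1.0))
                )
                if val_ce < best_val - 1e-6:
                    best_val = val_ce
                    best_flat = self._net.flat_parameters()
                    stall = 0
                else:
                    stall += 1
                    if stall >= self.patience:
                        break
        if best_flat is not None:
            self._net.set_flat_parameters(best_flat)
        self.final_loss_ = self.loss_curve_[-1]
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "spec_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise FormatError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = self.scaler_.transform(X) if self.scaler_ is not None else X
        return _softmax(self._net.forward(Xs))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def score_set(
        self, X, y, subject_ids=None, reading_ids=None, who_grades=None
    ) -> ScoreSet:
        """Score inputs into a :class:`ScoreSet` carrying the true labels."""
        return ScoreSet(
            probs=self.predict_proba(X),
            y_true=np.asarray(y),
            classes=tuple(self.classes_),
            subject_ids=None if subject_ids is None else np.asarray(subject_ids),
            reading_ids=None if reading_ids is None else np.asarray(reading_ids),
            who_grades=None if who_grades is None else np.asarray(who_grades),
        )


def train(
    spec: ModelSpec,
    X,
    y,
    X_val=None,
    y_val=None,
    random_state: int | None = 0,
    **fit_params,
) -> ImpedanceNetClassifier:
    """Convenience wrapper: build and fit a classifier from a ModelSpec."""
    clf = ImpedanceNetClassifier(
        model_name=spec.name,
        class_weights=spec.class_weights,
        l2_lambda=spec.l2_lambda,
        random_state=random_state,
        **fit_params,
    )
    return clf.fit(X, y, X_val=X_val, y_val=y_val)


def predict_scores(model: ImpedanceNetClassifier, X, y, **meta) -> ScoreSet:
    """Module-level alias for :meth:`ImpedanceNetClassifier.score_set`."""
    return model.score_set(X, y, **meta)
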