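"""Six-layer Takagi–Sugeno–Kang fuzzy neural network.

The network holds r fuzzy IF-THEN rules over m inputs and n outputs:

    IF x_1 is A_1j AND ... AND x_m is A_mj
    THEN y_j = sum_i a_ij x_i + b_j

Layer 1 distributes the inputs; layer 2 computes Gaussian memberships
mu1_j(x_i) = exp(-(x_i - c_ij)^2 / sigma_ij^2); layer 3 forms rule firing
strengths mu_j = prod_i mu1_j(x_i) (product t-norm; a ``min`` conjunction
is available but is not differentiable and cannot be gradient-trained);
layer 4 evaluates the linear consequents y_j; layer 5 weights them,
y1_j = mu_j * y_j; and layer 6 mixes rules into the k-th output through
trainable weights w_jk, normalised by the total firing strength:

    u_k = sum_j w_jk mu_j y_j / sum_j mu_j.

The predicted command class is the argmax over the n outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .eeg import ClassLabel
from .errors import InvalidWidthError, RecordingValidationError

MIN_WIDTH = 1e-6  # widths are clamped here to keep memberships defined


@dataclass
class AntecedentSet:
    """Gaussian membership centres and widths, both m-by-r."""

    centers: np.ndarray
    widths: np.ndarray

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        self.widths = np.atleast_2d(np.asarray(self.widths, dtype=np.float64))
        if self.centers.shape != self.widths.shape:
            raise RecordingValidationError("centers and widths must share a shape")
        if (self.widths <= 0).any():
            raise InvalidWidthError("membership widths must be strictly positive")


@dataclass
class ConsequentSet:
    """Linear-consequent coefficients a_ij (m-by-r) and intercepts b_j (r)."""

    coefficients: np.ndarray
    intercepts: np.ndarray

    def __post_init__(self) -> None:
        self.coefficients = np.atleast_2d(
            np.asarray(self.coefficients, dtype=np.float64)
        )
        self.intercepts = np.atleast_1d(
            np.asarray(self.intercepts, dtype=np.float64)
        )
        if self.intercepts.shape != (self.coefficients.shape[1],):
            raise RecordingValidationError("intercepts must have one entry per rule")
        if not (
            np.isfinite(self.coefficients).all()
            and np.isfinite(self.intercepts).all()
        ):
            raise RecordingValidationError("consequent parameters must be finite")


@dataclass
class MixingWeights:
    """Rule-to-output mixing weights w_jk (r-by-n)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=np.float64))
        if not np.isfinite(self.weights).all():
            raise RecordingValidationError("mixing weights must be finite")


@dataclass
class FNNModel:
    antecedents: AntecedentSet
    consequents: ConsequentSet
    mixing: MixingWeights
    class_names: tuple[str, ...] = ()
    feature_names: tuple[str, ...] = ()
    scaling_mins: np.ndarray | None = None
    scaling_maxs: np.ndarray | None = None
    tnorm: str = "product"

    def __post_init__(self) -> None:
        m, r = self.antecedents.centers.shape
        if self.consequents.coefficients.shape != (m, r):
            raise RecordingValidationError(
                "consequent coefficients must be m-by-r"
            )
        if self.mixing.weights.shape[0] != r:
            raise RecordingValidationError("mixing weights must be r-by-n")
        if self.tnorm not in ("product", "min"):
            raise RecordingValidationError("tnorm must be 'product' or 'min'")
        self.class_names = tuple(self.class_names)
        if self.class_names and len(self.class_names) != self.n:
            raise RecordingValidationError("need one class name per output")
        self.feature_names = tuple(self.feature_names)
        if self.scaling_mins is not None:
            self.scaling_mins = np.asarray(self.scaling_mins, dtype=np.float64)
        if self.scaling_maxs is not None:
            self.scaling_maxs = np.asarray(self.scaling_maxs, dtype=np.float64)

    @property
    def m(self) -> int:
        return self.antecedents.centers.shape[0]

    @property
    def r(self) -> int:
        return self.antecedents.centers.shape[1]

    @property
    def n(self) -> int:
        return self.mixing.weights.shape[1]

    # -- persistence ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "r": self.r,
            "n": self.n,
            "tnorm": self.tnorm,
            "centers": self.antecedents.centers.tolist(),
            "widths": self.antecedents.widths.tolist(),
            "coefficients": self.consequents.coefficients.tolist(),
            "intercepts": self.consequents.intercepts.tolist(),
            "mixing": self.mixing.weights.tolist(),
            "class_names": list(self.class_names),
            "feature_names": list(self.feature_names),
            "scaling_mins": (
                None if self.scaling_mins is None else self.scaling_mins.tolist()
            ),
            "scaling_maxs": (
                None if self.scaling_maxs is None else self.scaling_maxs.tolist()
            ),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FNNModel":
        return cls(
            AntecedentSet(np.array(d["centers"]), np.array(d["widths"])),
            ConsequentSet(np.array(d["coefficients"]), np.array(d["intercepts"])),
            MixingWeights(np.array(d["mixing"])),
            tuple(d.get("class_names") or ()),
            tuple(d.get("feature_names") or ()),
            None if d.get("scaling_mins") is None else np.array(d["scaling_mins"]),
            None if d.get("scaling_maxs") is None else np.array(d["scaling_maxs"]),
            d.get("tnorm", "product"),
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FNNModel":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"model file not found: {path}")
        return cls.from_dict(json.loads(path.read_text()))


# ---------------------------------------------------------------------------
# Forward pass


def membership(x: float, c: float, sigma: float) -> float:
    """Gaussian membership degree exp(-(x - c)^2 / sigma^2).

    Note the exponent uses sigma^2, not 2 sigma^2; the widths are fitted,
    so the convention is absorbed into them.
    """
    if sigma <= 0:
        raise InvalidWidthError("membership width must be > 0")
    z = (x - c) / sigma
    return float(np.exp(-z * z))


def membership_grid(x: np.ndarray, ants: AntecedentSet) -> np.ndarray:
    """Per-input, per-rule membership degrees; shape (..., m, r)."""
    x = np.asarray(x, dtype=np.float64)
    z = (x[..., :, None] - ants.centers) / ants.widths
    return np.exp(-z * z)


def firing_strengths(
    x: np.ndarray, ants: AntecedentSet, tnorm: str = "product"
) -> np.ndarray:
    """Conjunction of per-input memberships per rule; shape (..., r).

    Product t-norm by default; ``min`` is available for inference only.
    """
    grid = membership_grid(x, ants)
    if tnorm == "product":
        return grid.prod(axis=-2)
    if tnorm == "min":
        return grid.min(axis=-2)
    raise RecordingValidationError(f"unknown t-norm {tnorm!r}")


def _stable_firing(
    x: np.ndarray, ants: AntecedentSet, tnorm: str = "product"
) -> np.ndarray:
    """Firing strengths rescaled so the largest per sample is 1.

    The network output u_k = sum_j w_jk mu_j y_j / sum_j mu_j depends on
    the mu_j only through ratios, so dividing all of a sample's firing
    strengths by their maximum leaves u (and every gradient) unchanged
    while preventing exp underflow in high dimension.
    """
    z2 = ((x[..., :, None] - ants.centers) / ants.widths) ** 2
    if tnorm == "product":
        expo = z2.sum(axis=-2)  # (..., r)
    elif tnorm == "min":
        expo = z2.max(axis=-2)
    else:
        raise RecordingValidationError(f"unknown t-norm {tnorm!r}")
    return np.exp(-(expo - expo.min(axis=-1, keepdims=True)))


def consequent_outputs(x: np.ndarray, cons: ConsequentSet) -> np.ndarray:
    """Linear rule outputs y_j = sum_i x_i a_ij + b_j; shape (..., r)."""
    x = np.asarray(x, dtype=np.float64)
    return x @ cons.coefficients + cons.intercepts


def forward(x: np.ndarray, model: FNNModel) -> np.ndarray:
    """Network outputs u_k = sum_j w_jk mu_j y_j / sum_j mu_j.

    Accepts a single sample (m,) or a batch (N, m); returns (n,) or (N, n).
    """
    x = np.asarray(x, dtype=np.float64)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != model.m:
        raise RecordingValidationError(
            f"expected {model.m} inputs, got {x.shape[1]}"
        )
    mu = _stable_firing(x, model.antecedents, model.tnorm)  # (N, r)
    y = consequent_outputs(x, model.consequents)  # (N, r)
    y1 = mu * y
    denom = mu.sum(axis=1, keepdims=True)
    u = (y1 @ model.mixing.weights) / denom
    return u[0] if single else u


def classify(u: np.ndarray, class_names: tuple[str, ...]) -> ClassLabel:
    """Maximal-output decision; ties go to the lowest index."""
    u = np.asarray(u, dtype=np.float64)
    if not np.isfinite(u).all():
        raise RecordingValidationError("outputs must be finite to classify")
    idx = int(np.argmax(u))
    name = class_names[idx] if class_names else str(idx)
    return ClassLabel(name, idx)


def predict(model: FNNModel, X: np.ndarray, scale: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Outputs and argmax class indices for a batch.

    If the model carries feature-scaling bounds and ``scale`` is true, the
    inputs are min–max scaled (and clipped) with them first.
    """
    X = np.asarray(X, dtype=np.float64)
    if scale and model.scaling_mins is not None and model.scaling_maxs is not None:
        span = model.scaling_maxs - model.scaling_mins
        safe = np.where(span > 0, span, 1.0)
        X = np.clip((X - model.scaling_mins) / safe, 0.0, 1.0)
        X[:, span <= 0] = 0.0
    u = forward(X, model)
    return u, u.argmax(axis=1)
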