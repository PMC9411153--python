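"""The attention-based MIL network, in pure NumPy with analytic gradients.

A patient enters as a set of *units*: phenotype feature stacks for the
clustered model (Model 1) or individual instances for the instance-level
model (Model 2). Each unit is embedded by a shared 1x1 convolution (a
per-position linear map d -> M) followed by ReLU and global average
pooling; for 2x2 super-patch instances the kernel spans the whole grid,
i.e. acts on the flattened 4d input. Unit representations h_i are combined
by attention pooling

    z = sum_i a_i h_i,      a_i = softmax_i( w^T tanh(V h_i) ),

with trainable V (L x M) and w (L,); the tanh keeps both similarity and
dissimilarity signals in play. A small fully-connected head maps z to the
scalar risk score o. The attention vector a is returned with every
prediction for interpretability.

All forward/backward passes are deterministic for fixed parameters (with
dropout disabled), and gradients are exact — they are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoding import PatientBag

__all__ = [
    "MILParams",
    "RiskPrediction",
    "init_params",
    "embed_unit",
    "attention_weights",
    "aggregate",
    "forward_risk",
    "bag_to_units",
]

PARAM_NAMES = ("W", "b", "V", "w", "W1", "b1", "w2", "b2")


@dataclass
class MILParams:
    """All trainable parameters of the MIL network.

    W, b   — shared embedder kernel (M x p) and bias: unit rows -> M channels
    V, w   — attention parameters, V in R^{L x M}, w in R^{L}
    W1, b1 — first head layer (H x M)
    w2, b2 — output head layer (H,), scalar
    """

    W: np.ndarray
    b: np.ndarray
    V: np.ndarray
    w: np.ndarray
    W1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        M, _ = self.W.shape
        L, M_v = self.V.shape
        if M_v != M or self.w.shape != (L,) or self.b.shape != (M,):
            raise ValueError("inconsistent attention/embedder shapes")
        H, M_h = self.W1.shape
        if M_h != M or self.b1.shape != (H,) or self.w2.shape != (H,):
            raise ValueError("inconsistent head shapes")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")

    @property
    def in_dim(self) -> int:
        return self.W.shape[1]

    def as_dict(self) -> dict[str, np.ndarray]:
        return {k: getattr(self, k) for k in PARAM_NAMES}

    def copy(self) -> "MILParams":
        return MILParams(**{k: np.array(getattr(self, k), copy=True) for k in PARAM_NAMES},
                         dropout_rate=self.dropout_rate)

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(getattr(self, k)) for k in PARAM_NAMES}


@dataclass(frozen=True)
class RiskPrediction:
    """Scalar risk score o plus the attention weight of each input unit."""

    patient_id: str
    risk: float
    attention: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.attention, dtype=float)
        if not np.isclose(a.sum(), 1.0, atol=1e-6):
            raise ValueError("attention weights must sum to 1")
        object.__setattr__(self, "attention", a)


def init_params(
    in_dim: int,
    M: int = 64,
    L: int = 128,
    head_hidden: int = 32,
    dropout_rate: float = 0.0,
    seed: int = 0,
) -> MILParams:
    """He-style initialization of all parameter blocks under one seed.

    The attention parameters V and w are initialized *positive* (half-normal).
    Since unit representations are non-negative (ReLU), positive V and w make
    the initial attention logits increase with a unit's activation energy.
    This breaks the sign symmetry of softmax attention — the loss is blind to
    whether attention concentrates on or away from risk-carrying instances,
    because the head can absorb either orientation — and places training in
    the basin where attention favours high-activation (signal-bearing)
    instances, which is the orientation heatmaps are read with.
    """
    rng = np.random.default_rng(seed)
    return MILParams(
        W=rng.standard_normal((M, in_dim)) * np.sqrt(2.0 / in_dim),
        b=np.zeros(M),
        V=np.abs(rng.standard_normal((L, M))) * np.sqrt(1.0 / M),
        w=np.abs(rng.standard_normal(L)) * np.sqrt(1.0 / L),
        W1=rng.standard_normal((head_hidden, M)) * np.sqrt(2.0 / M),
        b1=np.zeros(head_hidden),
        w2=rng.standard_normal(head_hidden) * np.sqrt(1.0 / head_hidden),
        b2=np.zeros(()),
        dropout_rate=dropout_rate,
    )


def bag_to_units(source) -> tuple[np.ndarray, np.ndarray]:
    """Normalize any supported input into (stacked rows, rows-per-unit).

    Accepted: a PatientBag (each instance one unit), an (n, p) array (each
    row one unit), a list of 2-D arrays (each a multi-row unit, e.g. a
    phenotype stack), or an object exposing ``cluster_stacks``.
    """
    stacks = getattr(source, "cluster_stacks", None)
    if stacks is not None:
        units = [np.atleast_2d(s) for s in stacks]
    elif isinstance(source, PatientBag):
        units = [source.feature_matrix()]
        rows = units[0]
        return rows, np.ones(rows.shape[0], dtype=int)
    elif isinstance(source, np.ndarray):
        rows = np.atleast_2d(np.asarray(source, dtype=float))
        return rows, np.ones(rows.shape[0], dtype=int)
    else:
        units = [np.atleast_2d(np.asarray(u, dtype=float)) for u in source]
    if len(units) == 0:
        raise ValueError("empty input: a bag must contain at least one unit")
    counts = np.array([u.shape[0] for u in units], dtype=int)
    return np.concatenate(units, axis=0), counts


def _softmax(e: np.ndarray) -> np.ndarray:
    e = e - e.max()
    x = np.exp(e)
    return x / x.sum()


def _forward(
    rows: np.ndarray,
    counts: np.ndarray,
    params: MILParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray, dict]:
    """Full forward pass; returns (risk, attention, cache for backprop)."""
    if rows.shape[1] != params.in_dim:
        raise ValueError(f"unit channel dim {rows.shape[1]} != embedder input dim {params.in_dim}")
    if np.isnan(rows).any():
        raise ValueError("NaN in input features")
    offsets = np.concatenate(([0], np.cumsum(counts)[:-1]))
    A = rows @ params.W.T + params.b
    Rl = np.maximum(A, 0.0)
    h = np.add.reduceat(Rl, offsets, axis=0) / counts[:, None]
    drop_mask = None
    if train_mode and params.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - params.dropout_rate
        drop_mask = (rng.random(h.shape) < keep) / keep
        h = h * drop_mask
    T = np.tanh(h @ params.V.T)
    e = T @ params.w
    a = _softmax(e)
    z = a @ h
    q = params.W1 @ z + params.b1
    r = np.maximum(q, 0.0)
    o = float(params.w2 @ r + params.b2)
    cache = dict(rows=rows, counts=counts, offsets=offsets, A=A, h=h, T=T, a=a, z=z, q=q, r=r,
                 drop_mask=drop_mask)
    return o, a, cache


def _backward(cache: dict, params: MILParams, do: float, grads: dict[str, np.ndarray]) -> None:
    """Accumulate d(do * o)/d(params) into ``grads`` (exact backprop)."""
    rows, counts = cache["rows"], cache["counts"]
    A, h, T, a, z, q, r = (cache[k] for k in ("A", "h", "T", "a", "z", "q", "r"))
    grads["w2"] += do * r
    grads["b2"] += do
    dq = (do * params.w2) * (q > 0)
    grads["W1"] += np.outer(dq, z)
    grads["b1"] += dq
    dz = params.W1.T @ dq
    dh = np.outer(a, dz)  # via z = a @ h
    da = h @ dz
    de = a * (da - a @ da)  # softmax backward
    grads["w"] += T.T @ de
    dT = np.outer(de, params.w)
    dU = dT * (1.0 - T**2)
    grads["V"] += dU.T @ h
    dh += dU @ params.V
    if cache["drop_mask"] is not None:
        dh = dh * cache["drop_mask"]
    dhrow = np.repeat(dh / counts[:, None], counts, axis=0)
    dA = dhrow * (A > 0)
    grads["W"] += dA.T @ rows
    grads["b"] += dA.sum(axis=0)


# --- public, contract-level pieces -----------------------------------------

def embed_unit(
    unit: np.ndarray,
    params: MILParams,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Local representation h = GAP(ReLU(conv(unit))) of one unit.

    ``unit`` is (rows, d): a phenotype stack of row vectors, or a single
    flattened instance. The result is elementwise non-negative.
    """
    unit = np.atleast_2d(np.asarray(unit, dtype=float))
    if unit.shape[1] != params.in_dim:
        raise ValueError(f"unit has {unit.shape[1]} channels, embedder expects {params.in_dim}")
    h = np.maximum(unit @ params.W.T + params.b, 0.0).mean(axis=0)
    if train_mode and params.dropout_rate > 0.0:
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        keep = 1.0 - params.dropout_rate
        h = h * ((rng.random(h.shape) < keep) / keep)
    return h


def attention_weights(H: Sequence[np.ndarray] | np.ndarray, params: MILParams) -> np.ndarray:
    """Softmax attention a_i over unit representations; sums to one."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    logits = np.tanh(H @ params.V.T) @ params.w
    return _softmax(logits)


def aggregate(H: Sequence[np.ndarray] | np.ndarray, a: np.ndarray) -> np.ndarray:
    """Attention-weighted bag representation z = sum_i a_i h_i."""
    H = np.atleast_2d(np.asarray(H, dtype=float))
    a = np.asarray(a, dtype=float)
    if H.shape[0] != a.shape[0]:
        raise ValueError(f"{H.shape[0]} representations but {a.shape[0]} weights")
    return a @ H


def forward_risk(
    source,
    params: MILParams,
    patient_id: str | None = None,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> RiskPrediction:
    """Predict one patient's risk score and per-unit attention.

    ``source`` may be a PatientBag or an (n, p) array (instance model), or a
    PhenotypeSet / list of stacks (clustered model).
    """
    rows, counts = bag_to_units(source)
    o, a, _ = _forward(rows, counts, params, train_mode=train_mode, rng=rng)
    pid = patient_id if patient_id is not None else getattr(source, "patient_id", "")
    return RiskPrediction(patient_id=pid, risk=o, attention=a)
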