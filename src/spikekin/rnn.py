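"""Recurrent multilayer perceptron with delayed hidden-state feedback and a
from-scratch Levenberg-Marquardt trainer.

The network has two logistic-sigmoid hidden layers; each hidden layer
receives its own output delayed by one and by two steps through recurrent
weight matrices, and the readout is linear:

    y1(t) = sigmoid(x(t) W1 + y1(t-1) V1 + y1(t-2) U1 + b1)
    y2(t) = sigmoid(y1(t) W2 + y2(t-1) V2 + y2(t-2) U2 + b2)
    out(t) = y2(t) C

Hidden states are zero at sequence start.  The Jacobian of the residuals
with respect to every weight is propagated exactly through the recurrence
(forward-mode / real-time-recurrent-learning style) and is validated
against finite differences in the test suite.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import DecoderDataset

__all__ = [
    "RNNParams",
    "TrainConfig",
    "init_params",
    "rnn_forward",
    "compute_jacobian",
    "lm_train",
    "params_to_dict",
    "params_from_dict",
    "save_params",
    "load_params",
]


@dataclass
class RNNParams:
    """All weights of the two-hidden-layer recurrent MLP.

    Shapes: w1 (p, q), v1/u1 (q, q), b1 (q,), w2 (q, r), v2/u2 (r, r),
    b2 (r,), c (r, n_out).  Biases are included although the published
    update equations omit them (see README notes).
    """

    w1: np.ndarray
    v1: np.ndarray
    u1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    v2: np.ndarray
    u2: np.ndarray
    b2: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        for name in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        p, q = self.w1.shape
        r = self.w2.shape[1]
        if self.v1.shape != (q, q) or self.u1.shape != (q, q):
            raise ValueError("v1/u1 must be (q, q)")
        if self.b1.shape != (q,):
            raise ValueError("b1 must be (q,)")
        if self.w2.shape != (q, r):
            raise ValueError("w2 must be (q, r)")
        if self.v2.shape != (r, r) or self.u2.shape != (r, r):
            raise ValueError("v2/u2 must be (r, r)")
        if self.b2.shape != (r,):
            raise ValueError("b2 must be (r,)")
        if self.c.shape[0] != r:
            raise ValueError("c must be (r, n_out)")
        for name in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite values")

    @property
    def p(self) -> int:
        return int(self.w1.shape[0])

    @property
    def q(self) -> int:
        return int(self.w1.shape[1])

    @property
    def r(self) -> int:
        return int(self.w2.shape[1])

    @property
    def n_out(self) -> int:
        return int(self.c.shape[1])

    @property
    def n_weights(self) -> int:
        return sum(
            getattr(self, n).size
            for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c")
        )

    def pack(self) -> np.ndarray:
        return np.concatenate(
            [
                getattr(self, n).ravel()
                for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c")
            ]
        )

    def unpack(self, theta: np.ndarray) -> "RNNParams":
        out = {}
        pos = 0
        for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c"):
            a = getattr(self, n)
            out[n] = theta[pos : pos + a.size].reshape(a.shape).copy()
            pos += a.size
        if pos != theta.size:
            raise ValueError("theta length mismatch")
        return RNNParams(**out)

    def copy(self) -> "RNNParams":
        return self.unpack(self.pack())


@dataclass
class TrainConfig:
    """Levenberg-Marquardt schedule and stopping rules."""

    mu_init: float = 1e-3
    mu_up: float = 10.0
    mu_down: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 100
    val_fraction: float = 0.2
    patience: int = 10
    seed: int = 0
    weight_init_scale: float = 1.0
    washout: int = 2  # initial outputs excluded from the loss

    def __post_init__(self) -> None:
        if self.mu_init <= 0:
            raise ValueError("mu_init must be > 0")
        if not (self.mu_up > 1.0 > self.mu_down > 0.0):
            raise ValueError("need mu_up > 1 > mu_down > 0")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


def init_params(
    p: int,
    q: int,
    r: int,
    n_out: int = 3,
    seed: int = 0,
    scale: float = 1.0,
) -> RNNParams:
    """Seeded uniform init: each matrix in +-scale/sqrt(fan_in); zero biases."""
    rng = np.random.default_rng(seed)

    def u(shape, fan_in):
        s = scale / np.sqrt(max(fan_in, 1))
        return rng.uniform(-s, s, size=shape)

    return RNNParams(
        w1=u((p, q), p),
        v1=u((q, q), q),
        u1=u((q, q), q),
        b1=np.zeros(q),
        w2=u((q, r), q),
        v2=u((r, r), r),
        u2=u((r, r), r),
        b2=np.zeros(r),
        c=u((r, n_out), r),
    )


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-a))


def _forward_np(x, w1, v1, u1, b1, w2, v2, u2, b2):
    T = x.shape[0]
    q, r = w1.shape[1], w2.shape[1]
    y1 = np.zeros((T, q))
    y2 = np.zeros((T, r))
    y1p1 = np.zeros(q)
    y1p2 = np.zeros(q)
    y2p1 = np.zeros(r)
    y2p2 = np.zeros(r)
    for t in range(T):
        h1 = 1.0 / (1.0 + np.exp(-(x[t] @ w1 + y1p1 @ v1 + y1p2 @ u1 + b1)))
        h2 = 1.0 / (1.0 + np.exp(-(h1 @ w2 + y2p1 @ v2 + y2p2 @ u2 + b2)))
        y1[t] = h1
        y2[t] = h2
        y1p2, y1p1 = y1p1, h1
        y2p2, y2p1 = y2p1, h2
    return y1, y2


try:  # sequential recurrences gain ~50x from compilation; numpy fallback kept
    import numba as _nb

    _forward_jit = _nb.njit(cache=True, fastmath=False)(_forward_np)

    def _forward_core(x, *wts):
        return _forward_jit(x, *wts)

except ImportError:  # pragma: no cover - numba is normally present
    _forward_core = _forward_np


def rnn_forward(
    params: RNNParams, inputs: np.ndarray
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray]]:
    """Run the exact unrolled recursion; returns (outputs, (Y1, Y2)).

    ``inputs`` is (T, p); hidden states at t = -1, -2 are zero.  Outputs is
    (T, n_out); Y1 (T, q) and Y2 (T, r) hold the hidden trajectories.
    """
    x = np.ascontiguousarray(inputs, dtype=float)
    if x.ndim != 2 or x.shape[1] != params.p:
        raise ValueError(
            f"inputs must be (T, {params.p}), got {x.shape}"
        )
    y1, y2 = _forward_core(
        x,
        params.w1, params.v1, params.u1, params.b1,
        params.w2, params.v2, params.u2, params.b2,
    )
    return y2 @ params.c, (y1, y2)


def _slices(params: RNNParams) -> dict[str, slice]:
    pos = 0
    out = {}
    for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c"):
        size = getattr(params, n).size
        out[n] = slice(pos, pos + size)
        pos += size
    return out


def _diag_strided(buf: np.ndarray, start: int, n_outer: int, inner: int) -> np.ndarray:
    """Writable view of buf[i, start + j*inner + i] with shape (inner?, ...).

    For a (rows, W) buffer this exposes the elements [i, start + j*inner + i]
    for i in range(inner) and j in range(n_outer) as an (inner, n_outer)
    array, which is exactly the "diagonal" pattern of the direct derivative
    of a pre-activation w.r.t. its own (n_outer, inner) weight matrix.
    """
    s0, s1 = buf.strides
    return np.lib.stride_tricks.as_strided(
        buf[:, start:],
        shape=(inner, n_outer),
        strides=(s0 + s1, inner * s1),
        writeable=True,
    )


def _jacobian_np(x, tg, washout, params: RNNParams):
    T = x.shape[0]
    p, q, r, m = params.p, params.q, params.r, params.n_out
    W = params.n_weights

    sl = _slices(params)
    iq = np.arange(q)
    ir = np.arange(r)

    # rotating sensitivity stores dy/dtheta and fixed pre-activation buffers
    s1p1 = np.zeros((q, W))
    s1p2 = np.zeros((q, W))
    s1buf = np.zeros((q, W))
    s2p1 = np.zeros((r, W))
    s2p2 = np.zeros((r, W))
    s2buf = np.zeros((r, W))
    dA1 = np.empty((q, W))
    dA1b = np.empty((q, W))
    dA2 = np.empty((r, W))
    dA2b = np.empty((r, W))
    dOut = np.empty((m, W))

    # strided views onto the direct-derivative "diagonals" (created once)
    dA1_w1 = _diag_strided(dA1, sl["w1"].start, p, q)
    dA1_v1 = _diag_strided(dA1, sl["v1"].start, q, q)
    dA1_u1 = _diag_strided(dA1, sl["u1"].start, q, q)
    dA2_w2 = _diag_strided(dA2, sl["w2"].start, q, r)
    dA2_v2 = _diag_strided(dA2, sl["v2"].start, r, r)
    dA2_u2 = _diag_strided(dA2, sl["u2"].start, r, r)
    dOut_c = _diag_strided(dOut, sl["c"].start, r, m)
    b1_cols = sl["b1"].start + iq
    b2_cols = sl["b2"].start + ir

    y1p1 = np.zeros(q)
    y1p2 = np.zeros(q)
    y2p1 = np.zeros(r)
    y2p2 = np.zeros(r)

    n_res_rows = T - washout
    res = np.empty((n_res_rows, m))
    J = np.empty((n_res_rows * m, W))

    v1T = np.ascontiguousarray(params.v1.T)
    u1T = np.ascontiguousarray(params.u1.T)
    w2T = np.ascontiguousarray(params.w2.T)
    v2T = np.ascontiguousarray(params.v2.T)
    u2T = np.ascontiguousarray(params.u2.T)
    cT = np.ascontiguousarray(params.c.T)

    for t in range(T):
        xt = x[t]
        h1 = _sigmoid(xt @ params.w1 + y1p1 @ params.v1 + y1p2 @ params.u1 + params.b1)
        d1 = h1 * (1.0 - h1)

        np.matmul(v1T, s1p1, out=dA1)
        np.matmul(u1T, s1p2, out=dA1b)
        dA1 += dA1b
        dA1_w1 += xt
        dA1_v1 += y1p1
        dA1_u1 += y1p2
        dA1[iq, b1_cols] += 1.0
        s1 = np.multiply(dA1, d1[:, None], out=s1buf)

        h2 = _sigmoid(h1 @ params.w2 + y2p1 @ params.v2 + y2p2 @ params.u2 + params.b2)
        d2 = h2 * (1.0 - h2)

        np.matmul(w2T, s1, out=dA2)
        np.matmul(v2T, s2p1, out=dA2b)
        dA2 += dA2b
        np.matmul(u2T, s2p2, out=dA2b)
        dA2 += dA2b
        dA2_w2 += h1
        dA2_v2 += y2p1
        dA2_u2 += y2p2
        dA2[ir, b2_cols] += 1.0
        s2 = np.multiply(dA2, d2[:, None], out=s2buf)

        if t >= washout:
            k = t - washout
            res[k] = h2 @ params.c - tg[t]
            np.matmul(cT, s2, out=dOut)
            dOut_c += h2
            J[k * m : (k + 1) * m] = dOut

        y1p2, y1p1 = y1p1, h1
        y2p2, y2p1 = y2p1, h2
        s1p2, s1p1, s1buf = s1p1, s1, s1p2
        s2p2, s2p1, s2buf = s2p1, s2, s2p2

    return res.ravel(), J


def _jacobian_loops(x, tg, washout, w1, v1, u1, b1, w2, v2, u2, b2, c):
    """Explicit-loop RTRL (numba-compilable); same contract as _jacobian_np."""
    T, p = x.shape
    q = w1.shape[1]
    r = w2.shape[1]
    m = c.shape[1]
    o_w1 = 0
    o_v1 = o_w1 + p * q
    o_u1 = o_v1 + q * q
    o_b1 = o_u1 + q * q
    o_w2 = o_b1 + q
    o_v2 = o_w2 + q * r
    o_u2 = o_v2 + r * r
    o_b2 = o_u2 + r * r
    o_c = o_b2 + r
    W = o_c + r * m

    s1p1 = np.zeros((q, W))
    s1p2 = np.zeros((q, W))
    s1n = np.zeros((q, W))
    s2p1 = np.zeros((r, W))
    s2p2 = np.zeros((r, W))
    s2n = np.zeros((r, W))
    y1p1 = np.zeros(q)
    y1p2 = np.zeros(q)
    y2p1 = np.zeros(r)
    y2p2 = np.zeros(r)
    a1 = np.empty(q)
    a2 = np.empty(r)

    nr = T - washout
    res = np.empty((nr, m))
    J = np.empty((nr * m, W))

    for t in range(T):
        xt = x[t]
        for i in range(q):
            s = b1[i]
            for j in range(p):
                s += xt[j] * w1[j, i]
            for j in range(q):
                s += y1p1[j] * v1[j, i] + y1p2[j] * u1[j, i]
            a1[i] = s
        h1 = 1.0 / (1.0 + np.exp(-a1))
        d1 = h1 * (1.0 - h1)

        for i in range(q):
            row = s1n[i]
            for k in range(W):
                row[k] = 0.0
            for j in range(q):
                a = v1[j, i]
                b = u1[j, i]
                r1 = s1p1[j]
                r2 = s1p2[j]
                for k in range(W):
                    row[k] += a * r1[k] + b * r2[k]
            for j in range(p):
                row[o_w1 + j * q + i] += xt[j]
            for j in range(q):
                row[o_v1 + j * q + i] += y1p1[j]
                row[o_u1 + j * q + i] += y1p2[j]
            row[o_b1 + i] += 1.0
            di = d1[i]
            for k in range(W):
                row[k] *= di

        for i in range(r):
            s = b2[i]
            for j in range(q):
                s += h1[j] * w2[j, i]
            for j in range(r):
                s += y2p1[j] * v2[j, i] + y2p2[j] * u2[j, i]
            a2[i] = s
        h2 = 1.0 / (1.0 + np.exp(-a2))
        d2 = h2 * (1.0 - h2)

        for i in range(r):
            row = s2n[i]
            for k in range(W):
                row[k] = 0.0
            for j in range(q):
                a = w2[j, i]
                r1 = s1n[j]
                for k in range(W):
                    row[k] += a * r1[k]
            for j in range(r):
                a = v2[j, i]
                b = u2[j, i]
                r1 = s2p1[j]
                r2 = s2p2[j]
                for k in range(W):
                    row[k] += a * r1[k] + b * r2[k]
            for j in range(q):
                row[o_w2 + j * r + i] += h1[j]
            for j in range(r):
                row[o_v2 + j * r + i] += y2p1[j]
                row[o_u2 + j * r + i] += y2p2[j]
            row[o_b2 + i] += 1.0
            di = d2[i]
            for k in range(W):
                row[k] *= di

        if t >= washout:
            kk = t - washout
            for i in range(m):
                s = 0.0
                for j in range(r):
                    s += h2[j] * c[j, i]
                res[kk, i] = s - tg[t, i]
                row = J[kk * m + i]
                for k in range(W):
                    row[k] = 0.0
                for j in range(r):
                    a = c[j, i]
                    rj = s2n[j]
                    for k in range(W):
                        row[k] += a * rj[k]
                for j in range(r):
                    row[o_c + j * m + i] += h2[j]

        for i in range(q):
            y1p2[i] = y1p1[i]
            y1p1[i] = h1[i]
        for i in range(r):
            y2p2[i] = y2p1[i]
            y2p1[i] = h2[i]
        tmp1 = s1p2
        s1p2 = s1p1
        s1p1 = s1n
        s1n = tmp1
        tmp2 = s2p2
        s2p2 = s2p1
        s2p1 = s2n
        s2n = tmp2

    return res.ravel(), J


try:
    import numba as _nb2  # noqa: F811 - separate guard from the forward kernel

    _jacobian_jit = _nb2.njit(cache=True, fastmath=False)(_jacobian_loops)

    def _jacobian_core(x, tg, washout, params: RNNParams):
        return _jacobian_jit(
            x, tg, washout,
            params.w1, params.v1, params.u1, params.b1,
            params.w2, params.v2, params.u2, params.b2, params.c,
        )

except ImportError:  # pragma: no cover - numba is normally present
    def _jacobian_core(x, tg, washout, params: RNNParams):
        return _jacobian_np(x, tg, washout, params)


def compute_jacobian(
    params: RNNParams,
    inputs: np.ndarray,
    targets: np.ndarray,
    washout: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and their exact Jacobian w.r.t. every weight.

    Residuals are the row-major vectorization of (output - target) for
    t >= washout; J has one row per residual and one column per weight in
    pack() order.  Derivatives are carried through the recurrence exactly
    (forward accumulation), so J matches finite differences.
    """
    x = np.ascontiguousarray(inputs, dtype=float)
    tg = np.ascontiguousarray(targets, dtype=float)
    if x.shape[0] != tg.shape[0]:
        raise ValueError("inputs and targets must have equal rows")
    T = x.shape[0]
    p, m = params.p, params.n_out
    if T == 0:
        return np.empty(0), np.empty((0, params.n_weights))
    if x.shape[1] != p:
        raise ValueError(f"inputs must be (T, {p})")
    if tg.shape[1] != m:
        raise ValueError(f"targets must be (T, {m})")
    if washout < 0 or washout >= T:
        raise ValueError("washout must lie in [0, T)")
    return _jacobian_core(x, tg, washout, params)


def _sse(params: RNNParams, x: np.ndarray, tg: np.ndarray, washout: int) -> float:
    out, _ = rnn_forward(params, x)
    d = out[washout:] - tg[washout:]
    return float(np.sum(d * d))


def lm_train(
    params: RNNParams,
    data: DecoderDataset,
    cfg: TrainConfig,
) -> tuple[RNNParams, list[dict]]:
    """Levenberg-Marquardt training with validation-based early stopping.

    Each epoch solves (J'J + mu I) delta = -J'res on the training portion;
    a step is accepted only if the training SSE decreases (mu is multiplied
    by ``mu_up`` and the step retried otherwise; ``mu_down`` on accept).
    The validation set is the contiguous last ``val_fraction`` of the rows;
    the weights with the best validation SSE are returned together with the
    per-epoch history (epoch, sse_train, sse_val, mu).
    """
    x = data.inputs
    tg = data.targets
    n = x.shape[0]
    n_val = int(round(n * cfg.val_fraction))
    n_tr = n - n_val
    if n_tr <= cfg.washout:
        raise ValueError("too few training rows after washout")
    if n_tr < params.n_weights:
        warnings.warn(
            f"{n_tr} training rows < {params.n_weights} weights; "
            "the problem is under-determined",
            stacklevel=2,
        )
    x_tr, tg_tr = x[:n_tr], tg[:n_tr]

    def val_sse(pp: RNNParams) -> float:
        if n_val == 0:
            return _sse(pp, x_tr, tg_tr, cfg.washout)
        out, _ = rnn_forward(pp, x)  # full run keeps state continuity
        d = out[n_tr:] - tg[n_tr:]
        return float(np.sum(d * d))

    cur = params.copy()
    mu = cfg.mu_init
    sse = _sse(cur, x_tr, tg_tr, cfg.washout)
    if not np.isfinite(sse):
        raise FloatingPointError("non-finite initial loss")
    best_val = val_sse(cur)
    best_params = cur.copy()
    since_best = 0
    history: list[dict] = []
    eye = np.eye(cur.n_weights)

    for epoch in range(1, cfg.max_epochs + 1):
        res, J = compute_jacobian(cur, x_tr, tg_tr, washout=cfg.washout)
        A = J.T @ J
        g = J.T @ res
        accepted = False
        while mu <= cfg.mu_max:
            try:
                delta = np.linalg.solve(A + mu * eye, -g)
            except np.linalg.LinAlgError:
                mu *= cfg.mu_up
                continue
            cand = cur.unpack(cur.pack() + delta)
            sse_new = _sse(cand, x_tr, tg_tr, cfg.washout)
            if np.isfinite(sse_new) and sse_new < sse:
                cur = cand
                sse = sse_new
                mu = max(mu * cfg.mu_down, 1e-20)
                accepted = True
                break
            mu *= cfg.mu_up
        if not accepted:
            break  # mu overflow: no descent direction left

        v = val_sse(cur)
        history.append(
            {"epoch": epoch, "sse_train": sse, "sse_val": v, "mu": mu}
        )
        if v < best_val - 1e-15:
            best_val = v
            best_params = cur.copy()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    return best_params, history


def params_to_dict(params: RNNParams) -> dict:
    d = {
        n: getattr(params, n).tolist()
        for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c")
    }
    d["sizes"] = {
        "p": params.p,
        "q": params.q,
        "r": params.r,
        "n_out": params.n_out,
    }
    return d


def params_from_dict(d: dict) -> RNNParams:
    return RNNParams(
        **{
            n: np.asarray(d[n], dtype=float)
            for n in ("w1", "v1", "u1", "b1", "w2", "v2", "u2", "b2", "c")
        }
    )


def save_params(params: RNNParams, path) -> None:
    with open(path, "w") as fh:
        json.dump(params_to_dict(params), fh)


def load_params(path) -> RNNParams:
    with open(path) as fh:
        return params_from_dict(json.load(fh))
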