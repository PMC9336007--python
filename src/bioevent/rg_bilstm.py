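"""Bidirectional LSTM with a reading gate over a sentence-memory stream.

The cell extends the standard LSTM in two ways.  First, it reads *two*
input streams per token: the frozen pretrained embedding x_t and the
fine-tuned embedding x'_t, each with its own input weights in every gate.
Second, it carries a third state vector d_t ("sentence memory") alongside
h_t and c_t: d is initialized from the sentence embedding d0 and decays
multiplicatively through a sigmoid *reading gate* r_t,

    i_t, f_t, o_t, r_t = sigmoid(x_t W_x + x'_t W_x' + h_{t-1} W_h + b)
    c~_t              = tanh(  x_t W_x + x'_t W_x' + h_{t-1} W_h + b)
    d_t = r_t (*) d_{t-1}
    c_t = i_t (*) c~_t + f_t (*) c_{t-1} + tanh(d_t)
    h_t = o_t (*) tanh(c_t)

so every step injects a gated residue of global sentence information into
the cell state.  With d0 = 0 the d-stream vanishes identically and the cell
reduces exactly to a two-input LSTM — the ablation baseline.

The output equation h_t = o_t (*) tanh(c_t) is the standard LSTM output;
it is the only reading in which the output gate o_t has a consumer.
d0 has the embedding dimension while d_t must match the hidden dimension,
so a learned linear projection maps one to the other when they differ
(identity when equal).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .autodiff import Tensor, concat, dropout, stack

GATES = ("i", "f", "o", "c", "r")  # input, forget, output, proposal, reading


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> Tensor:
    bound = np.sqrt(6.0 / (n_in + n_out))
    return Tensor(rng.uniform(-bound, bound, size=(n_in, n_out)), requires_grad=True)


class CellParams:
    """Per-gate weights: two input streams, one recurrent stream, one bias."""

    def __init__(self, d_in: int, d_h: int, rng: np.random.Generator):
        self.d_in = d_in
        self.d_h = d_h
        self.w_x = {g: _glorot(rng, d_in, d_h) for g in GATES}
        self.w_xp = {g: _glorot(rng, d_in, d_h) for g in GATES}
        self.w_h = {g: _glorot(rng, d_h, d_h) for g in GATES}
        self.b = {g: Tensor(np.zeros(d_h), requires_grad=True) for g in GATES}


@dataclass
class CellState:
    h: Tensor  # hidden output
    c: Tensor  # cell value
    d: Tensor  # sentence memory

    @classmethod
    def initial(cls, d_h: int, d0: Tensor | None = None) -> "CellState":
        zeros = Tensor(np.zeros(d_h))
        return cls(h=zeros, c=Tensor(np.zeros(d_h)),
                   d=d0 if d0 is not None else Tensor(np.zeros(d_h)))


def cell_step(
    x: Tensor,
    xp: Tensor,
    prev: CellState,
    params: CellParams,
    *,
    use_reading_gate: bool = True,
) -> CellState:
    """One recurrent step; raises on dimension mismatch or non-finite output."""
    if x.shape != (params.d_in,) or xp.shape != (params.d_in,):
        raise ValueError(
            f"input shape {x.shape}/{xp.shape} does not match d_in={params.d_in}"
        )

    def pre(g: str) -> Tensor:
        return (
            x @ params.w_x[g]
            + xp @ params.w_xp[g]
            + prev.h @ params.w_h[g]
            + params.b[g]
        )

    i = pre("i").sigmoid()
    f = pre("f").sigmoid()
    o = pre("o").sigmoid()
    c_tilde = pre("c").tanh()
    if use_reading_gate:
        r = pre("r").sigmoid()
        d = r * prev.d
        c = i * c_tilde + f * prev.c + d.tanh()
    else:
        d = prev.d
        c = i * c_tilde + f * prev.c
    h = o * c.tanh()
    if not np.all(np.isfinite(h.data)):
        raise FloatingPointError("non-finite hidden state (exploding values)")
    return CellState(h=h, c=c, d=d)


class BiLSTMParams:
    """Stacked bidirectional parameters plus the optional d0 projection."""

    def __init__(
        self,
        d_in: int,
        d_h: int,
        n_layers: int,
        rng: np.random.Generator,
        combine: str = "sum",
    ):
        if n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if combine not in ("sum", "concat"):
            raise ValueError(f"unknown combine mode {combine!r}")
        self.d_in = d_in
        self.d_h = d_h
        self.n_layers = n_layers
        self.combine = combine
        self.layers: list[tuple[CellParams, CellParams]] = []
        layer_in = d_in
        for _ in range(n_layers):
            self.layers.append(
                (CellParams(layer_in, d_h, rng), CellParams(layer_in, d_h, rng))
            )
            layer_in = d_h if combine == "sum" else 2 * d_h
        self.out_dim = layer_in
        # d0 lives in embedding space; project into hidden space if needed.
        self.d0_proj = None if d_in == d_h else _glorot(rng, d_in, d_h)

    def project_d0(self, d0: Tensor | None) -> Tensor | None:
        if d0 is None:
            return None
        if self.d0_proj is None:
            return d0
        return d0 @ self.d0_proj


def _run_direction(
    xs: list[Tensor],
    xps: list[Tensor],
    d0: Tensor | None,
    params: CellParams,
    *,
    reverse: bool,
    use_reading_gate: bool,
) -> list[Tensor]:
    order = range(len(xs) - 1, -1, -1) if reverse else range(len(xs))
    state = CellState.initial(params.d_h, d0)
    hs: list[Tensor | None] = [None] * len(xs)
    for t in order:
        state = cell_step(
            xs[t], xps[t], state, params, use_reading_gate=use_reading_gate
        )
        hs[t] = state.h
    return hs  # type: ignore[return-value]


def run_bilstm(
    x_seq: Tensor,
    xp_seq: Tensor,
    d0: Tensor | None,
    params: BiLSTMParams,
    *,
    use_reading_gate: bool = True,
    dropout_rate: float = 0.0,
    rng: np.random.Generator | None = None,
    train: bool = False,
) -> Tensor:
    """Encode a sentence; returns the (n, out_dim) per-token hidden matrix.

    Both directions start from the same projected d0 (the sentence vector
    is order-invariant, so it is direction-independent).  Layers above the
    first consume the previous layer's combined outputs as both input
    streams; dropout (if any) applies between layers only.
    """
    n = x_seq.shape[0]
    if n == 0 or xp_seq.shape[0] != n:
        raise ValueError("sequences must be nonempty and of equal length")
    d0_h = params.project_d0(d0)
    xs = [x_seq[t] for t in range(n)]
    xps = [xp_seq[t] for t in range(n)]
    for k, (fwd, bwd) in enumerate(params.layers):
        hf = _run_direction(
            xs, xps, d0_h, fwd, reverse=False, use_reading_gate=use_reading_gate
        )
        hb = _run_direction(
            xs, xps, d0_h, bwd, reverse=True, use_reading_gate=use_reading_gate
        )
        if params.combine == "sum":
            combined = [a + b for a, b in zip(hf, hb)]
        else:
            combined = [concat([a, b], axis=0) for a, b in zip(hf, hb)]
        if k < params.n_layers - 1 and dropout_rate > 0.0 and rng is not None:
            combined = [dropout(h, dropout_rate, rng, train) for h in combined]
        xs = combined
        xps = combined
    return stack(xs, axis=0)
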