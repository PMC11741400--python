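"""LSTM cell, dense layer and learnable layer normalization."""

from __future__ import annotations

import numpy as np

from kinetraits.nn.autodiff import Tensor, layer_norm_raw


def init_lstm(
    rng: np.random.Generator, input_dim: int, hidden: int, prefix: str = "lstm"
) -> dict[str, Tensor]:
    """Glorot-style init; forget-gate bias starts at 1."""
    scale_x = np.sqrt(2.0 / (input_dim + hidden))
    scale_h = np.sqrt(2.0 / (2 * hidden))
    bias = np.zeros(4 * hidden)
    bias[hidden : 2 * hidden] = 1.0  # forget gate
    return {
        f"{prefix}.Wx": Tensor(rng.normal(0, scale_x, (input_dim, 4 * hidden))),
        f"{prefix}.Wh": Tensor(rng.normal(0, scale_h, (hidden, 4 * hidden))),
        f"{prefix}.b": Tensor(bias),
    }


def init_dense(
    rng: np.random.Generator, input_dim: int, output_dim: int, prefix: str = "dense"
) -> dict[str, Tensor]:
    scale = np.sqrt(2.0 / (input_dim + output_dim))
    return {
        f"{prefix}.W": Tensor(rng.normal(0, scale, (input_dim, output_dim))),
        f"{prefix}.b": Tensor(np.zeros(output_dim)),
    }


def init_layer_norm(hidden: int, prefix: str = "ln") -> dict[str, Tensor]:
    return {
        f"{prefix}.gain": Tensor(np.ones(hidden)),
        f"{prefix}.bias": Tensor(np.zeros(hidden)),
    }


def dense(params: dict[str, Tensor], x: Tensor, prefix: str = "dense") -> Tensor:
    return x @ params[f"{prefix}.W"] + params[f"{prefix}.b"]


def layer_norm(params: dict[str, Tensor], x: Tensor, prefix: str = "ln") -> Tensor:
    return layer_norm_raw(x) * params[f"{prefix}.gain"] + params[f"{prefix}.bias"]


def lstm_forward(
    params: dict[str, Tensor],
    x_seq: list[Tensor],
    hidden: int,
    prefix: str = "lstm",
    return_sequence: bool = False,
) -> Tensor | list[Tensor]:
    """Run a batched LSTM over a sequence of (B, D) inputs.

    Returns the final hidden state (B, H), or the full list of per-step
    hidden states when ``return_sequence`` is set.
    """
    Wx, Wh, b = params[f"{prefix}.Wx"], params[f"{prefix}.Wh"], params[f"{prefix}.b"]
    batch = x_seq[0].data.shape[0]
    h = Tensor(np.zeros((batch, hidden)))
    c = Tensor(np.zeros((batch, hidden)))
    states: list[Tensor] = []
    for x_t in x_seq:
        z = x_t @ Wx + h @ Wh + b
        i = z.cols(0, hidden).sigmoid()
        f = z.cols(hidden, 2 * hidden).sigmoid()
        g = z.cols(2 * hidden, 3 * hidden).tanh()
        o = z.cols(3 * hidden, 4 * hidden).sigmoid()
        c = f * c + i * g
        h = o * c.tanh()
        if return_sequence:
            states.append(h)
    return states if return_sequence else h
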