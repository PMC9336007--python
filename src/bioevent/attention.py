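"""Word-level and sentence-level (multi-level) attention layers.

Word-level attention scores each token state of one sentence and condenses
the sentence into a single context vector:

    N = tanh(H);  alpha = softmax(w^T N);  gamma = H alpha^T;  h* = tanh(gamma)

Sentence-level attention operates one level up, over the pooled instance
vectors of *relevant arguments* — argument candidates sharing a trigger —
within a batch.  Each instance's vector is scaled by its softmax weight and
squashed, so the group competes for mass and mutually informative instances
reinforce each other:

    N = tanh(H_S);  alpha = softmax(w^T N);  out_i = tanh(h_{S_i} * alpha_i)

Softmax is computed with max-subtraction for overflow safety throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor, softmax, stack


def make_attention_params(dim: int, rng: np.random.Generator) -> Tensor:
    """The trained scoring vector w (one per attention layer)."""
    return Tensor(rng.uniform(-0.1, 0.1, size=dim), requires_grad=True)


@dataclass
class AttentionOutput:
    alpha: Tensor  # (L,) softmax weights, nonnegative, sum to one
    context: Tensor  # (d,) attended vector after the final tanh


def word_attention(H: Tensor, w: Tensor) -> AttentionOutput:
    """Attend over the columns of a (d, L) state matrix with vector w (d,)."""
    if H.shape[1] == 0:
        raise ValueError("cannot attend over an empty sentence")
    if H.shape[0] != w.shape[0]:
        raise ValueError(f"dim mismatch: H {H.shape} vs w {w.shape}")
    N = H.tanh()
    alpha = softmax(w @ N, axis=-1)
    gamma = H @ alpha
    return AttentionOutput(alpha=alpha, context=gamma.tanh())


def pool_instance(states: Tensor) -> Tensor:
    """Mean over the L positions of an (L, p) per-token state matrix."""
    if states.shape[0] == 0:
        raise ValueError("cannot pool an empty instance")
    return states.mean(axis=0)


def sentence_attention(
    instances: Sequence[Tensor],
    w: Tensor,
    *,
    relevance_keys: Sequence[str] | None = None,
    residual: bool = False,
) -> tuple[Tensor, list[Tensor]]:
    """Weight a group of M relevant-instance vectors against each other.

    Returns ``(alpha, outputs)`` where ``outputs[i] = tanh(v_i * alpha_i)``
    (plus ``v_i`` itself when ``residual``, a variant kept off by default).
    All instances in a group must share a relevance key (the same trigger).
    """
    if len(instances) == 0:
        raise ValueError("empty relevance group")
    if relevance_keys is not None and len(set(relevance_keys)) > 1:
        raise ValueError(
            f"mixed relevance keys in one group: {sorted(set(relevance_keys))}"
        )
    Hs = stack(list(instances), axis=1)  # (p, M)
    N = Hs.tanh()
    alpha = softmax(w @ N, axis=-1)  # (M,)
    outputs = []
    for i, v in enumerate(instances):
        gamma = v * alpha[i]
        if residual:
            gamma = gamma + v
        outputs.append(gamma.tanh())
    return alpha, outputs
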