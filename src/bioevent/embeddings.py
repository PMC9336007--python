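"""Word-embedding tables and the differential sentence embedding.

Two tables coexist during training: a *pretrained* table x_t that stays
frozen, and a *fine-tuned* table x'_t initialized as a copy of the
pretrained one and updated by backpropagation.  The sentence embedding d0
is the per-sentence mean of the difference x'_t - x_t over its tokens: zero
at initialization, and growing exactly where fine-tuning has moved words
away from their pretrained positions — a summary of the task-relevant
content of the sentence that the reading-gate cell consumes.

Vectors load from word2vec text format ("count dim" header, then one
"token v1 ... vd" line each); without a vector file both tables are
random-initialized uniformly in [-0.05, 0.05] from a seed, which keeps the
whole pipeline runnable offline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

UNK = "<UNK>"
PAD = "<PAD>"

DEFAULT_DIM = 200  # published embedding / sentence-embedding size


@dataclass
class EmbeddingTable:
    """token -> row mapping over a |V| x d matrix.

    ``vectors`` is an autodiff Tensor; ``trainable`` controls whether it
    participates in gradient updates.  The PAD row is all-zero and is
    re-zeroed after every optimizer step (:meth:`enforce_pad`).
    """

    vocabulary: dict[str, int]
    vectors: Tensor
    trainable: bool = False

    def __post_init__(self) -> None:
        for special in (UNK, PAD):
            if special not in self.vocabulary:
                raise ValueError(f"vocabulary missing special token {special}")
        self.vectors.requires_grad = self.trainable

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def index(self, token: str) -> int:
        return self.vocabulary.get(token, self.vocabulary[UNK])

    def indices(self, tokens: list[str]) -> list[int]:
        return [self.index(t) for t in tokens]

    def lookup(self, tokens: list[str]) -> Tensor:
        """(n, d) tensor of rows; differentiable when trainable."""
        return self.vectors[np.array(self.indices(tokens), dtype=np.intp)]

    def enforce_pad(self) -> None:
        self.vectors.data[self.vocabulary[PAD], :] = 0.0


def _with_specials(
    vocab: list[str], matrix: np.ndarray
) -> tuple[dict[str, int], np.ndarray]:
    unk_row = matrix.mean(axis=0) if len(matrix) else np.zeros(matrix.shape[1])
    pad_row = np.zeros(matrix.shape[1])
    full = np.vstack([matrix, unk_row[None, :], pad_row[None, :]])
    mapping = {tok: i for i, tok in enumerate(vocab)}
    mapping[UNK] = len(vocab)
    mapping[PAD] = len(vocab) + 1
    return mapping, full


def load_vectors(
    path: str, *, expected_dim: int | None = None, trainable: bool = False
) -> EmbeddingTable:
    """Load a word2vec text file into a table (plus UNK and PAD rows).

    The UNK row is the mean of all loaded vectors, so out-of-vocabulary
    tokens get a central, finite representation.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed word2vec header {header}")
        count, dim = int(header[0]), int(header[1])
        if expected_dim is not None and dim != expected_dim:
            raise ValueError(
                f"{path}: vector dimension {dim} != configured {expected_dim}"
            )
        vocab: list[str] = []
        rows = np.empty((count, dim))
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path} line {lineno}: expected {dim + 1} fields, "
                    f"got {len(parts)}"
                )
            if len(vocab) >= count:
                raise ValueError(f"{path} line {lineno}: more rows than header declares")
            vocab.append(parts[0])
            rows[len(vocab) - 1] = [float(v) for v in parts[1:]]
        if len(vocab) != count:
            raise ValueError(
                f"{path}: header declares {count} rows, found {len(vocab)}"
            )
    mapping, full = _with_specials(vocab, rows)
    return EmbeddingTable(mapping, Tensor(full, requires_grad=trainable), trainable)


def random_table(
    vocab: list[str], dim: int = DEFAULT_DIM, *, seed: int = 0, trainable: bool = False
) -> EmbeddingTable:
    """Uniform [-0.05, 0.05] table over ``vocab`` (download-free fallback)."""
    rng = np.random.default_rng(seed)
    rows = rng.uniform(-0.05, 0.05, size=(len(vocab), dim))
    mapping, full = _with_specials(list(vocab), rows)
    full[mapping[PAD], :] = 0.0
    return EmbeddingTable(mapping, Tensor(full, requires_grad=trainable), trainable)


def init_tuned(pretrained: EmbeddingTable) -> EmbeddingTable:
    """Trainable copy of a pretrained table (the x' stream's start state)."""
    return EmbeddingTable(
        dict(pretrained.vocabulary),
        Tensor(pretrained.vectors.data.copy(), requires_grad=True),
        trainable=True,
    )


def sentence_embedding(x_seq: Tensor, xp_seq: Tensor) -> Tensor:
    """d0 = (1/n) * sum_t (x'_t - x_t) over the sentence's n tokens.

    Both arguments are (n, d); the result is the (d,) sentence vector.
    Differentiable through the fine-tuned stream, so training shapes d0.
    """
    if x_seq.shape != xp_seq.shape:
        raise ValueError(f"shape mismatch {x_seq.shape} vs {xp_seq.shape}")
    if x_seq.shape[0] == 0:
        raise ValueError("sentence embedding of an empty sentence")
    return (xp_seq - x_seq).mean(axis=0)
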