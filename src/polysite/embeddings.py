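"""Sequence and function-text embeddings behind a pluggable encoder contract.

The classifier consumes a per-residue sequence embedding F_seq (L x d_s) from
a protein language model and a pooled function-text embedding F_text (d_t)
from a biomedical language model.  Both arrive through :class:`EncoderSpec`:

* ``dummy``  -- deterministic seeded encoder, a pure function of
  (input string, seed, dimension); used by the tests and fixtures.
* ``file``   -- precomputed embeddings read from an HDF5 container.
* ``adapter``-- a user-supplied callable (e.g. wrapping a real pretrained
  model); adapters must strip any begin/end special tokens so the row count
  equals the residue count.

Text-token matrices are pooled by global average pooling over the token axis.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable

import h5py
import numpy as np

from .errors import ConsistencyError, EmptyInputError, SchemaError

MAX_SEQ_LEN = 1024
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass
class SequenceEmbedding:
    values: np.ndarray  # (L, d_s)
    encoder_name: str

    @property
    def d_s(self) -> int:
        return self.values.shape[1]

    def __post_init__(self):
        if not np.all(np.isfinite(self.values)):
            raise ConsistencyError("non-finite sequence embedding")


@dataclass
class TextEmbedding:
    pooled: np.ndarray  # (d_t,)
    n_tokens: int
    encoder_name: str

    @property
    def d_t(self) -> int:
        return self.pooled.shape[0]


@dataclass
class EncoderSpec:
    kind: str  # dummy | file | adapter
    dimension: int
    seed: int = 0
    path: str | None = None
    protein_id: str | None = None  # group within the file container
    adapter: Callable[[str], np.ndarray] | None = None

    def __post_init__(self):
        if self.kind not in ("dummy", "file", "adapter"):
            raise ConsistencyError(f"unknown encoder kind {self.kind!r}")


def _seeded_rows(key: str, n_rows: int, dim: int, seed: int) -> np.ndarray:
    """Standard-normal rows from a hash of (key, seed): deterministic across
    platforms and runs."""
    digest = hashlib.sha256(f"{key}|{seed}".encode()).digest()
    rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
    return rng.standard_normal((n_rows, dim))


def embed_sequence(sequence: str, spec: EncoderSpec) -> SequenceEmbedding:
    """Per-residue embedding of an amino-acid string, one row per residue."""
    if len(sequence) == 0:
        raise EmptyInputError("empty sequence")
    if len(sequence) > MAX_SEQ_LEN:
        raise ConsistencyError(
            f"sequence length {len(sequence)} exceeds the maximum {MAX_SEQ_LEN}")
    bad = set(sequence) - AA_ALPHABET
    if bad:
        raise ConsistencyError(f"invalid residue letters {sorted(bad)}")
    if spec.kind == "dummy":
        rows = np.stack([
            _seeded_rows(f"{aa}@{i}", 1, spec.dimension, spec.seed)[0]
            for i, aa in enumerate(sequence)])
        return SequenceEmbedding(rows, f"dummy-{spec.dimension}-s{spec.seed}")
    if spec.kind == "file":
        arrays = read_embeddings(spec.path, group=spec.protein_id)
        values = arrays["seq_embedding"]
        if values.shape[0] != len(sequence):
            raise ConsistencyError(
                f"embedding rows {values.shape[0]} != sequence length {len(sequence)}")
        return SequenceEmbedding(values, f"file:{spec.path}")
    values = np.asarray(spec.adapter(sequence), dtype=float)
    if values.shape[0] != len(sequence):
        raise ConsistencyError(
            f"adapter returned {values.shape[0]} rows for {len(sequence)} residues; "
            "adapters must strip special tokens")
    return SequenceEmbedding(values, "adapter")


def embed_text_tokens(text: str, spec: EncoderSpec) -> np.ndarray:
    """Dummy token-level text encoding: one seeded row per whitespace token."""
    tokens = text.split()
    if not tokens:
        raise EmptyInputError("empty text description")
    return np.stack([
        _seeded_rows(f"tok:{t}", 1, spec.dimension, spec.seed)[0] for t in tokens])


def pool_text(token_matrix: np.ndarray, encoder_name: str = "gap") -> TextEmbedding:
    """Global average pooling over the token axis."""
    token_matrix = np.asarray(token_matrix, dtype=float)
    if token_matrix.ndim != 2 or token_matrix.shape[0] == 0:
        raise EmptyInputError("token matrix must be (n_tokens >= 1, d_t)")
    return TextEmbedding(token_matrix.mean(axis=0), token_matrix.shape[0], encoder_name)


# ---------------------------------------------------------------------------
# container I/O (HDF5, little-endian float32)
# ---------------------------------------------------------------------------

_KNOWN_ARRAYS = ("seq_embedding", "text_tokens", "text_pooled")


def write_embeddings(path, arrays: dict[str, np.ndarray], group: str | None = None) -> None:
    """Write named embedding arrays with dimension metadata."""
    if "seq_embedding" not in arrays:
        raise SchemaError("missing required array 'seq_embedding'")
    with h5py.File(path, "a") as f:
        g = f.require_group(group) if group else f
        for name, arr in arrays.items():
            if name not in _KNOWN_ARRAYS:
                raise SchemaError(f"unknown array name {name!r}")
            if name in g:
                del g[name]
            g.create_dataset(name, data=np.asarray(arr).astype("<f4"))
        g.attrs["d_s"] = arrays["seq_embedding"].shape[1]
        if "text_tokens" in arrays:
            g.attrs["d_t"] = arrays["text_tokens"].shape[1]


def read_embeddings(path, group: str | None = None) -> dict[str, np.ndarray]:
    """Read a container written by :func:`write_embeddings`; validates schema."""
    with h5py.File(path, "r") as f:
        try:
            g = f[group] if group else f
        except KeyError:
            raise SchemaError(f"container has no group {group!r}")
        if "seq_embedding" not in g:
            raise SchemaError("container missing required array 'seq_embedding'")
        out = {name: np.asarray(g[name], dtype=np.float64)
               for name in _KNOWN_ARRAYS if name in g}
        d_s = int(g.attrs.get("d_s", out["seq_embedding"].shape[1]))
        if out["seq_embedding"].shape[1] != d_s:
            raise SchemaError(
                f"d_s metadata {d_s} inconsistent with array shape "
                f"{out['seq_embedding'].shape}")
        if "text_tokens" in out:
            d_t = int(g.attrs.get("d_t", out["text_tokens"].shape[1]))
            if out["text_tokens"].shape[1] != d_t:
                raise SchemaError("d_t metadata inconsistent with text_tokens shape")
    return out


def read_fasta(path) -> dict[str, str]:
    """Sequences keyed by record id."""
    from Bio import SeqIO

    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records
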