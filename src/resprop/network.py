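"""The multi-task sequence-labelling network and its output decoding.

Architecture (default downstream): the per-residue input encoding is fed to
two parallel wide-kernel 1-D convolutions (32 channels each; kernels 129 and
257 with 'same' padding), each followed by ReLU and dropout.  Their outputs
are concatenated with the raw input (D + 64 channels), batch-normalised, and
passed through a two-layer bidirectional LSTM (hidden 1024 per direction)
and a fully connected ReLU layer.  Six linear heads then emit, per residue:
Q8 logits (8), Q3 logits (3), disorder logits (2), RSA (1, sigmoid so the
value stays in [0, 1]), and sine-cosine pairs for phi and psi (2 each, tanh
so components stay in [-1, 1]).  Absolute accessibility is derived as
ASA = RSA × max-ASA of the residue type.

An alternative downstream replaces the CNN/biLSTM stack with a transformer
encoder (8 heads, 2 layers) over sinusoidally position-encoded inputs; the
head contract is identical.  The published variant used a cyclic positional
scheme that is not further specified; the standard sinusoidal encoding used
here is itself periodic per dimension and is the documented approximation.

Sequences longer than the window limit are processed by the moving-window
plan from :mod:`resprop.encode` and the per-window head outputs are stitched
back to full length before decoding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import nn
from .core import ModelConfig, ValidationError, max_asa_vector
from .encode import EmbeddingMatrix, WindowPlan, plan_windows, split_by_plan, stitch
from .nn import Tensor

#: Task names in head (and loss-weight) order.
TASKS = ("q8", "q3", "disorder", "rsa", "phi", "psi")

#: Output width of each task head.
HEAD_WIDTHS = {"q8": 8, "q3": 3, "disorder": 2, "rsa": 1, "phi": 2, "psi": 2}

CHECKPOINT_VERSION = 1


@dataclass
class PredictionBundle:
    """Per-residue outputs of all six tasks, plus derived quantities.

    Probability rows are simplexes; ``rsa`` lies in [0, 1]; sine-cosine
    entries lie in [-1, 1]; ``asa[i] == rsa[i] * max_asa(residue i)``.
    """

    q8_probs: np.ndarray      # (L, 8)
    q3_probs: np.ndarray      # (L, 3)
    disorder_probs: np.ndarray  # (L, 2)
    rsa: np.ndarray           # (L,)
    asa: np.ndarray           # (L,)
    phi_sincos: np.ndarray    # (L, 2)
    psi_sincos: np.ndarray    # (L, 2)
    phi_deg: np.ndarray       # (L,)
    psi_deg: np.ndarray       # (L,)

    def __len__(self) -> int:
        return len(self.rsa)


def decode_angles(sincos: np.ndarray, zero_sentinel: float | None = None) -> np.ndarray:
    """Decode (sin, cos) rows to angles in degrees in (-180, 180].

    A (0, 0) row has no defined angle: it raises unless ``zero_sentinel``
    provides a value to emit instead.
    """
    sincos = np.asarray(sincos, dtype=np.float64)
    s, c = sincos[:, 0], sincos[:, 1]
    degenerate = (s == 0.0) & (c == 0.0)
    if degenerate.any():
        if zero_sentinel is None:
            pos = int(np.argmax(degenerate))
            raise ValidationError(
                f"undefined angle: sine and cosine both zero at position {pos}"
            )
    deg = np.degrees(np.arctan2(s, c))
    deg = np.where(deg <= -180.0, deg + 360.0, deg)
    if degenerate.any():
        deg = np.where(degenerate, zero_sentinel, deg)
    return deg


def encode_angles(degrees: np.ndarray) -> np.ndarray:
    """Encode angles in degrees as (sin, cos) rows."""
    rad = np.radians(np.asarray(degrees, dtype=np.float64))
    return np.stack([np.sin(rad), np.cos(rad)], axis=-1)


def rsa_to_asa(rsa: np.ndarray, sequence: str, table=None,
               unknown_default: float | None = None) -> np.ndarray:
    """Absolute accessibility: elementwise RSA × residue-type maximum (Å²)."""
    rsa = np.asarray(rsa, dtype=np.float64)
    if rsa.shape[0] != len(sequence):
        raise ValidationError(
            f"rsa has {rsa.shape[0]} entries for a sequence of {len(sequence)}"
        )
    return rsa * max_asa_vector(sequence, table, unknown_default)


class MultiTaskModel(nn.Module):
    """CNN/biLSTM (or transformer) trunk with six per-residue task heads."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        D = config.input_dim
        p = config.dropout_p

        if config.downstream == "cnn_bilstm":
            k1, k2 = config.kernel_sizes
            p1, p2 = config.paddings
            ch = config.cnn_channels
            self.conv_a = nn.Conv1d(D, ch, k1, p1, rng)
            self.conv_b = nn.Conv1d(D, ch, k2, p2, rng)
            self.feature_width = D + 2 * ch
            self.norm = nn.MaskedBatchNorm1d(self.feature_width)
            self.lstm = nn.LSTM(self.feature_width, config.lstm_hidden,
                                config.lstm_layers, rng, bidirectional=True,
                                dropout_p=p)
            trunk_out = 2 * config.lstm_hidden
        else:
            self.in_proj = nn.Linear(D, config.transformer_dim, rng)
            self.encoder_layers = [
                nn.TransformerEncoderLayer(
                    config.transformer_dim, config.transformer_heads,
                    4 * config.transformer_dim, p, rng)
                for _ in range(config.transformer_layers)
            ]
            self.feature_width = config.transformer_dim
            trunk_out = config.transformer_dim

        self.fc = nn.Linear(trunk_out, config.fc_width, rng)
        self.drop = nn.Dropout(p, rng)
        self.heads = {
            task: nn.Linear(config.fc_width, width, rng)
            for task, width in HEAD_WIDTHS.items()
        }
        # register heads for parameter traversal
        self._head_modules = list(self.heads.values())

    def __call__(self, x: np.ndarray | Tensor, mask: np.ndarray) -> dict[str, Tensor]:
        """Map a padded batch (B, L, D) plus boolean mask (B, L) to raw head
        outputs; class heads emit logits, rsa is sigmoid-activated, phi/psi
        tanh-activated."""
        xd = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float64)
        if not np.isfinite(xd).all():
            raise ValidationError("non-finite values in network input")
        if xd.ndim != 3:
            raise ValidationError(f"expected (B, L, D) input, got shape {xd.shape}")
        mask = np.asarray(mask, dtype=bool)
        lengths = mask.sum(axis=1)
        # padding must be trailing so the masked reverse scan is well defined
        if not np.array_equal(mask, np.arange(xd.shape[1])[None, :] < lengths[:, None]):
            raise ValidationError("padding mask must mark a contiguous prefix")
        x = nn.as_tensor(xd * mask[:, :, None])

        if self.config.downstream == "cnn_bilstm":
            a = self.drop(self.conv_a(x).relu())
            b = self.drop(self.conv_b(x).relu())
            feats = nn.concatenate([x, a, b], axis=2)
            feats = self.norm(feats, mask)
            feats = self.lstm(feats, lengths)
        else:
            feats = self.in_proj(x) + Tensor(
                nn.sinusoidal_positions(xd.shape[1], self.config.transformer_dim)
            )
            for layer in self.encoder_layers:
                feats = layer(feats, mask)

        hidden = self.drop(self.fc(feats).relu())
        out = {task: head(hidden) for task, head in self.heads.items()}
        out["rsa"] = out["rsa"].sigmoid()
        out["phi"] = out["phi"].tanh()
        out["psi"] = out["psi"].tanh()
        return out


def build_model(config: ModelConfig) -> MultiTaskModel:
    """Construct the default CNN/biLSTM multi-task model."""
    if config.downstream != "cnn_bilstm":
        raise ValidationError("build_model expects downstream='cnn_bilstm'")
    return MultiTaskModel(config)


def build_transformer_variant(config: ModelConfig) -> MultiTaskModel:
    """Construct the transformer-encoder downstream variant."""
    if config.downstream != "transformer":
        raise ValidationError("build_transformer_variant expects downstream='transformer'")
    return MultiTaskModel(config)


def heads_to_bundle(raw: dict[str, np.ndarray], sequence: str,
                    table=None, unknown_default: float | None = None) -> PredictionBundle:
    """Post-process raw per-residue head outputs (L-length arrays) into a
    :class:`PredictionBundle`: softmax class probabilities, decoded angles
    and derived ASA."""

    def softmax_rows(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    rsa = raw["rsa"][:, 0]
    phi_sc = raw["phi"]
    psi_sc = raw["psi"]
    return PredictionBundle(
        q8_probs=softmax_rows(raw["q8"]),
        q3_probs=softmax_rows(raw["q3"]),
        disorder_probs=softmax_rows(raw["disorder"]),
        rsa=rsa,
        asa=rsa_to_asa(rsa, sequence, table, unknown_default),
        phi_sincos=phi_sc,
        psi_sincos=psi_sc,
        phi_deg=decode_angles(phi_sc, zero_sentinel=0.0),
        psi_deg=decode_angles(psi_sc, zero_sentinel=0.0),
    )


def predict_bundle(model: MultiTaskModel, embedding: EmbeddingMatrix | np.ndarray,
                   sequence: str, window_size: int = 1024,
                   window_stride: int = 824, window_trim: int = 50) -> PredictionBundle:
    """Predict all tasks for one sequence, windowing if it exceeds the limit.

    The model is run in eval mode on each planned window; raw head outputs
    are stitched to full length using the plan's keep intervals, then
    decoded.
    """
    values = embedding.values if isinstance(embedding, EmbeddingMatrix) else np.asarray(embedding)
    L = values.shape[0]
    if L != len(sequence):
        raise ValidationError(
            f"embedding rows ({L}) do not match sequence length ({len(sequence)})"
        )
    model.eval()
    plan: WindowPlan = plan_windows(L, window_size, window_stride, window_trim)
    per_window: list[dict[str, np.ndarray]] = []
    for block in split_by_plan(values, plan):
        mask = np.ones((1, block.shape[0]), dtype=bool)
        out = model(block[None, :, :], mask)
        per_window.append({t: v.data[0] for t, v in out.items()})
    raw = {
        t: stitch([w[t] for w in per_window], plan) for t in TASKS
    }
    cfg = model.config
    return heads_to_bundle(raw, sequence, cfg.max_asa, cfg.max_asa_unknown)


def save_checkpoint(model: MultiTaskModel, path) -> None:
    """Write config + parameters to a single ``.npz`` checkpoint."""
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config": model.config.to_dict()})
    state = model.state_dict()
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **state)


def load_checkpoint(path) -> MultiTaskModel:
    """Rebuild a model from a checkpoint written by :func:`save_checkpoint`."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValidationError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        config = ModelConfig.from_dict(meta["config"])
        config.max_asa = {k: float(v) for k, v in config.max_asa.items()}
        model = MultiTaskModel(config)
        model.load_state_dict({k: archive[k] for k in archive.files if k != "__meta__"})
    return model
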