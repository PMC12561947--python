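"""Spatiotemporal cough classifier.

A modified residual CNN (single-channel stem, classification head removed)
encodes each range-Doppler frame independently to a 512-dim embedding which
a linear layer projects to the model dimension (256 by default):

    f_t = G_resnet(X_t),   t = 1..T

A two-layer multi-head self-attention encoder (4 heads, post-norm blocks
with position-wise feed-forward networks) contextualizes the frame features
over time, temporal mean pooling collapses them to one vector, and a linear
classifier produces the two-class logits:

    h_{1..T} = SelfAttention(f_{1..T});  k = mean_t h_t;  p = softmax(W k + b)

Training minimizes mean cross-entropy.  Sinusoidal positional encodings are
added before the attention stack by default (without them the
attention + mean-pool composition is order-invariant); ``none`` disables
them.  Ablation variants: ``resnet_only`` (frame features mean-pooled
straight into the classifier) and ``attention_only`` (flattened frames
linearly embedded, no CNN).
"""

from __future__ import annotations

import json

import numpy as np

from . import nn
from .config import ModelConfig
from .pipeline import RDMSequence


class CoughClassifier(nn.Module):
    """Binary cough/non-cough classifier over RDM sequences."""

    def __init__(self, cfg: ModelConfig | None = None,
                 rng: np.random.Generator | int | None = None,
                 frame_shape: tuple[int, int] = (48, 125),
                 dtype=np.float32):
        super().__init__()
        self.cfg = cfg = cfg or ModelConfig()
        if isinstance(rng, (int, np.integer)) or rng is None:
            rng = np.random.default_rng(0 if rng is None else int(rng))
        self.frame_shape = tuple(frame_shape)
        self.dtype = dtype

        d = cfg.feature_dim
        if cfg.variant == "attention_only":
            self.trunk = None
            self.proj = nn.Linear(int(np.prod(frame_shape)), d, rng, dtype=dtype)
        else:
            self.trunk = nn.ResNetTrunk(
                depth=cfg.backbone_depth, in_channels=1,
                base_channels=cfg.base_channels, rng=rng, dtype=dtype,
            )
            self.proj = nn.Linear(self.trunk.out_dim, d, rng, dtype=dtype)

        if cfg.variant == "resnet_only":
            self.pos_enc = None
            self.encoder = []
        else:
            self.pos_enc = (
                nn.SinusoidalPositionalEncoding(d)
                if cfg.positional_encoding == "sinusoidal" else None
            )
            self.encoder = [
                nn.TransformerEncoderLayer(d, cfg.num_heads, cfg.ffn_hidden_dim,
                                           rng, dtype=dtype)
                for _ in range(cfg.num_attention_layers)
            ]
        self.head = nn.Linear(d, cfg.num_classes, rng, dtype=dtype)

    # -- stage-by-stage API (single sequence) --------------------------------

    def spatial_features(self, seq: RDMSequence | np.ndarray) -> np.ndarray:
        """Per-frame embeddings: (T, 1, H, W) -> (T, feature_dim)."""
        x = seq.data if isinstance(seq, RDMSequence) else np.asarray(seq)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (T, 1, H, W) sequence, got {x.shape}")
        return self._encode_frames(x[None].astype(self.dtype))[0]

    def temporal_features(self, f: np.ndarray) -> np.ndarray:
        """Contextualize frame features over time: (T, d) -> (T, d)."""
        f = np.asarray(f)
        if f.ndim != 2 or f.shape[1] != self.cfg.feature_dim:
            raise ValueError(
                f"expected (T, {self.cfg.feature_dim}) features, got {f.shape}"
            )
        return self._encode_time(f[None].astype(self.dtype))[0]

    @staticmethod
    def pool(h: np.ndarray) -> np.ndarray:
        """Temporal mean pooling: (T, d) -> (d,)."""
        h = np.asarray(h)
        if h.ndim != 2 or h.shape[0] == 0:
            raise ValueError("pooling needs a non-empty (T, d) array")
        return h.mean(axis=0)

    def classify(self, k: np.ndarray) -> dict:
        """Linear classifier + softmax on one pooled vector."""
        logits = self.head.forward(np.asarray(k, dtype=self.dtype)[None])[0]
        probs = nn.softmax(logits[None])[0]
        return {"logits": logits, "probs": probs}

    # -- batched internals ----------------------------------------------------

    def _encode_frames(self, x: np.ndarray) -> np.ndarray:
        """(B, T, 1, H, W) -> (B, T, d)."""
        B, T = x.shape[:2]
        if self.trunk is None:
            flat = x.reshape(B, T, -1)
            return self.proj.forward(flat)
        frames = x.reshape(B * T, *x.shape[2:])
        feats = self.proj.forward(self.trunk.forward(frames))
        return feats.reshape(B, T, -1)

    def _encode_time(self, f: np.ndarray) -> np.ndarray:
        """(B, T, d) -> (B, T, d)."""
        h = f
        if self.pos_enc is not None:
            h = self.pos_enc.forward(h)
        for layer in self.encoder:
            h = layer.forward(h)
        return h

    def forward(self, batch: np.ndarray) -> np.ndarray:
        """(B, T, 1, H, W) batch of sequences -> (B, num_classes) logits."""
        x = np.asarray(batch, dtype=self.dtype)
        if x.ndim == 4:
            x = x[None]
        if x.ndim != 5 or x.shape[2] != 1:
            raise ValueError(f"expected (B, T, 1, H, W) batch, got {x.shape}")
        self._batch_shape = x.shape
        f = self._encode_frames(x)
        h = self._encode_time(f)
        self._T = h.shape[1]
        k = h.mean(axis=1)
        return self.head.forward(k)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        B, T = self._batch_shape[:2]
        dk = self.head.backward(dlogits)
        dh = np.repeat(dk[:, None, :], self._T, axis=1) / self._T
        for layer in reversed(self.encoder):
            dh = layer.backward(dh)
        if self.pos_enc is not None:
            dh = self.pos_enc.backward(dh)
        if self.trunk is None:
            dflat = self.proj.backward(dh)
            return dflat.reshape(self._batch_shape)
        dframes = self.trunk.backward(self.proj.backward(dh.reshape(B * T, -1)))
        return dframes.reshape(self._batch_shape)

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """(B, T, 1, H, W) -> (B, 2) class probabilities (no state change)."""
        return nn.softmax(self.forward(batch))


def ce_loss(probs: np.ndarray, labels: np.ndarray) -> float:
    """Mean cross-entropy of predicted probabilities against integer labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    n = probs.shape[0]
    p_correct = probs[np.arange(n), labels]
    return float(-np.mean(np.log(np.maximum(p_correct, 1e-300))))


def save_checkpoint(path, model: CoughClassifier, extra: dict | None = None):
    """Persist weights + config (npz; text-loadable with numpy only)."""
    arrays = {f"param_{i:04d}": p.value for i, p in enumerate(model.parameters())}
    meta = {
        "config": model.cfg.__dict__,
        "frame_shape": list(model.frame_shape),
        "extra": extra or {},
    }
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[CoughClassifier, dict]:
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        keys = sorted(k for k in archive.files if k.startswith("param_"))
        state = [archive[k] for k in keys]
    model = CoughClassifier(ModelConfig(**meta["config"]),
                            frame_shape=tuple(meta["frame_shape"]))
    model.load_state_dict(state)
    return model, meta["extra"]
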