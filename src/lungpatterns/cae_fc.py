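"""Dual-channel 3D convolutional autoencoder with a feature-constructor head.

The encoder is a stack of stride-2 3x3x3 convolutions ending in E channels;
the nonnegative (ReLU) activations are averaged over the remaining spatial
support to give the length-E embedding.  The feature constructor (FC) is a
hard top-k gate: the k largest activations pass, the rest are zeroed, and the
ROI's pattern-cluster is the index of the maximal activation (lowest index on
ties).  The decoder mirrors the encoder with nearest-neighbour upsampling +
convolution stages and reconstructs both channels from the gated embedding.
Training minimises mean squared reconstruction error with Adam; gate
gradients are straight-through.

Determinism contract: given one seed, repeat runs in the same process
reproduce parameters, loss traces, and cluster assignments bitwise.
Cross-platform bitwise reproducibility is not promised.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .preprocessing import ROI


@dataclass
class CAEFCConfig:
    embedding_size: int
    encoder_channels: tuple[int, ...] = (16, 32, 64)
    roi_size_vox: int = 32
    gate_keep_k: int = 1
    learning_rate: float = 1e-3
    batch_size: int = 16
    epochs: int = 5
    balance_weight: float = 0.0
    seed: int = 0

    def __post_init__(self):
        self.encoder_channels = tuple(self.encoder_channels)
        e = self.embedding_size
        if not 1 <= self.gate_keep_k <= e:
            raise ValueError("gate_keep_k must be in [1, embedding_size]")
        n_stages = len(self.encoder_channels) + 1
        if self.roi_size_vox % (2 ** n_stages) != 0:
            raise ValueError(
                f"roi_size_vox {self.roi_size_vox} must be divisible by "
                f"2^{n_stages} (one halving per convolution stage)")

    @property
    def bottleneck_size(self) -> int:
        return self.roi_size_vox // (2 ** (len(self.encoder_channels) + 1))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class CAEFCModel:
    """Encoder / top-k gate / decoder with explicit-backprop numpy layers."""

    def __init__(self, config: CAEFCConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = [2, *config.encoder_channels, config.embedding_size]
        self.encoder: list = []
        for i, (cin, cout) in enumerate(zip(chans[:-1], chans[1:])):
            self.encoder.append(nn.Conv3d(cin, cout, stride=2, rng=rng))
            if i < len(chans) - 2:
                self.encoder.append(nn.ReLU())
        self.pool = nn.SpatialMean()
        # Standardising the pooled embedding channels across the batch before
        # the final ReLU keeps the argmax winner input-dependent; without it
        # the top-k gate collapses onto a single pattern-cluster.
        self.emb_norm = nn.BatchNorm(config.embedding_size, affine=True)
        self.emb_relu = nn.ReLU()
        self.gate = _TopKGate(config.gate_keep_k)
        self.broadcast = nn.Broadcast(config.bottleneck_size)
        dec_chans = [config.embedding_size, *reversed(config.encoder_channels)]
        self.decoder: list = []
        for cin, cout in zip(dec_chans[:-1], dec_chans[1:]):
            self.decoder += [nn.Upsample2(), nn.Conv3d(cin, cout, stride=1, rng=rng), nn.ReLU()]
        self.decoder += [nn.Upsample2(), nn.Conv3d(dec_chans[-1], 2, stride=1, rng=rng)]
        self.training_loss_trace: list[float] = []

    # -- parameter plumbing -------------------------------------------------
    def parameters(self):
        params = []
        for layer in [*self.encoder, self.emb_norm, *self.decoder]:
            params += layer.params()
        return params

    def state_arrays(self):
        """All persistent arrays: learnable parameters + normalisation stats."""
        arrays = [p for p, _ in self.parameters()]
        for layer in [*self.encoder, self.emb_norm, *self.decoder]:
            if hasattr(layer, "state_arrays"):
                arrays += layer.state_arrays()
        return arrays

    def set_training(self, flag: bool) -> None:
        for layer in [*self.encoder, self.emb_norm, *self.decoder]:
            if hasattr(layer, "training"):
                layer.training = flag

    def digest(self) -> str:
        """SHA-256 over all persistent arrays (leakage / reproducibility checks)."""
        h = hashlib.sha256()
        for p in self.state_arrays():
            h.update(np.ascontiguousarray(p).tobytes())
        return h.hexdigest()

    # -- forward passes ------------------------------------------------------
    def encode_batch(self, x: np.ndarray) -> np.ndarray:
        """(B, 2, s, s, s) -> nonnegative embeddings (B, E)."""
        self._check_input(x)
        h = x
        for layer in self.encoder:
            h = layer.forward(h)
        h = self.pool.forward(h)
        return self.emb_relu.forward(self.emb_norm.forward(h))

    def decode_batch(self, gated: np.ndarray) -> np.ndarray:
        """(B, E) gated embeddings -> reconstructions (B, 2, s, s, s)."""
        if gated.ndim != 2 or gated.shape[1] != self.config.embedding_size:
            raise ValueError("gated embedding length must equal embedding_size")
        h = self.broadcast.forward(gated.astype(np.float32))
        for layer in self.decoder:
            h = layer.forward(h)
        return h

    def forward_batch(self, x: np.ndarray):
        emb = self.encode_batch(x)
        gated = self.gate.forward(emb)
        recon = self.decode_batch(gated)
        return emb, gated, recon

    def backward_batch(self, grad_recon: np.ndarray,
                       grad_embedding: np.ndarray | None = None) -> None:
        g = grad_recon
        for layer in reversed(self.decoder):
            g = layer.backward(g)
        g = self.broadcast.backward(g)
        g = self.gate.backward(g)
        if grad_embedding is not None:
            g = g + grad_embedding
        g = self.emb_norm.backward(self.emb_relu.backward(g))
        g = self.pool.backward(g)
        for layer in reversed(self.encoder):
            g = layer.backward(g)

    def _check_input(self, x: np.ndarray) -> None:
        s = self.config.roi_size_vox
        if x.ndim != 5 or x.shape[1] != 2 or x.shape[2:] != (s, s, s):
            raise ValueError(f"expected input of shape (B, 2, {s}, {s}, {s}), got {x.shape}")


class _TopKGate:
    """Hard top-k gate with straight-through gradients."""

    def __init__(self, k: int):
        self.k = k

    def params(self):
        return []

    def forward(self, emb: np.ndarray) -> np.ndarray:
        gated, _ = construct_features(emb, self.k)
        return gated.astype(np.float32)

    def backward(self, g: np.ndarray) -> np.ndarray:
        return g


@dataclass(frozen=True)
class ClusterAssignment:
    subject_id: str
    origin_vox: tuple[int, int, int]
    cluster_id: int
    max_activation: float


def construct_features(embedding: np.ndarray, gate_keep_k: int):
    """Keep the k largest activations, zero the rest; cluster = argmax index.

    Accepts a single length-E vector or a (B, E) batch.  Ties are broken
    toward the lowest index, both for cluster assignment and for which of the
    tied activations the gate preserves (stable sort order).
    """
    emb = np.asarray(embedding)
    single = emb.ndim == 1
    mat = emb[None, :] if single else emb
    e = mat.shape[1]
    if not 1 <= gate_keep_k <= e:
        raise ValueError("gate_keep_k out of range")
    order = np.argsort(-mat, axis=1, kind="stable")
    keep = order[:, :gate_keep_k]
    gated = np.zeros_like(mat)
    rows = np.arange(mat.shape[0])[:, None]
    gated[rows, keep] = mat[rows, keep]
    clusters = order[:, 0]
    if single:
        return gated[0], int(clusters[0])
    return gated, clusters.astype(int)


def _roi_array(roi) -> np.ndarray:
    return roi.values if isinstance(roi, ROI) else np.asarray(roi)


def encode(model: CAEFCModel, roi) -> np.ndarray:
    """Length-E nonnegative embedding of one ROI."""
    x = _roi_array(roi).astype(np.float32)[None]
    return model.encode_batch(x)[0]


def decode(model: CAEFCModel, gated_embedding: np.ndarray) -> np.ndarray:
    """Reconstruct a (2, s, s, s) ROI from a gated length-E embedding."""
    out = model.decode_batch(np.asarray(gated_embedding, np.float32)[None])[0]
    if not np.isfinite(out).all():
        raise RuntimeError("non-finite reconstruction")
    return out


def train_cae_fc(rois: list, config: CAEFCConfig) -> CAEFCModel:
    """Train on ROIs by MSE over both channels; per-epoch loss trace recorded."""
    if len(rois) < config.batch_size:
        raise ValueError(f"need at least batch_size={config.batch_size} ROIs, got {len(rois)}")
    x_all = np.stack([_roi_array(r) for r in rois]).astype(np.float32)
    model = CAEFCModel(config)
    opt = nn.Adam(model.parameters(), lr=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 1)
    n = len(rois)
    bs = config.batch_size
    model.set_training(True)
    for epoch in range(config.epochs):
        perm = shuffle_rng.permutation(n)
        losses = []
        for start in range(0, n - bs + 1, bs):
            xb = x_all[perm[start:start + bs]]
            emb, _, recon = model.forward_batch(xb)
            diff = recon - xb
            loss = float(np.mean(diff.astype(np.float64) ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, step {start // bs}: {loss}")
            opt.zero_grad()
            grad_emb = None
            if config.balance_weight > 0:
                # Entropy balancing of batch-mean activations: gradient of
                # lambda * sum_c p_c ln p_c, p = mean activation share.  Keeps
                # the top-k gate from collapsing onto a single pattern-cluster;
                # cluster assignment semantics are untouched.
                m = emb.mean(axis=0).astype(np.float64) + 1e-9
                p = m / m.sum()
                a = float((p * np.log(p)).sum())
                grad_m = config.balance_weight * (np.log(p) - a) / m.sum()
                grad_emb = np.broadcast_to(
                    (grad_m / bs).astype(np.float32), emb.shape)
            model.backward_batch((2.0 / diff.size * diff).astype(np.float32),
                                 grad_embedding=grad_emb)
            opt.step()
            losses.append(loss)
        model.training_loss_trace.append(float(np.mean(losses)))
    model.set_training(False)
    return model


def assign_clusters(model: CAEFCModel, rois: list, batch_size: int = 64) -> list[ClusterAssignment]:
    """One assignment per ROI via encode + construct_features (batched)."""
    out: list[ClusterAssignment] = []
    k = model.config.gate_keep_k
    for i in range(0, len(rois), batch_size):
        chunk = rois[i:i + batch_size]
        x = np.stack([_roi_array(r) for r in chunk]).astype(np.float32)
        emb = model.encode_batch(x)
        _, clusters = construct_features(emb, k)
        for roi, emb_row, cid in zip(chunk, emb, clusters):
            sid = roi.subject_id if isinstance(roi, ROI) else ""
            origin = roi.origin_vox if isinstance(roi, ROI) else (0, 0, 0)
            out.append(ClusterAssignment(subject_id=sid, origin_vox=tuple(origin),
                                         cluster_id=int(cid),
                                         max_activation=float(emb_row[cid])))
    return out


def save_model(model: CAEFCModel, path) -> None:
    arrays = {f"state_{i}": a for i, a in enumerate(model.state_arrays())}
    arrays["loss_trace"] = np.asarray(model.training_loss_trace)
    arrays["config_json"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(str(path), **arrays)


def load_model(path) -> CAEFCModel:
    with np.load(str(path)) as data:
        cfg = CAEFCConfig(**json.loads(bytes(data["config_json"]).decode()))
        model = CAEFCModel(cfg)
        for i, a in enumerate(model.state_arrays()):
            a[...] = data[f"state_{i}"]
        model.training_loss_trace = [float(v) for v in data["loss_trace"]]
    return model


def assignments_frame(assignments: list[ClusterAssignment]):
    import pandas as pd

    return pd.DataFrame(
        [{"subject_id": a.subject_id, "z": a.origin_vox[0], "y": a.origin_vox[1],
          "x": a.origin_vox[2], "cluster_id": a.cluster_id,
          "max_activation": a.max_activation} for a in assignments])
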