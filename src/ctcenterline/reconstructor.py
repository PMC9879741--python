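"""Localizer-to-volume synthesis: an encoder--decoder network that maps the
2D AP localizer to the 3D coronal volume.

The 2D-to-3D mechanism: the network is a 2D U-Net over the (lateral, Z)
plane whose final layer emits ``output_ap_bins`` channels, interpreted as the
AP dimension of the coronal volume.  This keeps the stride-2x2 downsampling a
genuinely 2D operation while producing a full 3D output.  Defaults follow the
reference training recipe (five encoder/decoder levels with batch
normalization and ReLU, 50 epochs, batch size 1, Adam, no augmentation);
desk-scale configurations (depth 3, 48x32 inputs, 64 AP bins) train in
minutes on one CPU.

The public surface is model/results shaped: build a
:class:`LocalizerToVolumeModel`, call :meth:`~LocalizerToVolumeModel.fit`,
get a :class:`ReconstructionResults` carrying the loss history and
prediction/checkpoint methods.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import _nn
from .core import Volume3D
from .preprocess import CropRecord, TrainingPair, volume_from_prediction

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "LocalizerToVolumeModel",
    "ReconstructionResults",
    "build_model",
    "train",
    "predict_volume",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture knobs.

    ``input_shape`` is (lateral, Z) of the preprocessed localizer;
    ``output_ap_bins`` the AP depth of the coronal output volume.  Inputs not
    divisible by ``stride**depth`` are reflect-padded up to the next multiple
    and the output cropped back.
    """

    depth: int = 5
    base_channels: int = 16
    output_ap_bins: int = 184
    input_shape: Tuple[int, int] = (144, 64)
    norm: bool = True
    stride: int = 2
    global_context: bool = True
    global_context_lr_scale: float = 8.0
    shift_head: bool = True
    shift_head_lr_scale: float = 1.0

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.stride != 2:
            raise ValueError("only stride 2 is supported")

    def padded_shape(self) -> Tuple[int, int]:
        m = self.stride ** self.depth
        return tuple(int(np.ceil(s / m) * m) for s in self.input_shape)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_shape"] = list(self.input_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["input_shape"] = tuple(d["input_shape"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe (Adam, batch size 1, no augmentation by default)."""

    epochs: int = 50
    batch_size: int = 1
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    loss: str = "mse"
    seed: int = 0
    augmentation: str = "none"

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if self.loss not in ("mse", "l1"):
            raise ValueError("loss must be 'mse' or 'l1'")
        if self.augmentation != "none":
            raise ValueError("no augmentation strategies are implemented")

    def to_dict(self) -> dict:
        return asdict(self)


class LocalizerToVolumeModel:
    """U-Net-style encoder--decoder with skip connections (numpy backend)."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        self.seed = int(seed)
        self.preprocess_hash: Optional[str] = None
        rng = np.random.default_rng(self.seed)
        d, base = config.depth, config.base_channels

        enc_ch = [base * 2 ** i for i in range(d)]
        self.encoders = []
        in_ch = 1
        for c in enc_ch:
            block = [_nn.Conv2d(in_ch, c, k=3, stride=2, rng=rng)]
            if config.norm:
                block.append(_nn.BatchNorm2d(c))
            block.append(_nn.ReLU())
            self.encoders.append(_nn.Sequential(*block))
            in_ch = c

        bneck = []
        for _ in range(2):
            bneck.append(_nn.Conv2d(in_ch, in_ch, k=3, stride=1, rng=rng))
            if config.norm:
                bneck.append(_nn.BatchNorm2d(in_ch))
            bneck.append(_nn.ReLU())
        if config.global_context:
            bneck.append(_nn.GlobalContext(in_ch, rng=rng,
                                           lr_scale=config.global_context_lr_scale))
        self.bottleneck = _nn.Sequential(*bneck)

        # decoder level i restores resolution r_i; applied top-down.
        # Two convs per block: one to merge the upsampled and skip features,
        # one to sharpen past the blocky nearest-neighbour upsampling.
        self.upsamples = []
        self.dec_blocks = []
        self._skip_channels = []
        up_ch = in_ch
        for i in range(d - 1, -1, -1):
            skip_ch = 1 if i == 0 else enc_ch[i - 1]
            out_ch = base if i == 0 else enc_ch[i - 1]
            block = [_nn.Conv2d(up_ch + skip_ch, out_ch, k=3, stride=1, rng=rng)]
            if config.norm:
                block.append(_nn.BatchNorm2d(out_ch))
            block.append(_nn.ReLU())
            block.append(_nn.Conv2d(out_ch, out_ch, k=3, stride=1, rng=rng))
            if config.norm:
                block.append(_nn.BatchNorm2d(out_ch))
            block.append(_nn.ReLU())
            self.upsamples.append(_nn.UpsampleNearest2())
            self.dec_blocks.append(_nn.Sequential(*block))
            self._skip_channels.append(skip_ch)
            up_ch = out_ch

        head = []
        if config.global_context:
            head.append(_nn.GlobalContext(up_ch, rng=rng,
                                          lr_scale=config.global_context_lr_scale))
        head.append(_nn.Conv2d(up_ch, 2 * base, k=3, stride=1, rng=rng))
        if config.norm:
            head.append(_nn.BatchNorm2d(2 * base))
        head.append(_nn.ReLU())
        final = _nn.Conv2d(2 * base, config.output_ap_bins, k=1, stride=1,
                           rng=rng)
        final.W[...] = 0.0  # zero-init head: start from a flat volume
        head.append(final)
        self.head = _nn.Sequential(*head)

        # global vertical-placement head: a scalar AP shift (output-bin
        # units) predicted from pooled bottleneck features and applied as a
        # differentiable warp -- factors WHERE the body sits out of the
        # texture synthesis, which stride-2 convolutions render only slowly.
        # The branch is normalization-free on purpose: per-image batch
        # statistics (batch size 1) would erase the global width/intensity
        # information that encodes the geometric magnification.
        self.shift_branch = None
        self.shift_mlp = None
        if config.shift_head:
            sb_ch = 16
            self.shift_branch = _nn.Sequential(
                _nn.Conv2d(1, 8, k=3, stride=2, rng=rng), _nn.LeakyReLU(),
                _nn.Conv2d(8, sb_ch, k=3, stride=2, rng=rng), _nn.LeakyReLU(),
                _nn.Conv2d(sb_ch, sb_ch, k=3, stride=2, rng=rng), _nn.LeakyReLU(),
            )
            self.shift_mlp = _nn.ShiftMLP(sb_ch, hidden=16, rng=rng,
                                          lr_scale=config.shift_head_lr_scale)

    # -- plumbing ----------------------------------------------------------

    def _layers(self) -> List[_nn.Layer]:
        out: List[_nn.Layer] = []
        for s in self.encoders:
            out.extend(s.iter_layers())
        out.extend(self.bottleneck.iter_layers())
        for s in self.dec_blocks:
            out.extend(s.iter_layers())
        out.extend(self.head.iter_layers())
        if self.shift_mlp is not None:
            out.extend(self.shift_branch.iter_layers())
            out.append(self.shift_mlp)
        return out

    def parameter_count(self) -> int:
        return sum(int(p.size) for l in self._layers()
                   for p in l.params().values())

    def _pad_input(self, x: np.ndarray) -> Tuple[np.ndarray, Tuple[int, int]]:
        H, W = self.config.input_shape
        if x.shape[-2:] != (H, W):
            raise ValueError(
                f"localizer shape {x.shape[-2:]} does not match model input "
                f"{(H, W)}"
            )
        Hp, Wp = self.config.padded_shape()
        ph, pw = Hp - H, Wp - W
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)), mode="reflect")
        return x, (ph, pw)

    # -- forward / backward ------------------------------------------------

    def _forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        feats = [x]
        h = x
        for enc in self.encoders:
            h = enc.forward(h, training)
            feats.append(h)
        h = self.bottleneck.forward(h, training)
        if self.shift_mlp is not None:
            sb = self.shift_branch.forward(x, training)
            self._sb_shape = sb.shape
            g = sb.mean(axis=(2, 3))
            self._shift = self.shift_mlp.forward(g, training)
        self._feats = feats
        self._split_at = []
        d = self.config.depth
        for j in range(d):
            i = d - 1 - j
            h = self.upsamples[j].forward(h, training)
            skip = feats[i]
            self._split_at.append(h.shape[1])
            h = np.concatenate([h, skip], axis=1)
            h = self.dec_blocks[j].forward(h, training)
        v = self.head.forward(h, training)
        if self.shift_mlp is not None:
            self._v_shape = v.shape
            v, self._warp_cache = _nn.warp_channels(v, self._shift)
        return v

    def _backward(self, dout: np.ndarray) -> None:
        d = self.config.depth
        if self.shift_mlp is not None:
            dout, ds = _nn.warp_channels_backward(dout, self._v_shape,
                                                  self._warp_cache)
            dg = self.shift_mlp.backward(ds)
            _, _, Hb, Wb = self._sb_shape
            self.shift_branch.backward(
                np.broadcast_to(dg[:, :, None, None],
                                self._sb_shape).astype(np.float32)
                / np.float32(Hb * Wb))
        grad = self.head.backward(dout)
        skip_grads: List[Optional[np.ndarray]] = [None] * (d + 1)
        for j in range(d - 1, -1, -1):
            i = d - 1 - j
            grad = self.dec_blocks[j].backward(grad)
            n_up = self._split_at[j]
            g_up, g_skip = grad[:, :n_up], grad[:, n_up:]
            skip_grads[i] = g_skip
            grad = self.upsamples[j].backward(g_up)
        grad = self.bottleneck.backward(grad)
        for i in range(d - 1, -1, -1):
            if i < d - 1 and skip_grads[i + 1] is not None:
                grad = grad + skip_grads[i + 1]
            grad = self.encoders[i].backward(grad)

    # -- public API --------------------------------------------------------

    def fit(self, pairs: Sequence[TrainingPair],
            train_config: TrainConfig = TrainConfig()) -> "ReconstructionResults":
        """Train on preprocessed pairs; returns results with the per-epoch
        loss history.  Deterministic for fixed data, config, and seed."""
        if len(pairs) == 0:
            raise ValueError("need at least one training pair")
        shapes = {p.localizer_in.shape for p in pairs}
        if len(shapes) != 1:
            raise ValueError(f"training pairs have mixed shapes: {shapes}")
        for p in pairs:
            if p.volume_out is None:
                raise ValueError(f"pair {p.case_id} has no target volume")

        loss_fn = _nn.mse_loss if train_config.loss == "mse" else _nn.l1_loss
        opt = _nn.Adam(self._layers(), lr=train_config.learning_rate)
        rng = np.random.default_rng(train_config.seed)

        X = np.stack([p.localizer_in for p in pairs]).astype(np.float32)[:, None]
        Y = np.stack([p.volume_out for p in pairs]).astype(np.float32)

        history: List[float] = []
        n = len(pairs)
        bs = train_config.batch_size
        for epoch in range(train_config.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, bs):
                idx = perm[start:start + bs]
                xb, _ = self._pad_input(X[idx])
                pred = self._forward(xb, training=True)
                pred = self._crop_output(pred)
                loss, dgrad = loss_fn(pred, Y[idx])
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss {loss} at epoch {epoch}, "
                        f"cases {[pairs[i].case_id for i in idx]}"
                    )
                self._backward(self._pad_grad(dgrad))
                opt.step()
                losses.append(loss)
            history.append(float(np.mean(losses)))
        return ReconstructionResults(model=self, loss_history=history,
                                     train_config=train_config)

    def _crop_output(self, pred: np.ndarray) -> np.ndarray:
        H, W = self.config.input_shape
        return pred[:, :, :H, :W]

    def _pad_grad(self, dgrad: np.ndarray) -> np.ndarray:
        Hp, Wp = self.config.padded_shape()
        H, W = self.config.input_shape
        if (Hp, Wp) == (H, W):
            return dgrad
        out = np.zeros(dgrad.shape[:2] + (Hp, Wp), dtype=np.float32)
        out[:, :, :H, :W] = dgrad
        return out

    def predict_array(self, localizer_in: np.ndarray) -> np.ndarray:
        """Coronal (AP, lateral, Z) prediction in [0, 1] for one preprocessed
        localizer of shape (lateral, Z)."""
        x = localizer_in.astype(np.float32)[None, None]
        xb, _ = self._pad_input(x)
        pred = self._crop_output(self._forward(xb, training=False))[0]
        return np.clip(pred, 0.0, 1.0)

    def predict_volume(self, localizer_in: np.ndarray,
                       crop_record: CropRecord) -> Volume3D:
        """Predict and place the result back into the scanner frame (axial
        orientation, mm grid reconstructed from the crop record)."""
        return volume_from_prediction(self.predict_array(localizer_in),
                                      crop_record)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        arrays = {}
        for li, layer in enumerate(self._layers()):
            for name, p in layer.params().items():
                arrays[f"p_{li}_{name}"] = p
            if isinstance(layer, _nn.BatchNorm2d):
                arrays[f"p_{li}_running_mean"] = layer.running_mean
                arrays[f"p_{li}_running_var"] = layer.running_var
        meta = {
            "model_config": self.config.to_dict(),
            "seed": self.seed,
            "preprocess_hash": self.preprocess_hash,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, expected_preprocess_hash: Optional[str] = None
             ) -> "LocalizerToVolumeModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta_json"]).decode())
            model = cls(ModelConfig.from_dict(meta["model_config"]),
                        seed=meta.get("seed", 0))
            model.preprocess_hash = meta.get("preprocess_hash")
            if (expected_preprocess_hash is not None
                    and model.preprocess_hash is not None
                    and model.preprocess_hash != expected_preprocess_hash):
                raise ValueError(
                    "checkpoint was trained with a different preprocessing "
                    "configuration"
                )
            for li, layer in enumerate(model._layers()):
                for name, p in layer.params().items():
                    p[...] = data[f"p_{li}_{name}"]
                if isinstance(layer, _nn.BatchNorm2d):
                    layer.running_mean[...] = data[f"p_{li}_running_mean"]
                    layer.running_var[...] = data[f"p_{li}_running_var"]
        return model


@dataclass
class ReconstructionResults:
    """Fit results: the trained model plus its per-epoch loss history."""

    model: LocalizerToVolumeModel
    loss_history: List[float]
    train_config: TrainConfig

    @property
    def final_loss(self) -> Optional[float]:
        return self.loss_history[-1] if self.loss_history else None

    def predict_volume(self, localizer_in: np.ndarray,
                       crop_record: CropRecord) -> Volume3D:
        return self.model.predict_volume(localizer_in, crop_record)

    def summary(self) -> str:
        c = self.model.config
        lines = [
            "Localizer-to-volume reconstruction",
            "=" * 44,
            f"depth:            {c.depth}",
            f"base channels:    {c.base_channels}",
            f"input (lat, Z):   {c.input_shape}",
            f"output AP bins:   {c.output_ap_bins}",
            f"parameters:       {self.model.parameter_count()}",
            f"epochs trained:   {len(self.loss_history)}",
            f"loss ({self.train_config.loss}):       "
            f"{self.final_loss if self.final_loss is not None else 'n/a'}",
        ]
        return "\n".join(lines)


def preprocess_config_hash(config) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]


# Functional aliases mirroring the operation-level API.

def build_model(config: ModelConfig, seed: int = 0) -> LocalizerToVolumeModel:
    return LocalizerToVolumeModel(config, seed=seed)


def train(model: LocalizerToVolumeModel, pairs: Sequence[TrainingPair],
          train_config: TrainConfig = TrainConfig()) -> ReconstructionResults:
    return model.fit(pairs, train_config)


def predict_volume(model: LocalizerToVolumeModel, localizer_in: np.ndarray,
                   crop_record: CropRecord) -> Volume3D:
    return model.predict_volume(localizer_in, crop_record)
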