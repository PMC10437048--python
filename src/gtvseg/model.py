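"""SE-Norm residual 3D U-Net with deep-supervised auxiliary heads.

A single-path encoder-decoder for dual-modality input: PET and planning-CT
patches are concatenated channel-wise. Each convolutional block is
conv3x3x3 -> ReLU -> SE Norm. Encoder stages are residual blocks (two conv
blocks plus an identity shortcut, or a 1x1x1 projection when channel
counts change), separated by 2x2x2 max pooling; feature width starts at 24
and doubles per level. Decoder stages up-sample with a 3x3x3 stride-2
transposed convolution (halving channels), concatenate the encoder skip,
and apply two conv blocks. A 1x1x1 convolution + softmax gives the
voxel-wise class probabilities; the three coarsest decoder stages carry
auxiliary heads (1x1x1 conv to class channels, trilinear up-sampling to
full patch size) used for deep supervision.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .image import Mask, Volume
from .nn.functional import DTYPE, softmax_channels
from .nn.layers import Conv3d, ConvTranspose3d, MaxPool2, Param, ReLU, SENorm, Upsample

__all__ = ["SegModelConfig", "ModelOutput", "SENormUNet3D", "build_model", "predict",
           "save_checkpoint", "load_checkpoint"]


@dataclass(frozen=True)
class SegModelConfig:
    """Architecture hyperparameters (defaults are the full-scale architecture)."""

    in_channels: int = 2
    n_classes: int = 2
    base_width: int = 24
    n_levels: int = 4
    se_reduction: int = 2
    patch_size: int | None = None  # validated against 2**n_levels when given

    def __post_init__(self) -> None:
        if self.base_width < 1 or self.n_levels < 1 or self.in_channels < 1 or self.n_classes < 2:
            raise ValueError(f"invalid model config: {self}")
        if self.patch_size is not None and self.patch_size % (2**self.n_levels) != 0:
            raise ValueError(
                f"patch side {self.patch_size} is not divisible by 2^{self.n_levels}"
            )

    @property
    def n_heads(self) -> int:
        """Auxiliary deep-supervision heads: the coarsest non-top decoder stages."""
        return min(3, self.n_levels - 1) if self.n_levels > 1 else 0

    @property
    def encoder_widths(self) -> list[int]:
        return [self.base_width * 2**i for i in range(self.n_levels + 1)]


@dataclass
class ModelOutput:
    """Full-resolution logits from the main head and every auxiliary head."""

    main_logits: np.ndarray
    aux_logits: list  # ordered fine-to-coarse, each at full patch resolution

    @property
    def probabilities(self) -> np.ndarray:
        return softmax_channels(self.main_logits)


class _ConvBlock:
    """conv3x3x3 -> ReLU -> SE Norm."""

    def __init__(self, cin, cout, rng, reduction, name):
        self.conv = Conv3d(cin, cout, 3, rng, name=f"{name}.conv")
        self.relu = ReLU()
        self.norm = SENorm(cout, rng, reduction=reduction, name=f"{name}.norm")

    def params(self):
        return self.conv.params() + self.norm.params()

    def forward(self, x, train=False):
        return self.norm.forward(self.relu.forward(self.conv.forward(x, train), train), train)

    def backward(self, gy):
        return self.conv.backward(self.relu.backward(self.norm.backward(gy)))


class _ResidualBlock:
    """Two conv blocks with identity or 1x1x1 projection shortcut."""

    def __init__(self, cin, cout, rng, reduction, name):
        self.block1 = _ConvBlock(cin, cout, rng, reduction, f"{name}.block1")
        self.block2 = _ConvBlock(cout, cout, rng, reduction, f"{name}.block2")
        self.shortcut = None if cin == cout else Conv3d(cin, cout, 1, rng, name=f"{name}.proj")

    def params(self):
        p = self.block1.params() + self.block2.params()
        if self.shortcut is not None:
            p += self.shortcut.params()
        return p

    def forward(self, x, train=False):
        y = self.block2.forward(self.block1.forward(x, train), train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return y + s

    def backward(self, gy):
        gx = self.block1.backward(self.block2.backward(gy))
        gx = gx + (gy if self.shortcut is None else self.shortcut.backward(gy))
        return gx


class _DecoderStage:
    """Transposed-conv up-sample, skip concatenation, two conv blocks."""

    def __init__(self, cin, cout, rng, reduction, name):
        self.up = ConvTranspose3d(cin, cout, rng, name=f"{name}.up")
        self.block1 = _ConvBlock(2 * cout, cout, rng, reduction, f"{name}.block1")
        self.block2 = _ConvBlock(cout, cout, rng, reduction, f"{name}.block2")
        self.cout = cout

    def params(self):
        return self.up.params() + self.block1.params() + self.block2.params()

    def forward(self, x, skip, train=False):
        u = self.up.forward(x, train)
        cat = np.concatenate([u, skip], axis=0)
        return self.block2.forward(self.block1.forward(cat, train), train)

    def backward(self, gy):
        gcat = self.block1.backward(self.block2.backward(gy))
        gu, gskip = gcat[: self.cout], gcat[self.cout:]
        gx = self.up.backward(np.ascontiguousarray(gu))
        return gx, np.ascontiguousarray(gskip)


class SENormUNet3D:
    def __init__(self, cfg: SegModelConfig, rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        w = cfg.encoder_widths
        red = cfg.se_reduction
        self.encoder = [
            _ResidualBlock(cfg.in_channels if i == 0 else w[i - 1], w[i], rng, red, f"enc{i}")
            for i in range(cfg.n_levels + 1)
        ]
        self.pools = [MaxPool2() for _ in range(cfg.n_levels)]
        # decoder stage j (j=1 coarsest) maps width w[n-j+1] -> w[n-j]
        self.decoder = [
            _DecoderStage(w[cfg.n_levels - j + 1], w[cfg.n_levels - j], rng, red, f"dec{j}")
            for j in range(1, cfg.n_levels + 1)
        ]
        self.final = Conv3d(w[0], cfg.n_classes, 1, rng, name="final")
        # aux heads on decoder stages 1..n_heads (coarse to fine)
        self.aux_convs = [
            Conv3d(w[cfg.n_levels - j], cfg.n_classes, 1, rng, name=f"aux{j}")
            for j in range(1, cfg.n_heads + 1)
        ]
        self.aux_ups = [Upsample(cfg.n_levels - j) for j in range(1, cfg.n_heads + 1)]

    # -- parameters ---------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for blk in self.encoder:
            out += blk.params()
        for st in self.decoder:
            out += st.params()
        out += self.final.params()
        for c in self.aux_convs:
            out += c.params()
        return out

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0

    # -- forward / backward -------------------------------------------------
    def _check_input(self, x: np.ndarray) -> None:
        if x.ndim != 4 or x.shape[0] != self.cfg.in_channels:
            raise ValueError(
                f"expected input of shape ({self.cfg.in_channels}, D, H, W), got {x.shape}"
            )
        for side in x.shape[1:]:
            if side % (2**self.cfg.n_levels) != 0:
                raise ValueError(
                    f"patch side {side} is not divisible by 2^{self.cfg.n_levels}"
                )

    def forward(self, x: np.ndarray, train: bool = False) -> ModelOutput:
        self._check_input(x)
        x = np.ascontiguousarray(x, dtype=DTYPE)
        n = self.cfg.n_levels
        skips = []
        h = x
        for i in range(n):
            h = self.encoder[i].forward(h, train)
            skips.append(h)
            h = self.pools[i].forward(h, train)
        h = self.encoder[n].forward(h, train)

        aux = []
        for j, stage in enumerate(self.decoder, start=1):
            h = stage.forward(h, skips[n - j], train)
            if j <= len(self.aux_convs):
                a = self.aux_convs[j - 1].forward(h, train)
                aux.append(self.aux_ups[j - 1].forward(a, train))
        main = self.final.forward(h, train)
        # aux ordered fine-to-coarse to match head-weight convention
        return ModelOutput(main_logits=main, aux_logits=aux[::-1])

    def backward(self, d_main: np.ndarray, d_aux: list | None = None) -> None:
        """Accumulate parameter gradients; call after ``forward(train=True)``.

        ``d_aux`` is ordered fine-to-coarse like ``ModelOutput.aux_logits``.
        """
        n = self.cfg.n_levels
        d_aux = list(d_aux or [])
        if len(d_aux) != len(self.aux_convs):
            raise ValueError(f"expected {len(self.aux_convs)} aux gradients, got {len(d_aux)}")
        d_aux_coarse_first = d_aux[::-1]

        gh = self.final.backward(np.ascontiguousarray(d_main, dtype=DTYPE))
        gskips = [None] * n
        for j in range(n, 0, -1):
            stage = self.decoder[j - 1]
            if j <= len(self.aux_convs):
                ga = self.aux_ups[j - 1].backward(
                    np.ascontiguousarray(d_aux_coarse_first[j - 1], dtype=DTYPE))
                gh = gh + self.aux_convs[j - 1].backward(ga)
            gh, gskip = stage.backward(gh)
            gskips[n - j] = gskip
        gh = self.encoder[n].backward(gh)
        for i in range(n - 1, -1, -1):
            gh = self.pools[i].backward(gh)
            gh = gh + gskips[i]
            gh = self.encoder[i].backward(gh)

    # -- checkpointing ------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.data.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = {p.name: p for p in self.params()}
        if set(own) != set(state):
            raise ValueError("checkpoint parameter names do not match this architecture")
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.ascontiguousarray(state[name], dtype=DTYPE)


def build_model(cfg: SegModelConfig, seed: int = 0) -> SENormUNet3D:
    return SENormUNet3D(cfg, np.random.default_rng(seed))


def _stack_modalities(cfg: SegModelConfig, ct_patch: Volume | None, pet_patch: Volume | None) -> np.ndarray:
    given = [v for v in (ct_patch, pet_patch) if v is not None]
    if len(given) != cfg.in_channels:
        raise ValueError(
            f"model expects {cfg.in_channels} input modality(ies), got {len(given)}"
        )
    if len(given) == 2 and not given[0].same_grid(given[1]):
        raise ValueError("CT and PET patches are not on the same grid")
    return np.stack([np.asarray(v.data, dtype=DTYPE) for v in given], axis=0)


def predict(model: SENormUNet3D, ct_patch: Volume | None = None,
            pet_patch: Volume | None = None) -> Mask:
    """Run the network on preprocessed patch(es) and arg-max to a binary mask."""
    x = _stack_modalities(model.cfg, ct_patch, pet_patch)
    out = model.forward(x, train=False)
    labels = (out.probabilities.argmax(axis=0) > 0).astype(np.uint8)
    ref = ct_patch if ct_patch is not None else pet_patch
    return Mask(data=labels, spacing=ref.spacing, origin=ref.origin)


def save_checkpoint(model: SENormUNet3D, path) -> Path:
    """Weights as .npz next to a JSON sidecar of the architecture config."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    cfg_path = path.with_suffix(".json")
    cfg_path.write_text(json.dumps(asdict(model.cfg), indent=2) + "\n")
    return path


def load_checkpoint(path) -> SENormUNet3D:
    path = Path(path)
    weights_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    cfg = SegModelConfig(**json.loads(weights_path.with_suffix(".json").read_text()))
    model = SENormUNet3D(cfg, np.random.default_rng(0))
    with np.load(weights_path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
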