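"""Multi-exit student architecture with global-context exit branches,
plus plain residual classifiers used as teachers and as the transfer
backbone.

The student is a staged residual backbone; after each of the last
``n_exits`` stages an exit branch applies a global-context (GC) block,
a strided bottleneck that unifies the feature map to the deepest stage's
scale, and a pooled fully connected head.  The deepest exit is the
backbone's own head path (its bottleneck is the identity).  A forward
pass returns an :class:`ExitBundle` carrying every exit's logits and
scale-unified features, which is what the distillation losses consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .losses import soften

__all__ = [
    "ExitBundle", "StudentConfig", "BACKBONE_PRESETS",
    "GCBlock", "Bottleneck", "ResNetClassifier", "MultiExitStudent",
    "build_student", "build_teacher", "save_checkpoint", "load_checkpoint",
]


class ConfigurationError(ValueError):
    """Raised for invalid architecture configuration."""


#: backbone presets: stage channels, blocks per stage, stem stride.
#: resnet18/resnet34 are the full-scale basic-block networks (3x3 stem);
#: resnet8 / resnet8w are reduced-depth variants for desk-scale CPU runs
#: (one block per stage, narrow channels, stride-2 stem).
BACKBONE_PRESETS = {
    "resnet18": {"channels": (64, 128, 256, 512), "blocks": (2, 2, 2, 2), "stem_stride": 1},
    "resnet34": {"channels": (64, 128, 256, 512), "blocks": (3, 4, 6, 3), "stem_stride": 1},
    "resnet8": {"channels": (8, 16, 32, 64), "blocks": (1, 1, 1, 1), "stem_stride": 2},
    "resnet8w": {"channels": (16, 32, 64, 128), "blocks": (1, 1, 1, 1), "stem_stride": 2},
}


@dataclass
class ExitBundle:
    """Per-forward-pass outputs of a multi-exit network: logits S_1..S_n
    and scale-unified features mu_m(F_m) for every exit (the last entry
    is the deepest exit: S_n and F_n)."""

    logits_per_exit: list
    features_per_exit: list

    def __post_init__(self):
        if len(self.logits_per_exit) != len(self.features_per_exit):
            raise ValueError("logits/features lists must have equal length")
        if self.n < 2:
            raise ValueError("a multi-exit bundle needs at least 2 exits")
        shapes = {tuple(z.shape) for z in self.logits_per_exit}
        if len(shapes) != 1:
            raise ValueError(f"exit logit shapes differ: {shapes}")
        fshapes = {tuple(f.shape) for f in self.features_per_exit}
        if len(fshapes) != 1:
            raise ValueError(f"unified feature shapes differ: {fshapes}")

    @property
    def n(self) -> int:
        return len(self.logits_per_exit)

    @property
    def num_classes(self) -> int:
        return self.logits_per_exit[0].shape[-1]

    @property
    def deepest_logits(self):
        return self.logits_per_exit[-1]

    @property
    def deepest_features(self):
        return self.features_per_exit[-1]


@dataclass
class StudentConfig:
    backbone_id: str = "resnet18"
    n_exits: int = 4
    gc_on_exits: tuple | None = None  # None -> GC block on every exit
    gc_reduction_ratio: int = 16
    fusion_mode: str = "add"
    num_classes: int = 5

    def __post_init__(self):
        if self.backbone_id not in BACKBONE_PRESETS:
            raise ConfigurationError(
                f"unknown backbone {self.backbone_id!r}; "
                f"available: {sorted(BACKBONE_PRESETS)}")
        n_stages = len(BACKBONE_PRESETS[self.backbone_id]["channels"])
        if not 2 <= self.n_exits <= n_stages:
            raise ConfigurationError(
                f"n_exits must be in [2, {n_stages}] for {self.backbone_id}, "
                f"got {self.n_exits}")
        if self.gc_reduction_ratio < 1:
            raise ConfigurationError("gc_reduction_ratio must be >= 1")
        if self.fusion_mode not in ("add", "multiply"):
            raise ConfigurationError(f"fusion_mode must be add|multiply, "
                                     f"got {self.fusion_mode!r}")
        if self.gc_on_exits is not None:
            self.gc_on_exits = tuple(self.gc_on_exits)

    def uses_gc(self, exit_index: int) -> bool:
        """1-based exit index."""
        return self.gc_on_exits is None or exit_index in self.gc_on_exits

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["gc_on_exits"] is not None:
            d["gc_on_exits"] = list(d["gc_on_exits"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudentConfig":
        return cls(**d)


class GCBlock(nn.Module):
    """Global context block: (i) context modeling — a 1-channel spatial
    attention map, softmax-normalized over all H*W positions, pools the
    input into one C-vector per image; (ii) transform — a two-layer
    channel bottleneck (reduce by ``reduction``, layer norm + ReLU,
    expand back); (iii) fusion — the transformed vector is combined with
    the input at every spatial position.

    The final transform layer is zero-initialized (and for multiplicative
    fusion — the literal dot-product reading — its bias starts at one),
    so the block is exactly the identity at initialization under both
    fusion modes.
    """

    def __init__(self, channels: int, reduction: int = 16, fusion_mode: str = "add"):
        super().__init__()
        if channels % reduction != 0:
            raise ConfigurationError(
                f"gc_reduction_ratio={reduction} must divide channels={channels}")
        if fusion_mode not in ("add", "multiply"):
            raise ConfigurationError(f"unknown fusion_mode {fusion_mode!r}")
        self.fusion_mode = fusion_mode
        hidden = channels // reduction
        self.attn = nn.Conv2d(channels, 1, 1)
        self.reduce = nn.Conv2d(channels, hidden, 1)
        self.norm = nn.ChannelLayerNorm(hidden)
        self.expand = nn.Conv2d(hidden, channels, 1, zero_init=True)
        if fusion_mode == "multiply":
            self.expand.bias.data[...] = 1.0

    def attention_weights(self, x) -> np.ndarray:
        """Normalized spatial attention (N, H*W); rows sum to 1."""
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, _, h, w = x.shape
        logits = self.attn(x).reshape(n, h * w)
        return soften(logits, 1.0).data

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        n, c, h, w = x.shape
        attn = soften(self.attn(x).reshape(n, h * w), 1.0).reshape(n, h * w, 1)
        ctx = (x.reshape(n, c, h * w) @ attn).reshape(n, c, 1, 1)
        t = self.expand(self.norm(self.reduce(ctx)).relu())
        if self.fusion_mode == "add":
            return x + t
        return x * t


class BasicBlock(nn.Module):
    def __init__(self, in_ch: int, out_ch: int, stride: int = 1):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, stride=stride, padding=1, bias=False)
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, bias=False)
        self.bn2 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.shortcut = nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, stride=stride, bias=False),
                nn.BatchNorm2d(out_ch))
        else:
            self.shortcut = nn.Identity()

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + self.shortcut(x)).relu()


def _make_stage(in_ch, out_ch, n_blocks, stride):
    blocks = [BasicBlock(in_ch, out_ch, stride)]
    blocks += [BasicBlock(out_ch, out_ch) for _ in range(n_blocks - 1)]
    return nn.Sequential(*blocks)


def _build_trunk(backbone_id: str):
    preset = BACKBONE_PRESETS[backbone_id]
    ch = preset["channels"]
    stem = nn.Sequential(
        nn.Conv2d(3, ch[0], 3, stride=preset["stem_stride"], padding=1, bias=False),
        nn.BatchNorm2d(ch[0]),
        nn.ReLU())
    stages = []
    prev = ch[0]
    for i, (c, b) in enumerate(zip(ch, preset["blocks"])):
        stages.append(_make_stage(prev, c, b, stride=1 if i == 0 else 2))
        prev = c
    return stem, stages, ch


class ResNetClassifier(nn.Module):
    """Plain staged residual classifier: stem -> stages -> pool -> fc.
    Used as the teacher and as the stage-1 pretraining network."""

    def __init__(self, backbone_id: str = "resnet18", num_classes: int = 5):
        super().__init__()
        self.backbone_id = backbone_id
        self.num_classes = num_classes
        self.stem, self.stages, self._channels = _build_trunk(backbone_id)
        self.fc = nn.Linear(self._channels[-1], num_classes)

    def forward(self, x):
        x = x if isinstance(x, Tensor) else Tensor(x)
        x = self.stem(x)
        for stage in self.stages:
            x = stage(x)
        return self.fc(nn.global_avg_pool(x))


class Bottleneck(nn.Module):
    """Scale-unifying exit transform mu_m: a stack of stride-2 conv units
    (3x3 conv + BN + ReLU) whose depth is log2 of the spatial-size ratio
    between exit m's feature map and the deepest exit's, with channels
    projected to the deepest stage's width.  The deepest exit uses the
    identity."""

    def __init__(self, in_ch: int, out_ch: int, spatial_ratio: int):
        super().__init__()
        if spatial_ratio < 1 or (spatial_ratio & (spatial_ratio - 1)):
            raise ConfigurationError(
                f"spatial ratio between exit and deepest feature maps must be "
                f"a power of two, got {spatial_ratio}")
        self.spatial_steps = int(np.log2(spatial_ratio))
        chs = [in_ch]
        for _ in range(self.spatial_steps):
            chs.append(min(chs[-1] * 2, out_ch))
        if self.spatial_steps:
            chs[-1] = out_ch
        units = []
        for cin, cout in zip(chs[:-1], chs[1:]):
            units.append(nn.Sequential(
                nn.Conv2d(cin, cout, 3, stride=2, padding=1, bias=False),
                nn.BatchNorm2d(cout), nn.ReLU()))
        if self.spatial_steps == 0 and in_ch != out_ch:
            units.append(nn.Sequential(
                nn.Conv2d(in_ch, out_ch, 1, bias=False),
                nn.BatchNorm2d(out_ch), nn.ReLU()))
        self.units = units

    def forward(self, x):
        for unit in self.units:
            x = unit(x)
        return x


class ExitBranch(nn.Module):
    """GC block -> bottleneck -> global pool -> fully connected head."""

    def __init__(self, in_ch: int, deep_ch: int, spatial_ratio: int,
                 num_classes: int, use_gc: bool, gc_reduction: int,
                 fusion_mode: str):
        super().__init__()
        self.gc = (GCBlock(in_ch, gc_reduction, fusion_mode)
                   if use_gc else nn.Identity())
        self.bottleneck = (Bottleneck(in_ch, deep_ch, spatial_ratio)
                           if (spatial_ratio > 1 or in_ch != deep_ch)
                           else nn.Identity())
        self.fc = nn.Linear(deep_ch, num_classes)

    def forward(self, x):
        x = self.gc(x)
        feat = self.bottleneck(x)
        logits = self.fc(nn.global_avg_pool(feat))
        return logits, feat


class MultiExitStudent(nn.Module):
    """Staged residual backbone with an exit branch after each of the
    last ``n_exits`` stages.  The deepest exit is the backbone's own
    head path (identity bottleneck); its post-GC feature map F_n is the
    target of the feature-matching self-distillation loss."""

    def __init__(self, config: StudentConfig):
        super().__init__()
        self.config = config
        self.stem, self.stages, ch = _build_trunk(config.backbone_id)
        n_stages = len(ch)
        self._exit_stages = list(range(n_stages - config.n_exits, n_stages))
        deep_ch = ch[-1]
        self.exits = []
        for k, si in enumerate(self._exit_stages):
            ratio = 2 ** (n_stages - 1 - si)
            self.exits.append(ExitBranch(
                ch[si], deep_ch, ratio, config.num_classes,
                use_gc=config.uses_gc(k + 1),
                gc_reduction=config.gc_reduction_ratio,
                fusion_mode=config.fusion_mode))

    @property
    def n_exits(self) -> int:
        return self.config.n_exits

    def forward(self, x) -> ExitBundle:
        x = x if isinstance(x, Tensor) else Tensor(x)
        x = self.stem(x)
        logits, feats = [], []
        for si, stage in enumerate(self.stages):
            x = stage(x)
            if si in self._exit_stages:
                z, f = self.exits[self._exit_stages.index(si)](x)
                logits.append(z)
                feats.append(f)
        return ExitBundle(logits_per_exit=logits, features_per_exit=feats)


def build_student(config: StudentConfig | None = None,
                  init_seed: int | None = None) -> MultiExitStudent:
    """Construct a multi-exit student; ``init_seed`` makes the initial
    weights reproducible."""
    if init_seed is not None:
        nn.seed_init(init_seed)
    return MultiExitStudent(config or StudentConfig())


def build_teacher(source="resnet34", num_classes: int = 5,
                  init_seed: int | None = None) -> ResNetClassifier:
    """Build (or load) a teacher and freeze it.

    ``source`` is a backbone preset id or a checkpoint path produced by
    :func:`save_checkpoint`.  The returned model's parameters are marked
    non-trainable; its forward yields (batch, C) logits.
    """
    if init_seed is not None:
        nn.seed_init(init_seed)
    if isinstance(source, (str, Path)) and str(source) in BACKBONE_PRESETS:
        model = ResNetClassifier(str(source), num_classes)
    else:
        state, meta = load_checkpoint(source)
        backbone_id = meta.get("backbone_id", "resnet18")
        model = ResNetClassifier(backbone_id, meta.get("num_classes", num_classes))
        try:
            model.load_state_dict(state, strict=True)
        except ValueError as e:
            raise ValueError(f"teacher checkpoint {source} does not match "
                             f"architecture: {e}") from e
    return model.freeze()


def save_checkpoint(path, model: nn.Module, meta: dict | None = None) -> Path:
    """Serialize weights (+ JSON metadata) to an .npz file."""
    path = Path(path)
    meta = dict(meta or {})
    if isinstance(model, ResNetClassifier):
        meta.setdefault("backbone_id", model.backbone_id)
        meta.setdefault("num_classes", model.num_classes)
    elif isinstance(model, MultiExitStudent):
        meta.setdefault("student_config", model.config.to_dict())
    arrays = {f"param::{k}": v for k, v in model.state_dict().items()}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)
    return path


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint` -> (state_dict, meta)."""
    with np.load(Path(path), allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode()) if "__meta__" in z else {}
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    return state, meta
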