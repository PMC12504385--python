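"""The MBC-ATT network and its ablation variants.

Two convolutional branches extract modality-specific features: the EEG
branch stacks three temporal convolutions with (7, 1) kernels (sliding
along time, channels independent) followed by three (4, 4) convolutions
spanning channel groups; the fNIRS branch uses two (4, 1) and two (2, 2)
convolutions.  Each conv is followed by ReLU, max pooling and batch
normalization, and each branch ends in two fully connected layers.  Branch
features are projected into a shared hidden space as L tokens per modality
and fused by bidirectional 4-head scaled dot-product cross-attention (EEG
queries attend to fNIRS keys/values and vice versa); attended tokens are
mean-pooled, concatenated, and classified with softmax.

Inputs are laid out as one-channel 2-D planes [time x channels], so a
(k, 1) kernel spans k time steps on every channel row independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn

VARIANTS = ("full", "concat_ablation", "eeg_only", "fnirs_only")

#: architectural facts fixed by the method definition; changing any of them
#: requires an explicit allow_nonfixed=True
METHOD_FIXED = {
    "eeg_temporal_layers": 3,
    "eeg_temporal_kernel": (7, 1),
    "eeg_spatial_layers": 3,
    "eeg_spatial_kernel": (4, 4),
    "fnirs_temporal_layers": 2,
    "fnirs_temporal_kernel": (4, 1),
    "fnirs_spatial_layers": 2,
    "fnirs_spatial_kernel": (2, 2),
    "n_heads": 4,
    "eeg_fc_layers": 2,
}


@dataclass(frozen=True)
class ModelConfig:
    """Every architectural hyperparameter.

    The first block is fixed by the method (kernel counts/sizes, 4 heads,
    two FC layers); the second block is implementation-chosen and sized for
    CPU training: filter counts, pooling, hidden width d_model, token count
    L, FC widths, dropout.
    """

    n_classes: int
    # -- fixed by the method --
    eeg_temporal_layers: int = 3
    eeg_temporal_kernel: tuple[int, int] = (7, 1)
    eeg_spatial_layers: int = 3
    eeg_spatial_kernel: tuple[int, int] = (4, 4)
    fnirs_temporal_layers: int = 2
    fnirs_temporal_kernel: tuple[int, int] = (4, 1)
    fnirs_spatial_layers: int = 2
    fnirs_spatial_kernel: tuple[int, int] = (2, 2)
    n_heads: int = 4
    eeg_fc_layers: int = 2
    # -- implementation-chosen --
    eeg_filters: tuple[int, ...] = (4, 4, 8, 8, 16, 16)
    fnirs_filters: tuple[int, ...] = (8, 8, 16, 16)
    # one max-pool size per conv layer; (1, 1) = no pooling at that depth.
    # Temporal pooling is front-loaded so the 1000-sample EEG time axis
    # shrinks before the (4, 4) stack.
    eeg_pools: tuple[tuple[int, int], ...] = (
        (4, 1), (4, 1), (2, 1), (2, 2), (2, 2), (1, 1))
    fnirs_pools: tuple[tuple[int, int], ...] = (
        (2, 1), (2, 1), (2, 2), (2, 2))
    fc_widths: tuple[int, ...] = (128, 64)
    d_model: int = 64
    tokens: int = 4
    dropout: float = 0.25
    bn_before_pool: bool = False
    # -- input geometry --
    n_eeg_ch: int = 30
    eeg_samples: int = 1000
    n_fnirs_ch: int = 72          # 36 HbO + 36 HbR stacked
    fnirs_samples: int = 50

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.tokens < 1:
            raise ValueError("tokens must be >= 1")
        if len(self.eeg_filters) != self.eeg_temporal_layers + self.eeg_spatial_layers:
            raise ValueError("eeg_filters length must cover all EEG conv layers")
        if len(self.fnirs_filters) != self.fnirs_temporal_layers + self.fnirs_spatial_layers:
            raise ValueError("fnirs_filters length must cover all fNIRS conv layers")
        if len(self.eeg_pools) != len(self.eeg_filters):
            raise ValueError("eeg_pools must give one pool size per conv layer")
        if len(self.fnirs_pools) != len(self.fnirs_filters):
            raise ValueError("fnirs_pools must give one pool size per conv layer")
        if len(self.fc_widths) != self.eeg_fc_layers:
            raise ValueError("fc_widths length must equal the FC layer count")

    def validate_fixed(self, allow_nonfixed: bool = False) -> None:
        """Reject configurations that alter method-fixed architecture."""
        if allow_nonfixed:
            return
        for key, want in METHOD_FIXED.items():
            have = getattr(self, key)
            if tuple(np.atleast_1d(have)) != tuple(np.atleast_1d(want)):
                raise ValueError(
                    f"{key}={have!r} deviates from the fixed architecture "
                    f"({want!r}); pass allow_nonfixed=True to override")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        def _tuplify(v):
            return tuple(_tuplify(e) for e in v) if isinstance(v, (list, tuple)) else v

        return cls(**{k: _tuplify(v) for k, v in d.items()})


def _conv_shape(h, w, kernel, padding):
    if padding == "same":
        return h, w
    kh, kw = kernel
    ho, wo = h - kh + 1, w - kw + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"kernel {kernel} does not fit input extent {(h, w)}")
    return ho, wo


class _Branch(nn.Layer):
    """One modality's conv stack + FC head.  Built from shape propagation so
    the flatten width is exact; a pool stage is skipped when it would empty
    the map."""

    def __init__(self, cfg: ModelConfig, modality: str, rng, dtype=np.float32):
        if modality == "eeg":
            h, w = cfg.eeg_samples, cfg.n_eeg_ch
            t_layers, t_kernel = cfg.eeg_temporal_layers, cfg.eeg_temporal_kernel
            s_layers, s_kernel = cfg.eeg_spatial_layers, cfg.eeg_spatial_kernel
            filters, pools = cfg.eeg_filters, cfg.eeg_pools
        else:
            h, w = cfg.fnirs_samples, cfg.n_fnirs_ch
            t_layers, t_kernel = cfg.fnirs_temporal_layers, cfg.fnirs_temporal_kernel
            s_layers, s_kernel = cfg.fnirs_spatial_layers, cfg.fnirs_spatial_kernel
            filters, pools = cfg.fnirs_filters, cfg.fnirs_pools
        layers, c_in = [], 1
        specs = ([(t_kernel, "same")] * t_layers + [(s_kernel, "valid")] * s_layers)
        for li, ((kernel, padding), pool, c_out) in enumerate(zip(specs, pools, filters)):
            h, w = _conv_shape(h, w, kernel, padding)
            layers.append(nn.Conv2d(c_in, c_out, kernel, padding, rng, dtype,
                                    name=f"{modality}.conv{li}"))
            layers.append(nn.ReLU())
            stage = []
            ph, pw = pool
            if (ph, pw) != (1, 1) and h // ph >= 1 and w // pw >= 1:
                stage.append(nn.MaxPool2d(pool))
                h, w = h // ph, w // pw
            stage.append(nn.BatchNorm2d(c_out, dtype=dtype, name=f"{modality}.bn{li}"))
            if cfg.bn_before_pool:
                stage.reverse()
            layers.extend(stage)
            c_in = c_out
        layers.append(nn.Flatten())
        n_in = c_in * h * w
        for fi, width in enumerate(cfg.fc_widths):
            layers.append(nn.Linear(n_in, width, rng, dtype, name=f"{modality}.fc{fi}"))
            layers.append(nn.ReLU())
            if fi == 0 and cfg.dropout > 0:
                layers.append(nn.Dropout(cfg.dropout, rng))
            n_in = width
        self.net = nn.Sequential(*layers)
        self.out_dim = n_in

    def parameters(self):
        return self.net.parameters()

    def forward(self, x, training=False):
        return self.net.forward(x, training=training)

    def backward(self, grad):
        return self.net.backward(grad)


class _Tokenizer(nn.Layer):
    """Project a branch feature vector to L tokens of width d_model via a
    single linear map, then reshape.  L = 1 degenerates to single-token
    attention (allowed; logged by callers)."""

    def __init__(self, n_in, tokens, d_model, rng, dtype, name):
        self.tokens, self.d_model = tokens, d_model
        self.lin = nn.Linear(n_in, tokens * d_model, rng, dtype, name=name)

    def parameters(self):
        return self.lin.parameters()

    def forward(self, x, training=False):
        flat = self.lin.forward(x, training=training)
        return flat.reshape(x.shape[0], self.tokens, self.d_model)

    def backward(self, grad):
        return self.lin.backward(grad.reshape(grad.shape[0], -1))


class MBCATT:
    """The full network or one of its ablation variants.

    kind: 'full' (cross-attention fusion), 'concat_ablation' (branch features
    concatenated, no attention), 'eeg_only', 'fnirs_only'.  Unimodal variants
    never touch the other modality's input.
    """

    def __init__(self, config: ModelConfig, kind: str = "full", seed: int = 0,
                 dtype=np.float32, allow_nonfixed: bool = False):
        if kind not in VARIANTS:
            raise ValueError(f"unknown variant {kind!r}; expected one of {VARIANTS}")
        config.validate_fixed(allow_nonfixed)
        self.config, self.kind, self.seed = config, kind, seed
        rng = np.random.default_rng(seed)
        self.eeg_branch = self.fnirs_branch = None
        self.tok_e = self.tok_f = self.attention = None
        if kind in ("full", "concat_ablation", "eeg_only"):
            self.eeg_branch = _Branch(config, "eeg", rng, dtype)
        if kind in ("full", "concat_ablation", "fnirs_only"):
            self.fnirs_branch = _Branch(config, "fnirs", rng, dtype)
        if kind == "full":
            self.tok_e = _Tokenizer(self.eeg_branch.out_dim, config.tokens,
                                    config.d_model, rng, dtype, "tok.eeg")
            self.tok_f = _Tokenizer(self.fnirs_branch.out_dim, config.tokens,
                                    config.d_model, rng, dtype, "tok.fnirs")
            self.attention = nn.CrossModalAttention(config.d_model, config.n_heads,
                                                    rng, dtype)
            head_in = 2 * config.d_model
        elif kind == "concat_ablation":
            head_in = self.eeg_branch.out_dim + self.fnirs_branch.out_dim
        elif kind == "eeg_only":
            head_in = self.eeg_branch.out_dim
        else:
            head_in = self.fnirs_branch.out_dim
        self.classifier = nn.Linear(head_in, config.n_classes, rng, dtype,
                                    name="classifier")
        self._cache = None
        self.training_history: list[dict] = []

    # ------------------------------------------------------------------ core
    def parameters(self) -> list[nn.Parameter]:
        groups = self.parameter_groups()
        return [p for ps in groups.values() for p in ps]

    def parameter_groups(self) -> dict[str, list[nn.Parameter]]:
        groups = {}
        if self.eeg_branch is not None:
            groups["eeg_branch"] = self.eeg_branch.parameters()
        if self.fnirs_branch is not None:
            groups["fnirs_branch"] = self.fnirs_branch.parameters()
        if self.tok_e is not None:
            groups["tokenizers"] = self.tok_e.parameters() + self.tok_f.parameters()
            groups["attention"] = self.attention.parameters()
        groups["classifier"] = self.classifier.parameters()
        return groups

    def parameter_count(self) -> dict[str, int]:
        counts = {name: int(sum(p.data.size for p in ps))
                  for name, ps in self.parameter_groups().items()}
        counts["total"] = sum(counts.values())
        return counts

    @staticmethod
    def _plane(patch: np.ndarray) -> np.ndarray:
        # [B, channels, samples] -> CBHW [1, B, time, channels]; contiguity
        # matters: every conv pads/copies this array
        return np.ascontiguousarray(patch.transpose(0, 2, 1))[None, :, :, :]

    def forward(self, eeg: np.ndarray | None, fnirs: np.ndarray | None,
                training: bool = False) -> np.ndarray:
        """Logits [B x n_classes] from window patch batches [B x ch x samples]."""
        if self.kind == "eeg_only":
            feats = self.eeg_branch.forward(self._plane(eeg), training)
            self._cache = ("uni",)
            return self.classifier.forward(feats, training)
        if self.kind == "fnirs_only":
            feats = self.fnirs_branch.forward(self._plane(fnirs), training)
            self._cache = ("uni",)
            return self.classifier.forward(feats, training)
        fe = self.eeg_branch.forward(self._plane(eeg), training)
        ff = self.fnirs_branch.forward(self._plane(fnirs), training)
        if self.kind == "concat_ablation":
            self._cache = ("concat", fe.shape[1])
            return self.classifier.forward(np.concatenate([fe, ff], axis=1), training)
        te = self.tok_e.forward(fe, training)
        tf = self.tok_f.forward(ff, training)
        ea, fa = self.attention.forward_pair(te, tf)
        pooled = np.concatenate([ea.mean(axis=1), fa.mean(axis=1)], axis=1)
        self._cache = ("full", te.shape[1])
        return self.classifier.forward(pooled, training)

    def backward(self, grad_logits: np.ndarray) -> None:
        tag = self._cache[0]
        grad = self.classifier.backward(grad_logits)
        if tag == "uni":
            branch = self.eeg_branch if self.kind == "eeg_only" else self.fnirs_branch
            branch.backward(grad)
            return
        if tag == "concat":
            split = self._cache[1]
            self.eeg_branch.backward(grad[:, :split])
            self.fnirs_branch.backward(grad[:, split:])
            return
        n_tok = self._cache[1]
        d = self.config.d_model
        # mean over tokens: spread the pooled gradient uniformly
        dea = np.repeat(grad[:, None, :d], n_tok, axis=1) / n_tok
        dfa = np.repeat(grad[:, None, d:], n_tok, axis=1) / n_tok
        dte, dtf = self.attention.backward_pair(dea, dfa)
        self.eeg_branch.backward(self.tok_e.backward(dte))
        self.fnirs_branch.backward(self.tok_f.backward(dtf))

    def predict_proba(self, eeg, fnirs) -> np.ndarray:
        """Class probability rows (non-negative, each summing to 1)."""
        return nn.softmax(self.forward(eeg, fnirs, training=False), axis=1)

    def predict(self, eeg, fnirs) -> np.ndarray:
        """argmax class indices; ties break toward the lowest class index."""
        return np.argmax(self.predict_proba(eeg, fnirs), axis=1)

    @property
    def attention_maps(self) -> np.ndarray | None:
        """[2 x B x n_heads x L x L] weights from the last forward pass
        (direction 0: EEG queries -> fNIRS keys), or None for variants
        without attention."""
        return None if self.attention is None else self.attention.last_maps

    # --------------------------------------------------------------- storage
    def _stateful_layers(self):
        out = []
        for branch in (self.eeg_branch, self.fnirs_branch):
            if branch is not None:
                out.extend(l for l in branch.net.layers if isinstance(l, nn.BatchNorm2d))
        return out

    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for p in self.parameters()]
        for bn in self._stateful_layers():
            arrays.extend([bn.running_mean, bn.running_var])
        return arrays


def build_variant(kind: str, config: ModelConfig, seed: int = 0, **kw) -> MBCATT:
    """Construct the full model or an ablation variant."""
    return MBCATT(config, kind=kind, seed=seed, **kw)


def save_model(model: MBCATT, path) -> Path:
    """Checkpoint: arrays + config + variant + seed + training history."""
    path = Path(path)
    meta = {"config": model.config.to_dict(), "kind": model.kind,
            "seed": model.seed, "history": model.training_history}
    arrays = {f"a{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)
    return path


def load_model(path) -> MBCATT:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        model = MBCATT(ModelConfig.from_dict(meta["config"]), kind=meta["kind"],
                       seed=meta["seed"], allow_nonfixed=True)
        model.training_history = meta.get("history", [])
        for i, target in enumerate(model.state_arrays()):
            target[...] = z[f"a{i}"]
    return model
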