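"""Transformer network predicting 1D/2D RNA geometry distributions.

Each block updates an MSA representation (n, L, c) and a pair
representation (L, L, c') in four directions:

* **MSA -> MSA** — row-wise gated self-attention (with a bias derived from
  the pair representation added to the attention logits), column-wise gated
  self-attention, and a feed-forward transition;
* **MSA -> pair** — outer-product mean: the MSA representation is projected
  to a small dimension and, for each pair (i, j), the outer products of the
  i-th and j-th column vectors are averaged over the rows;
* **pair -> pair** — multiplicative triangle updates (outgoing and
  incoming) whose inputs pass through a multi-scale (4-scale, 3x3)
  residual convolution stack to sharpen local detail, followed by a
  feed-forward transition;
* **pair -> MSA** — the pair representation is linearly projected to
  per-head attention maps which are applied to the MSA representation,
  followed by a feed-forward transition.

A single pass stacks ``n_blocks`` blocks; the full inference recycles the
final pair representation and the first MSA row back into the input
embeddings for ``n_cycles`` passes.  Prediction heads produce categorical
distributions over binned distances and orientations plus a contact
probability map.

All computation runs on the package's reverse-mode autodiff engine; a
parameter set is a flat ``{name: Tensor}`` dict, serializable to an ``.npz``
checkpoint with a JSON config manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat, conv3x3, stack
from .features import FeatureBundle
from .geometry import BinSpec, ORI2D_KIND

__all__ = [
    "ModelConfig", "GeometryPrediction", "PredictionTensors",
    "init_parameters", "rnaformer_block", "single_pass", "forward",
    "outer_product_mean", "save_checkpoint", "load_checkpoint",
]


class CapacityError(ValueError):
    pass


class NumericError(FloatingPointError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    The production-scale setting is 48 blocks cycled 4 times; the defaults
    here are the desk-scale test configuration.
    """

    n_blocks: int = 2
    n_cycles: int = 1
    msa_channels: int = 32
    pair_channels: int = 32
    n_heads: int = 4
    opm_dim: int = 8
    tri_dim: int = 16
    ff_mult: int = 2
    conv_groups: int = 4
    head_hidden: int = 64
    max_rows: int = 256
    max_len: int = 512
    seed: int = 0

    def __post_init__(self):
        for f_ in ("n_blocks", "n_cycles", "msa_channels", "pair_channels",
                   "n_heads", "opm_dim", "tri_dim", "ff_mult",
                   "conv_groups", "max_rows", "max_len"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be positive")
        if self.msa_channels % self.n_heads:
            raise ValueError("msa_channels must be divisible by n_heads")
        if self.pair_channels % self.conv_groups:
            raise ValueError("pair_channels must divide into conv groups")


@dataclass
class GeometryPrediction:
    """Predicted probability distributions (numpy).

    ``dist``: (5, L, L, 39); ``ori2d``: list of 5 (L, L, 25|13) arrays;
    ``ori1d``: (4, L, 25); ``contact``: (L, L) in [0, 1], symmetric.
    """

    dist: np.ndarray
    ori2d: list
    ori1d: np.ndarray
    contact: np.ndarray

    @property
    def L(self) -> int:
        return self.dist.shape[1]

    def p_within_horizon(self) -> np.ndarray:
        """P(d_P-P < 40 A) per pair = 1 - catch-all probability."""
        return 1.0 - self.dist[0, :, :, -1]


@dataclass
class PredictionTensors:
    """Head outputs kept in the autodiff graph (for training).

    Probability tensors plus the matching log-probabilities / logits.
    """

    dist: list            # 5 Tensors (L, L, 39)
    dist_logp: list
    ori2d: list           # 5 Tensors (L, L, 25|13)
    ori2d_logp: list
    ori1d: list           # 4 Tensors (L, 25)
    ori1d_logp: list
    contact: Tensor       # (L, L) probabilities
    contact_logit: Tensor

    def to_prediction(self) -> GeometryPrediction:
        contact = self.contact.v
        return GeometryPrediction(
            dist=np.stack([t.v for t in self.dist]),
            ori2d=[t.v for t in self.ori2d],
            ori1d=np.stack([t.v for t in self.ori1d]),
            contact=0.5 * (contact + contact.T))


# ----------------------------------------------------------------------
# parameters

def _lin_shapes(cfg: ModelConfig):
    c, cp = cfg.msa_channels, cfg.pair_channels
    h, d, ct = cfg.n_heads, cfg.opm_dim, cfg.tri_dim
    g = cp // cfg.conv_groups
    shapes = {}
    for b in range(cfg.n_blocks):
        p = f"b{b}."
        shapes.update({
            p + "row.q": (c, c), p + "row.k": (c, c), p + "row.v": (c, c),
            p + "row.bias": (cp, h), p + "row.gate": (c, c),
            p + "row.out": (c, c, "zero"),
            p + "col.q": (c, c), p + "col.k": (c, c), p + "col.v": (c, c),
            p + "col.gate": (c, c), p + "col.out": (c, c, "zero"),
            p + "mff.w1": (c, cfg.ff_mult * c),
            p + "mff.w2": (cfg.ff_mult * c, c, "zero"),
            p + "opm.a": (c, d), p + "opm.b": (c, d),
            p + "opm.out": (d * d, cp, "zero"),
        })
        for t in ("tro", "tri"):
            shapes.update({
                p + t + ".conv1": (3, 3, g, g, "conv"),
                p + t + ".conv2": (3, 3, g, g, "conv"),
                p + t + ".conv3": (3, 3, g, g, "conv"),
                p + t + ".mix": (cp, cp, "zero"),
                p + t + ".a": (cp, ct), p + t + ".ag": (cp, ct),
                p + t + ".b": (cp, ct), p + t + ".bg": (cp, ct),
                p + t + ".gate": (cp, cp),
                p + t + ".out": (ct, cp, "zero"),
            })
        shapes.update({
            p + "pff.w1": (cp, cfg.ff_mult * cp),
            p + "pff.w2": (cfg.ff_mult * cp, cp, "zero"),
            p + "p2m.attn": (cp, h), p + "p2m.v": (c, c),
            p + "p2m.gate": (c, c), p + "p2m.out": (c, c, "zero"),
            p + "mff2.w1": (c, cfg.ff_mult * c),
            p + "mff2.w2": (cfg.ff_mult * c, c, "zero"),
        })
    bins = BinSpec()
    hh = cfg.head_hidden
    shapes["head.pair_hidden"] = (cp, hh)
    for k in range(5):
        shapes[f"head.dist{k}"] = (hh, bins.n_dist_classes)
        shapes[f"head.ori2d{k}"] = (hh, bins.ori2d_classes(k))
    shapes["head.attn1d"] = (c, 1)
    shapes["head.msa_hidden"] = (c, hh)
    for g_ in range(4):
        shapes[f"head.ori1d{g_}"] = (hh, bins.n_ori1d_classes)
    shapes["head.contact"] = (hh, 1)
    return shapes


def init_parameters(cfg: ModelConfig, seed: int | None = None) -> dict:
    """Seeded parameter dict.  Residual output projections start at zero,
    so an untrained block is the identity map; gate biases start at +1
    (gates open)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    params: dict[str, Tensor] = {}
    for name, shape in _lin_shapes(cfg).items():
        tagged = isinstance(shape[-1], str)
        tag = shape[-1] if tagged else None
        dims = shape[:-1] if tagged else shape
        if tag == "zero":
            w = np.zeros(dims)
        elif tag == "conv":
            w = rng.normal(0.0, 0.02, size=dims)
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(dims[0]), size=dims)
        params[name + ".w"] = Tensor(w, requires_grad=True)
        if tag == "conv":
            continue        # the 3x3 convolutions are bias-free
        bias = np.zeros(dims[-1])
        if name.endswith(("gate", ".ag", ".bg")):
            bias = np.ones(dims[-1])
        params[name + ".b"] = Tensor(bias, requires_grad=True)
    return params


def _lin(params, name, x):
    return x @ params[name + ".w"] + params[name + ".b"]


def _check_finite(t: Tensor, where: str):
    if not np.isfinite(t.v).all():
        raise NumericError(f"non-finite activations in {where}")


# ----------------------------------------------------------------------
# block sublayers

def _heads_split(t: Tensor, n_heads: int) -> Tensor:
    """(..., L, h*dh) -> (..., h, L, dh)"""
    *lead, L, c = t.shape
    dh = c // n_heads
    t = t.reshape(*lead, L, n_heads, dh)
    axes = list(range(t.ndim))
    axes[-3], axes[-2] = axes[-2], axes[-3]
    return t.transpose(*axes)


def _heads_merge(t: Tensor) -> Tensor:
    """(..., h, L, dh) -> (..., L, h*dh)"""
    axes = list(range(t.ndim))
    axes[-3], axes[-2] = axes[-2], axes[-3]
    t = t.transpose(*axes)
    *lead, L, h, dh = t.shape
    return t.reshape(*lead, L, h * dh)


def _row_attention(m: Tensor, z: Tensor, params, pfx, cfg) -> Tensor:
    ml = m.layernorm()
    zl = z.layernorm()
    h = cfg.n_heads
    dh = cfg.msa_channels // h
    q = _heads_split(_lin(params, pfx + "row.q", ml), h)   # (n,h,L,dh)
    k = _heads_split(_lin(params, pfx + "row.k", ml), h)
    v = _heads_split(_lin(params, pfx + "row.v", ml), h)
    bias = _lin(params, pfx + "row.bias", zl).transpose(2, 0, 1)  # (h,L,L)
    logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
    attn = (logits + bias).softmax(axis=-1)
    out = _heads_merge(attn @ v)
    gate = _lin(params, pfx + "row.gate", ml).sigmoid()
    return m + _lin(params, pfx + "row.out", gate * out)


def _col_attention(m: Tensor, params, pfx, cfg) -> Tensor:
    ml = m.layernorm()
    h = cfg.n_heads
    dh = cfg.msa_channels // h
    mt = ml.transpose(1, 0, 2)                              # (L,n,c)
    q = _heads_split(_lin(params, pfx + "col.q", mt), h)    # (L,h,n,dh)
    k = _heads_split(_lin(params, pfx + "col.k", mt), h)
    v = _heads_split(_lin(params, pfx + "col.v", mt), h)
    attn = ((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            ).softmax(axis=-1)
    out = _heads_merge(attn @ v).transpose(1, 0, 2)         # (n,L,c)
    gate = _lin(params, pfx + "col.gate", ml).sigmoid()
    return m + _lin(params, pfx + "col.out", gate * out)


def _transition(x: Tensor, params, pfx, name) -> Tensor:
    xl = x.layernorm()
    return x + _lin(params, f"{pfx}{name}.w2",
                    _lin(params, f"{pfx}{name}.w1", xl).relu())


def outer_product_mean(m: Tensor, params, pfx, cfg) -> Tensor:
    """(n, L, c) -> (L, L, c') pair update via averaged outer products."""
    ml = m.layernorm()
    a = _lin(params, pfx + "opm.a", ml)   # (n,L,d)
    b = _lin(params, pfx + "opm.b", ml)
    n, L, d = a.shape
    A = a.transpose(1, 2, 0).reshape(L * d, n)
    B = b.transpose(0, 1, 2).reshape(n, L * d)
    op = (A @ B) * (1.0 / n)
    op = op.reshape(L, d, L, d).transpose(0, 2, 1, 3).reshape(L, L, d * d)
    return _lin(params, pfx + "opm.out", op)


def _res2net(z: Tensor, params, pfx, cfg) -> Tensor:
    """Multi-scale residual 3x3 convolution stack over the pair map."""
    g = cfg.pair_channels // cfg.conv_groups
    parts = [z[..., i * g:(i + 1) * g] for i in range(cfg.conv_groups)]
    y = parts[0]
    outs = [y]
    prev = None
    for i in range(1, cfg.conv_groups):
        x = parts[i] if prev is None else parts[i] + prev
        prev = conv3x3(x, params[f"{pfx}conv{i}.w"]).relu()
        outs.append(prev)
    mixed = _lin(params, pfx + "mix", concat(outs, axis=-1))
    return z + mixed


def _triangle(z: Tensor, params, pfx, cfg, outgoing: bool) -> Tensor:
    zl = z.layernorm()
    zc = _res2net(zl, params, pfx, cfg)
    a = _lin(params, pfx + "a", zc) * _lin(params, pfx + "ag", zc).sigmoid()
    b = _lin(params, pfx + "b", zc) * _lin(params, pfx + "bg", zc).sigmoid()
    At = a.transpose(2, 0, 1)     # (ct,L,L)
    Bt = b.transpose(2, 0, 1)
    if outgoing:   # out[i,j] = sum_k a[i,k] b[j,k]
        prod = At @ Bt.transpose(0, 2, 1)
    else:          # out[i,j] = sum_k a[k,i] b[k,j]
        prod = At.transpose(0, 2, 1) @ Bt
    out = prod.transpose(1, 2, 0).layernorm()
    gate = _lin(params, pfx + "gate", zc).sigmoid()
    return z + gate * _lin(params, pfx + "out", out)


def _pair_to_msa(m: Tensor, z: Tensor, params, pfx, cfg) -> Tensor:
    ml = m.layernorm()
    zl = z.layernorm()
    attn = _lin(params, pfx + "p2m.attn", zl).transpose(2, 0, 1)  # (h,L,L)
    attn = attn.softmax(axis=-1)
    h = cfg.n_heads
    v = _heads_split(_lin(params, pfx + "p2m.v", ml), h)  # (n,h,L,dh)
    out = _heads_merge(attn @ v)                          # (n,L,c)
    gate = _lin(params, pfx + "p2m.gate", ml).sigmoid()
    return m + _lin(params, pfx + "p2m.out", gate * out)


def rnaformer_block(m: Tensor, z: Tensor, params, cfg: ModelConfig,
                    block_index: int = 0):
    """One block: MSA->MSA, MSA->pair, pair->pair, pair->MSA."""
    pfx = f"b{block_index}."
    m = _row_attention(m, z, params, pfx, cfg)
    _check_finite(m, f"block {block_index} row attention")
    m = _col_attention(m, params, pfx, cfg)
    m = _transition(m, params, pfx, "mff")
    z = z + outer_product_mean(m, params, pfx, cfg)
    z = _triangle(z, params, pfx + "tro.", cfg, outgoing=True)
    z = _triangle(z, params, pfx + "tri.", cfg, outgoing=False)
    _check_finite(z, f"block {block_index} triangle updates")
    z = _transition(z, params, pfx, "pff")
    m = _pair_to_msa(m, z, params, pfx, cfg)
    m = _transition(m, params, pfx, "mff2")
    return m, z


# ----------------------------------------------------------------------
# full network

def _subsample_rows(msa_init: np.ndarray, cfg: ModelConfig) -> np.ndarray:
    n = msa_init.shape[0]
    if n <= cfg.max_rows:
        return msa_init
    rng = np.random.default_rng(cfg.seed)
    keep = rng.choice(np.arange(1, n), size=cfg.max_rows - 1, replace=False)
    return msa_init[np.concatenate([[0], np.sort(keep)])]


def single_pass(features: FeatureBundle, params, cfg: ModelConfig,
                recycle=None, train: bool = False):
    """One pass through all blocks; returns (msa_repr, pair_repr).

    ``recycle``: optional (first_msa_row (L, c), pair (L, L, c')) numpy
    arrays from the previous cycle, added after layer normalization.
    """
    msa_np = _subsample_rows(np.asarray(features.msa_init, float), cfg)
    n, L, c = msa_np.shape
    if L > cfg.max_len:
        raise CapacityError(f"L={L} exceeds max_len={cfg.max_len}")
    if c != cfg.msa_channels:
        raise CapacityError(
            f"feature channels {c} != model msa_channels "
            f"{cfg.msa_channels}")
    m = Tensor(msa_np)
    z = Tensor(np.asarray(features.pair_init, float))
    if recycle is not None:
        prev_m0, prev_z = recycle
        row0 = Tensor(np.asarray(prev_m0, float)).layernorm()
        pad = np.zeros((n, 1, 1))
        pad[0] = 1.0
        m = m + Tensor(pad) * row0
        z = z + Tensor(np.asarray(prev_z, float)).layernorm()
    for b in range(cfg.n_blocks):
        m, z = rnaformer_block(m, z, params, cfg, b)
    return m, z


def _heads(m: Tensor, z: Tensor, params, cfg: ModelConfig
           ) -> PredictionTensors:
    bins = BinSpec()
    zl = z.layernorm()
    zsym = zl + zl.transpose(1, 0, 2)
    hsym = _lin(params, "head.pair_hidden", zsym).relu()
    hraw = _lin(params, "head.pair_hidden", zl).relu()
    dist, dist_logp = [], []
    for k in range(5):
        src = hsym if k < 4 else hraw   # C4'-N map is asymmetric
        logits = _lin(params, f"head.dist{k}", src)
        dist.append(logits.softmax())
        dist_logp.append(logits.log_softmax())
    ori2d, ori2d_logp = [], []
    for k in range(5):
        src = hsym if k == 0 else hraw  # omega is the symmetric dihedral
        logits = _lin(params, f"head.ori2d{k}", src)
        ori2d.append(logits.softmax())
        ori2d_logp.append(logits.log_softmax())
    ml = m.layernorm()
    w = _lin(params, "head.attn1d", ml).softmax(axis=0)   # (n,L,1)
    s1d = (w * ml).sum(axis=0)                            # (L,c)
    h1d = _lin(params, "head.msa_hidden", s1d).relu()
    ori1d, ori1d_logp = [], []
    for g in range(4):
        logits = _lin(params, f"head.ori1d{g}", h1d)
        ori1d.append(logits.softmax())
        ori1d_logp.append(logits.log_softmax())
    clogit = _lin(params, "head.contact", hsym)
    clogit = clogit.reshape(clogit.shape[0], clogit.shape[1])
    return PredictionTensors(
        dist=dist, dist_logp=dist_logp, ori2d=ori2d, ori2d_logp=ori2d_logp,
        ori1d=ori1d, ori1d_logp=ori1d_logp,
        contact=clogit.sigmoid(), contact_logit=clogit)


def forward(features: FeatureBundle, params, cfg: ModelConfig,
            train: bool = False):
    """Full inference: ``n_cycles`` recycled passes, then the heads.

    Returns :class:`PredictionTensors`; call ``.to_prediction()`` for the
    numpy :class:`GeometryPrediction`.  During training the recycling
    inputs are detached (no gradient across cycles).
    """
    recycle = None
    m = z = None
    for _ in range(cfg.n_cycles):
        m, z = single_pass(features, params, cfg, recycle=recycle,
                           train=train)
        recycle = (m.v[0].copy(), z.v.copy())   # stop-gradient
    return _heads(m, z, params, cfg)


# ----------------------------------------------------------------------
# checkpoints

def save_checkpoint(path, params: dict, cfg: ModelConfig) -> None:
    arrays = {k: p.v for k, p in params.items()}
    arrays["__config__"] = np.frombuffer(
        json.dumps(asdict(cfg)).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_checkpoint(path):
    with np.load(str(path)) as zf:
        cfg = ModelConfig(**json.loads(bytes(zf["__config__"]).decode()))
        params = {k: Tensor(zf[k], requires_grad=True)
                  for k in zf.files if k != "__config__"}
    return params, cfg
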