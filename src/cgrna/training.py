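"""Loss stack, self-distillation confidence filtering, and training.

The total training loss combines cross-entropies over the 2D geometries
(10 channels: 5 distances + 5 orientations), the 1D torsions (4 channels)
and the contact map::

    Loss = L_2D + L_1D + 5 * L_cont
    L_2D   = 1/(10 L^2) sum_{i,j,g} CE(P^g_ij, Y^g_ij)
    L_1D   = 1/(4 L)    sum_{i,g}   CE(P^g_i,  Y^g_i)
    L_cont = 1/L^2      sum_{i,j}   CE(P^cont_ij, Y^cont_ij)

Masked elements contribute zero without changing the fixed normalizers.

For self-distillation, a reference P-P distance distribution is accumulated
per sequence separation s <= 128 over a sample of predictions; a pair's
confidence is the KL divergence of its predicted distribution from that
reference, and a nucleotide's confidence averages its pair scores over a
fixed window of 128.  Elements with confidence below 0.5 are masked out of
the distillation loss; the surviving predicted distributions become soft
labels.

Training runs in three phases: real labels only; a 1:3 mix of real and
distilled samples per epoch; and a fine-tune on long sequences at half the
learning rate (Adam, 1e-4 then 5e-5).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor
from .features import FeatureBundle
from .geometry import GeometryLabels
from .network import (GeometryPrediction, ModelConfig, PredictionTensors,
                      forward)

logger = logging.getLogger(__name__)

__all__ = [
    "LossBreakdown", "ReferenceDistribution", "ConfidenceMap", "SoftLabels",
    "losses", "total_loss", "build_reference", "kl_confidence",
    "make_distillation_labels", "Adam", "TrainingSchedule", "train",
    "distance_argmax_accuracy",
]

_EPS = 1e-12
KL_WINDOW = 128          # sequence-separation window of the confidence map
CONF_THRESHOLD = 0.5     # distillation mask threshold (nats)
CONTACT_LOSS_WEIGHT = 5.0


# ----------------------------------------------------------------------
# losses

@dataclass
class LossBreakdown:
    """Loss components; ``total = l2d + l1d + 5 * lcont``.

    ``graph`` holds the scalar Tensor when computed inside the autodiff
    graph (for backward), else None.
    """

    total: float
    l2d: float
    l1d: float
    lcont: float
    graph: Tensor | None = None


def total_loss(l2d: float, l1d: float, lcont: float):
    """The published combination of the three loss components."""
    return l2d + l1d + CONTACT_LOSS_WEIGHT * lcont


@dataclass
class SoftLabels:
    """Distillation labels: predicted distributions plus masks."""

    dist: np.ndarray       # (5, L, L, 39)
    ori2d: list            # 5 x (L, L, classes)
    ori1d: np.ndarray      # (4, L, 25)
    contact: np.ndarray    # (L, L) probabilities
    mask2d: np.ndarray     # (L, L) bool
    mask1d: np.ndarray     # (4, L) bool


def _as_logp(t, is_tensor: bool):
    if is_tensor:
        return t
    return Tensor(np.log(np.asarray(t, float) + _EPS))


def _ce_2d(logp: Tensor, label, mask: np.ndarray) -> Tensor:
    """Masked cross-entropy summed over one 2D channel."""
    L = logp.shape[0]
    if np.asarray(label).ndim == 2:       # hard classes
        ii = np.arange(L)[:, None] * np.ones((1, L), int)
        jj = np.arange(L)[None, :] * np.ones((L, 1), int)
        picked = logp[ii, jj, np.asarray(label)]
        return -(picked * Tensor(mask.astype(float))).sum()
    y = Tensor(np.asarray(label, float) * mask[..., None])
    return -(y * logp).sum()


def _ce_1d(logp: Tensor, label, mask: np.ndarray) -> Tensor:
    L = logp.shape[0]
    if np.asarray(label).ndim == 1:
        picked = logp[np.arange(L), np.asarray(label)]
        return -(picked * Tensor(mask.astype(float))).sum()
    y = Tensor(np.asarray(label, float) * mask[..., None])
    return -(y * logp).sum()


def losses(pred, labels, extra_mask2d: np.ndarray | None = None,
           extra_mask1d: np.ndarray | None = None) -> LossBreakdown:
    """Loss breakdown for one sample.

    ``pred`` is a :class:`PredictionTensors` (training, keeps the graph) or
    a :class:`GeometryPrediction` (numpy).  ``labels`` is
    :class:`GeometryLabels` (one-hot classes) or :class:`SoftLabels`
    (distillation distributions).  Extra masks — e.g. the distillation
    confidence masks — are intersected with the label masks.
    """
    is_tensor = isinstance(pred, PredictionTensors)
    L = (pred.dist[0].shape[0] if is_tensor else pred.dist.shape[1])
    n_pred_classes = (pred.dist[0].shape[-1] if is_tensor
                      else pred.dist.shape[-1])
    lab_dist = np.asarray(labels.dist)
    if lab_dist.ndim == 4 and lab_dist.shape[-1] != n_pred_classes:
        raise ValueError(
            f"label class count {lab_dist.shape[-1]} != prediction "
            f"{n_pred_classes}")

    mask2d = labels.mask2d.copy()
    mask1d = labels.mask1d.copy()
    if extra_mask2d is not None:
        mask2d &= extra_mask2d
    if extra_mask1d is not None:
        mask1d = mask1d & extra_mask1d

    zero = Tensor(0.0)
    l2d_t = zero
    for k in range(5):
        logp = (pred.dist_logp[k] if is_tensor
                else _as_logp(pred.dist[k], False))
        l2d_t = l2d_t + _ce_2d(logp, labels.dist[k], mask2d)
    for k in range(5):
        logp = (pred.ori2d_logp[k] if is_tensor
                else _as_logp(pred.ori2d[k], False))
        l2d_t = l2d_t + _ce_2d(logp, labels.ori2d[k], mask2d)
    l2d_t = l2d_t * (1.0 / (10.0 * L * L))

    l1d_t = zero
    for g in range(4):
        logp = (pred.ori1d_logp[g] if is_tensor
                else _as_logp(pred.ori1d[g], False))
        l1d_t = l1d_t + _ce_1d(logp, labels.ori1d[g], mask1d[g])
    l1d_t = l1d_t * (1.0 / (4.0 * L))

    y = np.asarray(labels.contact, float)
    mk = Tensor(mask2d.astype(float))
    if is_tensor:
        z = pred.contact_logit
        bce = z.softplus() - Tensor(y) * z
    else:
        p = np.clip(np.asarray(pred.contact, float), _EPS, 1 - _EPS)
        bce = Tensor(-(y * np.log(p) + (1 - y) * np.log(1 - p)))
    lcont_t = (bce * mk).sum() * (1.0 / (L * L))

    total_t = l2d_t + l1d_t + CONTACT_LOSS_WEIGHT * lcont_t
    return LossBreakdown(
        total=float(total_t.v), l2d=float(l2d_t.v), l1d=float(l1d_t.v),
        lcont=float(lcont_t.v), graph=total_t if is_tensor else None)


# ----------------------------------------------------------------------
# self-distillation confidence

@dataclass
class ReferenceDistribution:
    """Mean P-P distance distribution per sequence separation.

    ``probs``: (max_sep, n_classes), row s-1 for separation s; rows sum to
    1 where ``present``.
    """

    probs: np.ndarray
    present: np.ndarray
    max_sep: int = KL_WINDOW


def build_reference(pred_set, max_sep: int = KL_WINDOW
                    ) -> ReferenceDistribution:
    """Accumulate the mean P-P distance distribution by separation."""
    pred_set = list(pred_set)
    if not pred_set:
        raise ValueError("need at least one prediction")
    n_classes = pred_set[0].dist.shape[-1]
    acc = np.zeros((max_sep, n_classes))
    cnt = np.zeros(max_sep)
    for pred in pred_set:
        L = pred.L
        pp = pred.dist[0]
        for s in range(1, min(L, max_sep + 1)):
            rows = pp[np.arange(L - s), np.arange(s, L)]
            acc[s - 1] += rows.sum(axis=0)
            cnt[s - 1] += len(rows)
    present = cnt > 0
    probs = np.zeros_like(acc)
    probs[present] = acc[present] / cnt[present, None]
    probs[present] /= probs[present].sum(axis=1, keepdims=True)
    return ReferenceDistribution(probs=probs, present=present,
                                 max_sep=max_sep)


@dataclass
class ConfidenceMap:
    """KL confidence per pair (c_ij) and per nucleotide (c_i)."""

    c_pair: np.ndarray
    c_nt: np.ndarray
    threshold: float = CONF_THRESHOLD


def kl_confidence(pred: GeometryPrediction, ref: ReferenceDistribution,
                  eps: float = 1e-8) -> ConfidenceMap:
    """c_ij = KL(P_ij || P^ref_|i-j|) on the P-P distance distributions,
    for separations within the window; c_i averages c_ij over the fixed
    window of 128 pairs j = i+1 .. i+128 (out-of-range terms are 0)."""
    L = pred.L
    pp = pred.dist[0]
    c_pair = np.zeros((L, L))
    smoothed = False
    for s in range(1, min(L, ref.max_sep + 1)):
        if not ref.present[s - 1]:
            continue
        r = ref.probs[s - 1]
        if (r <= 0).any():
            smoothed = True
            r = np.where(r > 0, r, eps)   # smooth zero-mass bins only
        i = np.arange(L - s)
        p = pp[i, i + s]
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(p > 0, p * np.log(p / r), 0.0)
        kl = term.sum(axis=1)
        c_pair[i, i + s] = kl
        c_pair[i + s, i] = kl
    if smoothed:
        logger.debug("reference rows epsilon-smoothed (%g)", eps)
    c_nt = np.zeros(L)
    for i in range(L):
        hi = min(L, i + KL_WINDOW + 1)
        c_nt[i] = c_pair[i, i + 1:hi].sum() / KL_WINDOW
    return ConfidenceMap(c_pair=c_pair, c_nt=c_nt)


def make_distillation_labels(pred: GeometryPrediction, conf: ConfidenceMap,
                             threshold: float = CONF_THRESHOLD):
    """Soft labels from a prediction plus the confidence masks.

    Pairs with c_ij < threshold and nucleotides with c_i < threshold are
    masked out of the 2D / 1D losses respectively."""
    L = pred.L
    mask2d = conf.c_pair >= threshold
    np.fill_diagonal(mask2d, False)
    mask1d = np.broadcast_to(conf.c_nt >= threshold, (4, L)).copy()
    return SoftLabels(dist=pred.dist.copy(),
                      ori2d=[a.copy() for a in pred.ori2d],
                      ori1d=pred.ori1d.copy(),
                      contact=pred.contact.copy(),
                      mask2d=mask2d, mask1d=mask1d)


# ----------------------------------------------------------------------
# optimizer and schedule

class Adam:
    """Standard Adam on a flat parameter dict, with optional global-norm
    gradient clipping (stabilizes small-batch training)."""

    def __init__(self, params: dict, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float | None = 5.0):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = {k: np.zeros_like(p.v) for k, p in params.items()}
        self.u = {k: np.zeros_like(p.v) for k, p in params.items()}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = 1.0
        if self.clip_norm is not None:
            gsq = sum(float((p.grad ** 2).sum())
                      for p in self.params.values() if p.grad is not None)
            gnorm = np.sqrt(gsq)
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad * scale
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.u[k] = b2 * self.u[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            uhat = self.u[k] / (1 - b2 ** self.t)
            p.v -= self.lr * mhat / (np.sqrt(uhat) + self.eps)

    def zero_grad(self):
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainingSchedule:
    """Three-phase schedule: real-only, 1:3 real:distilled, long-sequence
    fine-tune at the reduced learning rate."""

    phase1_epochs: int = 1
    phase2_epochs: int = 0
    phase3_epochs: int = 0
    lr: float = 1e-4
    lr_finetune: float = 5e-5
    distill_ratio: int = 3
    long_cutoff: int = 100
    crop: int = 150
    batch_size: int = 1            # samples per optimizer step
    clip_norm: float = 5.0
    seed: int = 0
    max_steps: int | None = None   # optional cap per phase (toy runs)


def _crop_sample(sample: dict, crop: int, rng) -> dict:
    bundle: FeatureBundle = sample["features"]
    L = bundle.pair_init.shape[0]
    if L <= crop:
        return sample
    start = int(rng.integers(0, L - crop + 1))
    sl = slice(start, start + crop)
    labels: GeometryLabels = sample["labels"]
    cropped_labels = GeometryLabels(
        dist=labels.dist[:, sl, sl],
        ori2d=[a[sl, sl] for a in labels.ori2d],
        ori1d=labels.ori1d[:, sl],
        contact=labels.contact[sl, sl],
        mask2d=labels.mask2d[sl, sl],
        mask1d=labels.mask1d[:, sl])
    out = dict(sample)
    out["features"] = FeatureBundle(msa_init=bundle.msa_init[:, sl],
                                    pair_init=bundle.pair_init[sl, sl])
    out["labels"] = cropped_labels
    return out


def _run_phase(params, cfg: ModelConfig, samples, epochs: int, lr: float,
               rng, log: list, schedule: TrainingSchedule,
               phase_name: str) -> None:
    if epochs <= 0 or not samples:
        return
    opt = Adam(params, lr=lr, clip_norm=schedule.clip_norm)
    steps = 0
    bs = max(1, schedule.batch_size)
    for epoch in range(epochs):
        order = rng.permutation(len(samples))
        for lo in range(0, len(order), bs):
            chunk = order[lo:lo + bs]
            opt.zero_grad()
            tot = np.zeros(4)
            for si in chunk:
                sample = _crop_sample(samples[si], schedule.crop, rng)
                pred = forward(sample["features"], params, cfg, train=True)
                br = losses(pred, sample["labels"],
                            sample.get("distill_mask2d"),
                            sample.get("distill_mask1d"))
                br.graph.backward()
                tot += (br.total, br.l2d, br.l1d, br.lcont)
            opt.step()
            tot /= len(chunk)
            log.append((phase_name, epoch, *tot))
            steps += 1
            if schedule.max_steps is not None and steps >= schedule.max_steps:
                return


def train(params, cfg: ModelConfig, pdb_set, distill_set=None,
          schedule: TrainingSchedule | None = None, log_path=None):
    """Three-phase training; mutates and returns ``params``.

    ``pdb_set``: samples with real (one-hot) labels; ``distill_set``:
    samples whose labels are :class:`SoftLabels` with confidence masks.
    Returns (params, log) where log rows are (phase, epoch, total, l2d,
    l1d, lcont).
    """
    schedule = schedule or TrainingSchedule()
    pdb_set = list(pdb_set)
    distill_set = list(distill_set or [])
    if not pdb_set:
        raise ValueError("empty training set")
    rng = np.random.default_rng(schedule.seed)
    log: list = []

    _run_phase(params, cfg, pdb_set, schedule.phase1_epochs, schedule.lr,
               rng, log, schedule, "real")

    if schedule.phase2_epochs > 0:
        n = len(pdb_set)
        want = schedule.distill_ratio * n
        for epoch_block in range(schedule.phase2_epochs):
            if distill_set:
                take = min(want, len(distill_set))
                idx = rng.choice(len(distill_set), size=take, replace=False)
                mixed = pdb_set + [distill_set[i] for i in idx]
            else:
                mixed = pdb_set
            _run_phase(params, cfg, mixed, 1, schedule.lr, rng, log,
                       schedule, "mixed")

    long_set = [s for s in pdb_set
                if s["features"].pair_init.shape[0] > schedule.long_cutoff]
    if schedule.phase3_epochs > 0 and not long_set:
        logger.info("no sequences above %d nt; fine-tune phase skipped",
                    schedule.long_cutoff)
    _run_phase(params, cfg, long_set, schedule.phase3_epochs,
               schedule.lr_finetune, rng, log, schedule, "finetune")

    if log_path is not None:
        with open(log_path, "w") as fh:
            fh.write("phase\tepoch\ttotal\tl2d\tl1d\tlcont\n")
            for row in log:
                fh.write("\t".join(str(x) for x in row) + "\n")
    return params, log


def distance_argmax_accuracy(pred, labels: GeometryLabels) -> float:
    """Fraction of unmasked pair elements whose argmax distance class
    matches the label, over all five distance channels."""
    if isinstance(pred, PredictionTensors):
        dist = np.stack([t.v for t in pred.dist])
    else:
        dist = pred.dist
    hits = 0
    tot = 0
    for k in range(5):
        am = dist[k].argmax(-1)
        m = labels.mask2d
        hits += int((am[m] == labels.dist[k][m]).sum())
        tot += int(m.sum())
    return hits / max(tot, 1)
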