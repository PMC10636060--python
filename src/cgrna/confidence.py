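"""Model-confidence features and the fitted eRMSD estimator.

Four variables summarize how confident a prediction/fold is:

* ``pRMSD`` — mean pairwise RMSD (A) of the ten lowest-energy decoys:
  decoy convergence;
* ``mp`` — mean maximum probability of the predicted P-P distances over
  the top 15 L pairs ranked by P(d_P-P < 40 A), averaged per occupied
  distance bin over the 38 finite bins: prediction sharpness;
* ``std`` — mean per-pair standard deviation of the P-P distance
  probability vectors: map contrast;
* ``prop`` — fraction of pairs with P(d_P-P < 40 A) > 0.45: restraint
  coverage.

The estimated model RMSD is the fitted linear form

    eRMSD = 0.64*pRMSD - 189.43*std - 4.01*mp - 1.06*prop + 15.2

whose coefficients can be refit by ordinary least squares on (features,
true RMSD) samples.  The same ``std`` statistic ranks candidate MSAs:
sharper predicted distance maps (larger std) indicate the more informative
alignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .evalio import kabsch_rmsd
from .geometry import BinSpec
from .network import GeometryPrediction

logger = logging.getLogger(__name__)

__all__ = [
    "ConfidenceFeatures", "EstimatorCoefficients", "compute_mp",
    "compute_std", "compute_prop", "compute_features", "estimate_rmsd",
    "refit_estimator", "select_msa",
]

_BINS = BinSpec()
PROP_THRESHOLD = 0.45
TOP_PAIRS_PER_NT = 15


@dataclass(frozen=True)
class ConfidenceFeatures:
    pRMSD: float
    mp: float
    std: float
    prop: float

    def __post_init__(self):
        if not (0 <= self.mp <= 1 and 0 <= self.prop <= 1
                and self.pRMSD >= 0 and self.std >= 0):
            raise ValueError("confidence features out of range")

    def as_vector(self) -> np.ndarray:
        return np.array([self.pRMSD, self.std, self.mp, self.prop])


@dataclass(frozen=True)
class EstimatorCoefficients:
    """Fitted linear-regression coefficients (order: pRMSD, std, mp,
    prop, intercept)."""

    pRMSD: float = 0.64
    std: float = -189.43
    mp: float = -4.01
    prop: float = -1.06
    intercept: float = 15.2

    def as_vector(self) -> np.ndarray:
        return np.array([self.pRMSD, self.std, self.mp, self.prop])


def _top_pairs(pred: GeometryPrediction):
    """Indices of the top 15 L pairs (i < j) by P(d_P-P < 40 A)."""
    L = pred.L
    pw = pred.p_within_horizon()
    iu, ju = np.triu_indices(L, 1)
    scores = pw[iu, ju]
    k = min(TOP_PAIRS_PER_NT * L, len(scores))
    order = np.argsort(-scores, kind="stable")[:k]
    return iu[order], ju[order]


def compute_mp(pred: GeometryPrediction) -> float:
    """Mean maximum distance probability, bin-averaged (Eq. mp).

    Each selected pair is assigned to the distance bin of its maximum
    probability (ties broken toward the lower class); pairs whose argmax
    is the catch-all class fall outside the 38 finite bins and are
    excluded; empty bins contribute 0.
    """
    if pred.L < 2:
        raise ValueError("need at least 2 nucleotides")
    ii, jj = _top_pairs(pred)
    pp = pred.dist[0][ii, jj]              # (m, 39)
    kmax = pp.argmax(axis=1)               # ties -> lowest index
    pmax = pp[np.arange(len(pp)), kmax]
    nb = _BINS.n_dist                      # 38 finite bins
    total = 0.0
    for k in range(nb):
        sel = kmax == k
        if sel.any():
            total += pmax[sel].mean()
    return float(total / nb)


def compute_std(pred: GeometryPrediction) -> float:
    """Mean per-pair standard deviation of the P-P probability vectors."""
    L = pred.L
    iu, ju = np.triu_indices(L, 1)
    return float(pred.dist[0][iu, ju].std(axis=1).mean())


def compute_prop(pred: GeometryPrediction,
                 threshold: float = PROP_THRESHOLD) -> float:
    L = pred.L
    iu, ju = np.triu_indices(L, 1)
    return float((pred.p_within_horizon()[iu, ju] > threshold).mean())


def compute_features(pred: GeometryPrediction, decoys) -> ConfidenceFeatures:
    """All four confidence features from a prediction and its decoys."""
    decoys = list(decoys)
    if not decoys:
        raise ValueError("need at least one decoy")
    order = np.argsort([d.energy for d in decoys], kind="stable")
    top = [decoys[i] for i in order[:10]]
    if len(top) == 1:
        logger.warning("single decoy: pRMSD is 0 by definition")
        prmsd = 0.0
    else:
        vals = [kabsch_rmsd(top[a].structure, top[b].structure)
                for a in range(len(top)) for b in range(a + 1, len(top))]
        prmsd = float(np.mean(vals))
    return ConfidenceFeatures(pRMSD=prmsd, mp=compute_mp(pred),
                              std=compute_std(pred),
                              prop=compute_prop(pred))


def estimate_rmsd(f: ConfidenceFeatures,
                  c: EstimatorCoefficients | None = None) -> float:
    """The fitted linear eRMSD (A); may be negative for very confident
    predictions (reported raw)."""
    c = c or EstimatorCoefficients()
    val = float(f.as_vector() @ c.as_vector() + c.intercept)
    if val < 0:
        logger.info("negative eRMSD %.2f (very confident prediction)", val)
    return val


def refit_estimator(samples) -> tuple[EstimatorCoefficients, float]:
    """Ordinary least squares of true RMSD on the four features.

    ``samples``: iterable of (ConfidenceFeatures, rmsd).  Returns
    (coefficients, R^2).  Raises on fewer than 5 samples or a rank-
    deficient design.
    """
    samples = list(samples)
    if len(samples) < 5:
        raise ValueError(f"need at least 5 samples, got {len(samples)}")
    X = np.stack([f.as_vector() for f, _ in samples])
    y = np.array([r for _, r in samples], float)
    A = np.column_stack([X, np.ones(len(y))])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise np.linalg.LinAlgError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - float((resid ** 2).sum()) / max(ss_tot, 1e-300)
    coef = EstimatorCoefficients(pRMSD=float(beta[0]), std=float(beta[1]),
                                 mp=float(beta[2]), prop=float(beta[3]),
                                 intercept=float(beta[4]))
    return coef, r2


def select_msa(candidates, predictor) -> int:
    """Pick the alignment whose predicted distance maps are sharpest.

    ``predictor``: callable Alignment -> GeometryPrediction.  Returns the
    argmax of the ``std`` statistic (ties -> lowest index): confident,
    peaked distance distributions have larger per-vector spread than flat
    ones.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("no candidate alignments")
    stds = [compute_std(predictor(c)) for c in candidates]
    return int(np.argmax(stds))
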