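"""Restraint potentials and 3D folding by energy minimization.

Predicted geometry distributions are converted into smooth potentials of
the form -ln((p + eps) / (p_ref + eps)) tabulated at bin centers and
cubically interpolated (periodic for dihedrals).  Only confident elements
become restraints: distance pairs with P(d < 40 A) above 0.45, 2D
orientations with assigned-mass above 0.65, contacts with probability
above 0.6; the four 1D torsion channels are always restrained.

The total energy of a coarse structure is the published weighted sum

    E = w1 E_dist + w2 E_ori + w3 E_cont + w4 E_int,
    E_ori = E_ori2D + (L/2) E_ori1D,

with default weights w1 = 1.03, w2 = 1.0, w3 = 1.05, w4 = 0.05.  E_int is
a simplified physics term (this package folds a 4-atom-per-nucleotide
coarse-grained chain, not full-atom models): harmonic virtual bonds and
angles toward ideal A-form values plus a quartic soft-sphere repulsion
below 3.2 A between non-bonded coarse atoms.

Folding generates 20 starting structures (predicted stems as ideal A-form
helices, the rest as seeded self-avoiding walks), minimizes each with
L-BFGS under a staged schedule that ramps the repulsion up late, applies a
clash-refinement step, and returns the lowest-energy decoy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .evalio import clash_count
from .geometry import BinSpec, CoarseStructure, DIST_PAIRS, ORI2D_KIND
from .network import GeometryPrediction
from .synthetic import build_from_pairs, helix_pair_coords

logger = logging.getLogger(__name__)

__all__ = [
    "EnergyWeights", "RestraintConfig", "RestraintSet", "Decoy",
    "FoldResult", "MinimizeOptions", "potentials_from_prediction",
    "energy", "combine_energy", "internal_energy", "generate_starts",
    "minimize", "fold", "refine_clashes", "nested_stems_from_matrix",
]

_BINS = BinSpec()


@dataclass(frozen=True)
class EnergyWeights:
    """Published weights of the total-energy combination."""

    w_dist: float = 1.03
    w_ori: float = 1.0
    w_cont: float = 1.05
    w_internal: float = 0.05

    def __post_init__(self):
        if min(self.w_dist, self.w_ori, self.w_cont, self.w_internal) < 0:
            raise ValueError("weights must be nonnegative")


@dataclass(frozen=True)
class RestraintConfig:
    """Selection thresholds and potential parameters."""

    dist_threshold: float = 0.45
    ori_threshold: float = 0.65
    contact_threshold: float = 0.6
    eps: float = 1e-4            # probability floor inside the log-ratio
    left_slope: float = 4.0      # linear penalty slope below the 2 A edge
    use_distances: bool = True
    use_orientations: bool = True
    use_contacts: bool = True

    def __post_init__(self):
        for t in (self.dist_threshold, self.ori_threshold,
                  self.contact_threshold):
            if not 0.0 <= t <= 1.0:
                raise ValueError("thresholds must lie in [0, 1]")


@dataclass
class MinimizeOptions:
    """Staged L-BFGS schedule: each stage is (repulsion scale, potential
    smoothing in bins, orientation scale).  Early stages run on
    bin-smoothed potentials with soft sterics and no orientation terms so
    the distance restraints can set the global topology; orientations and
    repulsion ramp up late, and the last stage uses the exact potentials."""

    maxiter: int = 300            # L-BFGS iterations per stage
    stages: tuple = ((0.0, 6.0, 0.0), (0.0, 3.0, 0.0), (0.2, 1.5, 0.0),
                     (0.5, 0.75, 0.5), (1.0, 0.0, 1.0))
    lbfgs_memory: int = 10
    ftol: float = 1e-8


def combine_energy(e_dist: float, e_ori2d: float, e_ori1d: float,
                   e_cont: float, e_internal: float, L: int,
                   weights: EnergyWeights | None = None) -> float:
    """The published weighted energy combination (with the L/2 factor
    joining the 2D and 1D orientation terms)."""
    w = weights or EnergyWeights()
    e_ori = e_ori2d + 0.5 * L * e_ori1d
    return (w.w_dist * e_dist + w.w_ori * e_ori + w.w_cont * e_cont
            + w.w_internal * e_internal)


# ----------------------------------------------------------------------
# cubic (Catmull-Rom) interpolation on a uniform grid

class _Spline:
    """Vectorized per-row cubic interpolation of tabulated potentials.

    ``values``: (m, nb) tables on centers x0 + dx*k.  Periodic tables wrap;
    aperiodic tables clamp flat beyond the last center and rise linearly
    with ``left_slope`` below the first center.
    """

    def __init__(self, values: np.ndarray, x0: float, dx: float,
                 periodic: bool, left_slope: float = 0.0):
        self.V = np.asarray(values, float)
        self.x0 = x0
        self.dx = dx
        self.periodic = periodic
        self.left_slope = left_slope
        # Monotonicity-limited tangents (Fritsch-Butland): log-ratio
        # potential tables have deep wells next to flat plateaus, and
        # unlimited cubic tangents would overshoot there, carpeting the
        # energy surface with spurious local minima.
        V = self.V
        if periodic:
            d = np.roll(V, -1, axis=1) - V          # slope k -> k+1
            d_prev = np.roll(d, 1, axis=1)
            self.M = self._limited(d_prev, d)
        else:
            d = np.diff(V, axis=1)
            M = np.empty_like(V)
            M[:, 1:-1] = self._limited(d[:, :-1], d[:, 1:])
            M[:, 0] = d[:, 0]
            M[:, -1] = d[:, -1]
            self.M = M

    @staticmethod
    def _limited(d_prev, d_next):
        """Harmonic-mean tangents, zero across extrema."""
        prod = d_prev * d_next
        with np.errstate(divide="ignore", invalid="ignore"):
            harm = 2.0 * prod / (d_prev + d_next)
        return np.where(prod > 0, harm, 0.0)

    def __call__(self, x: np.ndarray):
        """(values, derivatives d/dx) at x, one table row per element."""
        V, M = self.V, self.M
        m, nb = V.shape
        rows = np.arange(m)
        if self.periodic:
            period = nb * self.dx
            s = np.mod(x - self.x0, period) / self.dx
            k = np.floor(s).astype(int) % nb
            t = s - np.floor(s)
            k1 = (k + 1) % nb
            v0, v1 = V[rows, k], V[rows, k1]
            m0, m1 = M[rows, k], M[rows, k1]
        else:
            lo = self.x0
            hi = self.x0 + (nb - 1) * self.dx
            xc = np.clip(x, lo, hi)
            s = (xc - lo) / self.dx
            k = np.minimum(np.floor(s).astype(int), nb - 2)
            t = s - k
            v0, v1 = V[rows, k], V[rows, k + 1]
            m0, m1 = M[rows, k], M[rows, k + 1]
        t2 = t * t
        t3 = t2 * t
        h00 = 2 * t3 - 3 * t2 + 1
        h10 = t3 - 2 * t2 + t
        h01 = -2 * t3 + 3 * t2
        h11 = t3 - t2
        u = h00 * v0 + h10 * m0 + h01 * v1 + h11 * m1
        du = ((6 * t2 - 6 * t) * v0 + (3 * t2 - 4 * t + 1) * m0
              + (-6 * t2 + 6 * t) * v1 + (3 * t2 - 2 * t) * m1) / self.dx
        if not self.periodic:
            below = x < lo
            above = x > hi
            if below.any():
                u = np.where(below, V[rows, 0] + (lo - x) * self.left_slope,
                             u)
                du = np.where(below, -self.left_slope, du)
            if above.any():
                du = np.where(above, 0.0, du)
                u = np.where(above, V[rows, -1], u)
        return u, du


# ----------------------------------------------------------------------
# restraint construction

@dataclass
class _PairChannel:
    idx_i: np.ndarray
    idx_j: np.ndarray
    spline: _Spline


@dataclass
class _ContactChannel:
    idx_i: np.ndarray
    idx_j: np.ndarray
    strength: np.ndarray      # -ln(p/(1-p)), negative = favorable


@dataclass
class RestraintSet:
    """Interpolated potentials for one prediction."""

    L: int
    dist: list                 # 5 _PairChannel (possibly empty)
    ori2d: list                # 5 _PairChannel
    ori1d: list                # 4 _PairChannel (idx_j unused)
    contact: _ContactChannel
    config: RestraintConfig

    @property
    def n_selected(self) -> dict:
        def count(chs):
            return sum(len(c.idx_i) for c in chs if c is not None)
        return {"dist": count(self.dist), "ori2d": count(self.ori2d),
                "ori1d": count(self.ori1d),
                "contact": len(self.contact.idx_i)}


def potentials_from_prediction(pred: GeometryPrediction,
                               cfg: RestraintConfig | None = None,
                               reference=None) -> RestraintSet:
    """Build the restraint set from predicted distributions.

    ``reference``: optional :class:`~cgrna.training.ReferenceDistribution`
    supplying the background P-P distance distribution by separation;
    without it a uniform background is used for every channel.
    """
    cfg = cfg or RestraintConfig()
    bins = _BINS
    L = pred.L
    eps = cfg.eps
    iu, ju = np.triu_indices(L, 1)
    p_within = pred.p_within_horizon()

    dist_ch = []
    dc0 = bins.dist_centers()[0]
    if cfg.use_distances:
        sel_sym = p_within[iu, ju] > cfg.dist_threshold
        for k in range(5):
            if k < 4:
                ii, jj = iu[sel_sym], ju[sel_sym]
            else:       # C4'-N: both directions are distinct restraints
                ii = np.concatenate([iu[sel_sym], ju[sel_sym]])
                jj = np.concatenate([ju[sel_sym], iu[sel_sym]])
            if len(ii) == 0:
                dist_ch.append(None)
                continue
            p = pred.dist[k][ii, jj, :bins.n_dist]
            pref = np.full(bins.n_dist_classes, 1.0 / bins.n_dist_classes)
            pref_rows = np.broadcast_to(pref[:bins.n_dist],
                                        p.shape).copy()
            if reference is not None and k == 0:
                sep = np.abs(ii - jj)
                ok = (sep <= reference.max_sep) & \
                    reference.present[np.clip(sep - 1, 0,
                                              reference.max_sep - 1)]
                pref_rows[ok] = reference.probs[sep[ok] - 1][:, :bins.n_dist]
            V = -np.log((p + eps) / (pref_rows + eps))
            V = V - V[:, -1:]        # anchor: flat zero beyond 40 A
            dist_ch.append(_PairChannel(ii, jj, _Spline(
                V, dc0, 1.0, periodic=False, left_slope=cfg.left_slope)))
    else:
        dist_ch = [None] * 5

    ori_ch = []
    if cfg.use_orientations:
        for k in range(5):
            nb = bins.n_dihedral if ORI2D_KIND[k] == "dihedral" \
                else bins.n_angle
            assigned = 1.0 - pred.ori2d[k][:, :, -1]
            if k == 0:
                ii, jj = iu, ju        # symmetric: one direction suffices
            else:
                off = ~np.eye(L, dtype=bool)
                ii, jj = np.nonzero(off)
            sel = assigned[ii, jj] > cfg.ori_threshold
            ii, jj = ii[sel], jj[sel]
            if len(ii) == 0:
                ori_ch.append(None)
                continue
            p = pred.ori2d[k][ii, jj, :nb]
            n_classes = pred.ori2d[k].shape[-1]
            V = -np.log((p + eps) / (1.0 / n_classes + eps))
            if ORI2D_KIND[k] == "dihedral":
                sp = _Spline(V, bins.dihedral_centers()[0], 15.0,
                             periodic=True)
            else:
                sp = _Spline(V, bins.angle_centers()[0], 15.0,
                             periodic=False)
            ori_ch.append(_PairChannel(ii, jj, sp))
    else:
        ori_ch = [None] * 5

    ori1d_ch = []
    if cfg.use_orientations:
        for g in range(4):
            assigned = 1.0 - pred.ori1d[g][:, -1]
            idx = np.nonzero(assigned > 0.5)[0]
            if len(idx) == 0:
                ori1d_ch.append(None)
                continue
            p = pred.ori1d[g][idx, :bins.n_dihedral]
            n_classes = pred.ori1d[g].shape[-1]
            V = -np.log((p + eps) / (1.0 / n_classes + eps))
            ori1d_ch.append(_PairChannel(
                idx, idx, _Spline(V, bins.dihedral_centers()[0], 15.0,
                                  periodic=True)))
    else:
        ori1d_ch = [None] * 4

    if cfg.use_contacts:
        sep = ju - iu
        psel = pred.contact[iu, ju]
        m = (psel > cfg.contact_threshold) & (sep >= 2)
        strength = -np.log((psel[m] + eps) / (1 - psel[m] + eps))
        contact = _ContactChannel(iu[m], ju[m], strength)
    else:
        contact = _ContactChannel(np.array([], int), np.array([], int),
                                  np.array([]))

    rs = RestraintSet(L=L, dist=dist_ch, ori2d=ori_ch, ori1d=ori1d_ch,
                      contact=contact, config=cfg)
    if sum(rs.n_selected.values()) == 0:
        logger.warning("empty restraint selection; folding will proceed on "
                       "the internal energy only")
    return rs


def nested_stems_from_matrix(ss: np.ndarray, threshold: float = 0.5,
                             min_loop: int = 3) -> list:
    """Greedy nested base-pair extraction from a pairing-probability
    matrix: accept pairs by descending probability, skipping conflicts and
    crossings."""
    ss = np.asarray(ss, float)
    L = ss.shape[0]
    iu, ju = np.triu_indices(L, min_loop + 1)
    probs = ss[iu, ju]
    order = np.argsort(-probs)
    chosen: list[tuple[int, int]] = []
    used = np.zeros(L, bool)
    for t in order:
        if probs[t] <= threshold:
            break
        i, j = int(iu[t]), int(ju[t])
        if used[i] or used[j]:
            continue
        if any(a < i < b < j or i < a < j < b for a, b in chosen):
            continue
        chosen.append((i, j))
        used[i] = used[j] = True
    return sorted(chosen)


# ----------------------------------------------------------------------
# energy terms and analytic gradients

def _dihedral_val_grad(p0, p1, p2, p3):
    """Dihedrals (degrees, matching geometry.dihedral) and gradients
    (degrees per Angstrom) w.r.t. the four atom sets, vectorized (m, 3)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=-1)
    m = np.cross(n1, b2 / b2n[:, None])
    x = (n1 * n2).sum(-1)
    y = (m * n2).sum(-1)
    phi = np.degrees(np.arctan2(y, x))
    phi = np.where(phi >= 180.0, phi - 360.0, phi)
    n1sq = (n1 * n1).sum(-1)
    n2sq = (n2 * n2).sum(-1)
    # signs match the atan2 convention of geometry.dihedral
    g0 = (b2n / np.maximum(n1sq, 1e-12))[:, None] * n1
    g3 = -(b2n / np.maximum(n2sq, 1e-12))[:, None] * n2
    c12 = ((b1 * b2).sum(-1) / np.maximum(b2n ** 2, 1e-12))[:, None]
    c32 = ((b3 * b2).sum(-1) / np.maximum(b2n ** 2, 1e-12))[:, None]
    g1 = -(1.0 + c12) * g0 + c32 * g3
    g2 = -(g0 + g1 + g3)
    f = 180.0 / np.pi
    return phi, g0 * f, g1 * f, g2 * f, g3 * f


def _angle_val_grad(p0, p1, p2):
    """Planar angles (degrees) and gradients (degrees/Angstrom)."""
    u = p0 - p1
    v = p2 - p1
    un = np.linalg.norm(u, axis=-1)
    vn = np.linalg.norm(v, axis=-1)
    uh = u / un[:, None]
    vh = v / vn[:, None]
    c = np.clip((uh * vh).sum(-1), -1.0, 1.0)
    theta = np.degrees(np.arccos(c))
    s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
    g0 = (c[:, None] * uh - vh) / (un * s)[:, None]
    g2 = (c[:, None] * vh - uh) / (vn * s)[:, None]
    g1 = -(g0 + g2)
    f = 180.0 / np.pi
    return theta, g0 * f, g1 * f, g2 * f


# ideal internal geometry, measured from the A-form template
def _ideal_internal():
    a0, _ = helix_pair_coords(0)
    a1, _ = helix_pair_coords(1)
    bonds = {
        "P-C4": np.linalg.norm(a0[1] - a0[0]),
        "C4-C1": np.linalg.norm(a0[2] - a0[1]),
        "C1-N": np.linalg.norm(a0[3] - a0[2]),
        "C4-P+": np.linalg.norm(a1[0] - a0[1]),
    }

    def ang(p, q, r):
        u, v = p - q, r - q
        return float(np.degrees(np.arccos(
            np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))))

    angles = {
        "P-C4-C1": ang(a0[0], a0[1], a0[2]),
        "C4-C1-N": ang(a0[1], a0[2], a0[3]),
        "P-C4-P+": ang(a0[0], a0[1], a1[0]),
        "C4-P+-C4+": ang(a0[1], a1[0], a1[1]),
    }
    return bonds, angles


_IDEAL_BONDS, _IDEAL_ANGLES = _ideal_internal()
_KBOND = 10.0       # kcal-like units per A^2
_KANGLE = 0.003     # per deg^2 (soft; loops deviate from helix ideals)
_KREP = 10.0        # quartic soft-sphere prefactor
_REP_CUT = 3.2      # A
# Sigmoidal contact well: centred just outside the 8 A contact
# definition with a sharp edge, so pairs already in contact sit on the
# flat floor (no inward over-compaction) while separated pairs are pulled
# back across the boundary.
_CONTACT_D0 = 8.75  # A, centre of the sigmoidal contact well
_CONTACT_ALPHA = 0.35


class _EnergyModel:
    """Callable total energy + gradient on flat coordinates."""

    def __init__(self, restraints: RestraintSet, weights: EnergyWeights,
                 repulsion_scale: float = 1.0, tether=None,
                 tether_k: float = 0.0, ori_scale: float = 1.0):
        self.r = restraints
        self.w = weights
        self.rep = repulsion_scale
        self.ori_scale = ori_scale
        self.tether = tether
        self.tether_k = tether_k

    # -- individual terms ------------------------------------------------
    def _dist_term(self, xyz, grad):
        E = 0.0
        for k, ch in enumerate(self.r.dist):
            if ch is None or len(ch.idx_i) == 0:
                continue
            a, b = DIST_PAIRS[k]
            vec = xyz[ch.idx_i, a] - xyz[ch.idx_j, b]
            d = np.linalg.norm(vec, axis=-1)
            u, du = ch.spline(d)
            E += u.sum()
            if grad is not None:
                gv = (du / np.maximum(d, 1e-9))[:, None] * vec
                np.add.at(grad, (ch.idx_i, a), gv)
                np.add.at(grad, (ch.idx_j, b), -gv)
        return E

    _ORI2D_ATOMS = (
        # (atom indices of i..., atom indices of j...) per channel; see
        # the geometry module for the quadruple definitions
        ((2, 3), (3, 2)),      # omega: C1'i Ni Nj C1'j
        ((1, 2, 3), (3,)),     # theta_a: C4'i C1'i Ni Nj
        ((0, 1, 2), (3,)),     # theta_b: Pi C4'i C1'i Nj
        ((2, 3), (3,)),        # phi_a: C1'i Ni Nj
        ((1, 3), (3,)),        # phi_b: C4'i Ni Nj
    )

    def _ori2d_term(self, xyz, grad):
        E = 0.0
        for k, ch in enumerate(self.r.ori2d):
            if ch is None or len(ch.idx_i) == 0:
                continue
            ai, aj = self._ORI2D_ATOMS[k]
            pts = [xyz[ch.idx_i, a] for a in ai] + \
                  [xyz[ch.idx_j, a] for a in aj]
            owners = [(ch.idx_i, a) for a in ai] + \
                     [(ch.idx_j, a) for a in aj]
            if len(pts) == 4:
                val, *gs = _dihedral_val_grad(*pts)
            else:
                val, *gs = _angle_val_grad(*pts)
            u, du = ch.spline(val)
            E += u.sum()
            if grad is not None:
                for (own, a), g in zip(owners, gs):
                    np.add.at(grad, (own, a), du[:, None] * g)
        return E

    def _ori1d_term(self, xyz, grad):
        # torsion atom lists per channel: (nt offset, atom index) x 4
        specs = (
            ((-1, 1), (0, 0), (0, 1), (1, 0)),   # eta
            ((0, 0), (0, 1), (1, 0), (1, 1)),    # theta
            ((0, 0), (0, 1), (0, 2), (0, 3)),    # chi
            ((0, 2), (0, 1), (1, 0), (1, 1)),    # zeta
        )
        E = 0.0
        L = self.r.L
        for g_, ch in enumerate(self.r.ori1d):
            if ch is None or len(ch.idx_i) == 0:
                continue
            spec = specs[g_]
            idx = ch.idx_i
            ok = np.ones(len(idx), bool)
            for off, _ in spec:
                ok &= (idx + off >= 0) & (idx + off < L)
            idx = idx[ok]
            if len(idx) == 0:
                continue
            pts = [xyz[idx + off, a] for off, a in spec]
            val, *gs = _dihedral_val_grad(*pts)
            u, du = _eval_rows(ch.spline, np.nonzero(ok)[0], val)
            E += u.sum()
            if grad is not None:
                for (off, a), g in zip(spec, gs):
                    np.add.at(grad, (idx + off, a), du[:, None] * g)
        return E

    def _contact_term(self, xyz, grad):
        # sigmoidal well on a softmin (smooth minimum) of the 16 coarse
        # atom-pair distances; the softmin keeps the gradient continuous
        # when the closest atom pair changes
        ch = self.r.contact
        if len(ch.idx_i) == 0:
            return 0.0
        from scipy.special import expit
        tau = 0.5
        ci = xyz[ch.idx_i]            # (m,4,3)
        cj = xyz[ch.idx_j]
        diff = ci[:, :, None, :] - cj[:, None, :, :]
        d = np.linalg.norm(diff, axis=-1).reshape(len(ci), 16)
        dmin = d.min(axis=1, keepdims=True)
        w = np.exp(-(d - dmin) / tau)
        wsum = w.sum(axis=1, keepdims=True)
        dsoft = (dmin - tau * np.log(wsum))[:, 0]
        s = expit((_CONTACT_D0 - dsoft) / _CONTACT_ALPHA)
        E = float((ch.strength * s).sum())
        if grad is not None:
            ds = -s * (1 - s) / _CONTACT_ALPHA    # dE/d(dsoft) per unit
            coeff = (ch.strength * ds)[:, None]
            wn = (w / wsum)                       # d dsoft / d d_k
            gd = (coeff * wn).reshape(len(ci), 4, 4)
            unit = diff / np.maximum(
                np.linalg.norm(diff, axis=-1, keepdims=True), 1e-9)
            gv = gd[..., None] * unit             # (m,4,4,3)
            np.add.at(grad, (ch.idx_i[:, None], np.arange(4)[None, :]),
                      gv.sum(axis=2))
            np.add.at(grad, (ch.idx_j[:, None], np.arange(4)[None, :]),
                      -gv.sum(axis=1))
        return E

    def _internal_term(self, xyz, grad):
        L = self.r.L
        E = 0.0
        # bonds
        bond_specs = (
            ("P-C4", (0, 0), (0, 1)), ("C4-C1", (0, 1), (0, 2)),
            ("C1-N", (0, 2), (0, 3)), ("C4-P+", (0, 1), (1, 0)),
        )
        for name, (o1, a1), (o2, a2) in bond_specs:
            n = L - max(o1, o2)
            i = np.arange(n)
            vec = xyz[i + o1, a1] - xyz[i + o2, a2]
            d = np.linalg.norm(vec, axis=-1)
            dd = d - _IDEAL_BONDS[name]
            E += _KBOND * (dd ** 2).sum()
            if grad is not None:
                gv = (2 * _KBOND * dd / np.maximum(d, 1e-9))[:, None] * vec
                np.add.at(grad, (i + o1, a1), gv)
                np.add.at(grad, (i + o2, a2), -gv)
        # angles
        angle_specs = (
            ("P-C4-C1", (0, 0), (0, 1), (0, 2)),
            ("C4-C1-N", (0, 1), (0, 2), (0, 3)),
            ("P-C4-P+", (0, 0), (0, 1), (1, 0)),
            ("C4-P+-C4+", (0, 1), (1, 0), (1, 1)),
        )
        for name, *spec in angle_specs:
            n = L - max(o for o, _ in spec)
            i = np.arange(n)
            pts = [xyz[i + o, a] for o, a in spec]
            val, *gs = _angle_val_grad(*pts)
            dv = val - _IDEAL_ANGLES[name]
            E += _KANGLE * (dv ** 2).sum()
            if grad is not None:
                for (o, a), g in zip(spec, gs):
                    np.add.at(grad, (i + o, a),
                              (2 * _KANGLE * dv)[:, None] * g)
        # soft-sphere repulsion (quartic below the cutoff, |i-j| >= 2)
        rep = self.rep
        if rep > 0:
            flat = xyz.reshape(L * 4, 3)
            diff = flat[:, None] - flat[None, :]
            d = np.linalg.norm(diff, axis=-1)
            nt = np.repeat(np.arange(L), 4)
            sep_ok = np.abs(nt[:, None] - nt[None, :]) >= 2
            tri = np.triu(np.ones((L * 4, L * 4), bool), 1)
            mask = sep_ok & tri & (d < _REP_CUT)
            if mask.any():
                ii, jj = np.nonzero(mask)
                dd = _REP_CUT - d[ii, jj]
                E += rep * _KREP * (dd ** 4).sum()
                if grad is not None:
                    coeff = -4 * rep * _KREP * dd ** 3 / np.maximum(
                        d[ii, jj], 1e-9)
                    gv = coeff[:, None] * diff[ii, jj]
                    gflat = np.zeros_like(flat)
                    np.add.at(gflat, ii, gv)
                    np.add.at(gflat, jj, -gv)
                    grad += gflat.reshape(L, 4, 3)
        return E

    # -- assembly ---------------------------------------------------------
    def terms(self, xyz, grad_terms=None):
        """Per-term energies; if ``grad_terms`` is a dict, fills weighted
        gradients into grad_terms['total']."""
        want = grad_terms is not None
        w = self.w
        L = self.r.L
        shapes = xyz.shape
        g_dist = np.zeros(shapes) if want else None
        g_o2 = np.zeros(shapes) if want else None
        g_o1 = np.zeros(shapes) if want else None
        g_c = np.zeros(shapes) if want else None
        g_i = np.zeros(shapes) if want else None
        e_dist = self._dist_term(xyz, g_dist)
        # orientation and contact terms share the late-stage ramp: both
        # refine detail and distort topology formation if applied before
        # the distance restraints have set the global fold
        os = self.ori_scale
        e_o2 = self._ori2d_term(xyz, g_o2) if os > 0 else 0.0
        e_o1 = self._ori1d_term(xyz, g_o1) if os > 0 else 0.0
        e_c = self._contact_term(xyz, g_c) if os > 0 else 0.0
        e_i = self._internal_term(xyz, g_i)
        total = combine_energy(e_dist, os * e_o2, os * e_o1, os * e_c,
                               e_i, L, w)
        if want:
            gt = (w.w_dist * g_dist
                  + w.w_ori * os * (g_o2 + 0.5 * L * g_o1)
                  + w.w_cont * os * g_c + w.w_internal * g_i)
            if self.tether is not None and self.tether_k > 0:
                dvec = xyz - self.tether
                total += self.tether_k * (dvec ** 2).sum()
                gt += 2 * self.tether_k * dvec
            grad_terms["total"] = gt
        elif self.tether is not None and self.tether_k > 0:
            total += self.tether_k * ((xyz - self.tether) ** 2).sum()
        return {"total": total, "dist": e_dist, "ori2d": e_o2,
                "ori1d": e_o1, "cont": e_c, "internal": e_i}

    def __call__(self, xflat: np.ndarray):
        xyz = xflat.reshape(self.r.L, 4, 3)
        gt: dict = {}
        t = self.terms(xyz, gt)
        return t["total"], gt["total"].ravel()


def _smoothed_restraints(rs: RestraintSet, sigma_bins: float
                         ) -> RestraintSet:
    """Copy of a restraint set with Gaussian-smoothed potential tables
    (wrapped for periodic channels); sigma 0 returns the set unchanged."""
    if sigma_bins <= 0:
        return rs
    from scipy.ndimage import gaussian_filter1d

    def smooth_channel(ch):
        if ch is None or len(ch.idx_i) == 0:
            return ch
        sp = ch.spline
        mode = "wrap" if sp.periodic else "nearest"
        V = gaussian_filter1d(sp.V, sigma_bins, axis=1, mode=mode)
        return _PairChannel(ch.idx_i, ch.idx_j, _Spline(
            V, sp.x0, sp.dx, sp.periodic, sp.left_slope))

    return RestraintSet(
        L=rs.L, dist=[smooth_channel(c) for c in rs.dist],
        ori2d=[smooth_channel(c) for c in rs.ori2d],
        ori1d=[smooth_channel(c) for c in rs.ori1d],
        contact=rs.contact, config=rs.config)


def _eval_rows(sp: _Spline, rows: np.ndarray, x: np.ndarray):
    """Evaluate a subset of a spline's table rows."""
    sub = _Spline.__new__(_Spline)
    sub.V = sp.V[rows]
    sub.M = sp.M[rows]
    sub.x0, sub.dx = sp.x0, sp.dx
    sub.periodic = sp.periodic
    sub.left_slope = sp.left_slope
    return sub(x)


def energy(structure: CoarseStructure, restraints: RestraintSet,
           weights: EnergyWeights | None = None,
           repulsion_scale: float = 1.0):
    """(total, breakdown dict) of a structure under a restraint set."""
    if len(structure) != restraints.L:
        raise ValueError("structure length does not match restraints")
    if not np.isfinite(structure.coords).all():
        raise FloatingPointError("non-finite coordinates")
    model = _EnergyModel(restraints, weights or EnergyWeights(),
                         repulsion_scale)
    t = model.terms(structure.coords)
    return t["total"], t


def internal_energy(structure: CoarseStructure,
                    repulsion_scale: float = 1.0) -> float:
    """Simplified physics term alone (bonded + soft-sphere repulsion)."""
    empty = RestraintSet(
        L=len(structure), dist=[None] * 5, ori2d=[None] * 5,
        ori1d=[None] * 4,
        contact=_ContactChannel(np.array([], int), np.array([], int),
                                np.array([])),
        config=RestraintConfig())
    model = _EnergyModel(empty, EnergyWeights(), repulsion_scale)
    return float(model._internal_term(structure.coords, None))


# ----------------------------------------------------------------------
# decoys

@dataclass
class Decoy:
    structure: CoarseStructure
    energy: float
    breakdown: dict
    converged: bool = True


@dataclass
class FoldResult:
    best: Decoy
    decoys: list
    restraints: RestraintSet


def generate_starts(sequence: str, ss: np.ndarray, n: int = 20,
                    seed: int = 0) -> list:
    """``n`` distinct starting structures: probable stems (pair probability
    > 0.5, greedily nested) as ideal A-form helices, the rest as seeded
    self-avoiding walks."""
    if len(sequence) < 2:
        raise ValueError("need at least 2 nucleotides")
    pairs = nested_stems_from_matrix(np.asarray(ss, float))
    out = []
    k = 0
    attempt = 0
    while len(out) < n and attempt < 10 * n:
        try:
            out.append(build_from_pairs(sequence, pairs,
                                        seed=seed * 7919 + attempt))
        except Exception:
            pass
        attempt += 1
    if len(out) < n:
        raise RuntimeError(f"only {len(out)}/{n} starts could be built")
    return out


def minimize(start: CoarseStructure, restraints: RestraintSet,
             weights: EnergyWeights | None = None,
             opts: MinimizeOptions | None = None) -> Decoy:
    """Staged L-BFGS minimization of the total energy.

    Stages ramp the soft-sphere repulsion up late so restraints shape the
    fold before sterics harden.  The returned decoy is the best full-energy
    iterate seen (never worse than the start)."""
    weights = weights or EnergyWeights()
    opts = opts or MinimizeOptions()
    full = _EnergyModel(restraints, weights, repulsion_scale=1.0)
    x = start.coords.ravel().copy()
    candidates = [x.copy()]
    converged = True
    for rep, smooth, *rest in opts.stages:
        ori = rest[0] if rest else 1.0
        rset = _smoothed_restraints(restraints, smooth)
        model = _EnergyModel(rset, weights, repulsion_scale=rep,
                             ori_scale=ori)
        res = _scipy_minimize(
            model, x, jac=True, method="L-BFGS-B",
            options={"maxiter": opts.maxiter, "maxcor": opts.lbfgs_memory,
                     "ftol": opts.ftol})
        x = res.x
        candidates.append(x.copy())
        if not res.success and "ITERATIONS" not in str(res.message).upper():
            converged = False
    energies = [full(c)[0] for c in candidates]
    best = int(np.argmin(energies))
    if best == 0:
        converged = False
        logger.warning("minimization did not improve on the start")
    xyz = candidates[best].reshape(restraints.L, 4, 3)
    structure = CoarseStructure(start.sequence, xyz)
    total, terms = energy(structure, restraints, weights)
    return Decoy(structure=structure, energy=float(total), breakdown=terms,
                 converged=converged)


def refine_clashes(decoy: Decoy, restraints: RestraintSet,
                   weights: EnergyWeights | None = None,
                   maxiter: int = 100) -> Decoy:
    """Clash-removal step: short minimization with the repulsion weight
    scaled x10, the restraint terms frozen at their current values, and a
    positional tether bounding the move (< 2 A RMSD)."""
    weights = weights or EnergyWeights()
    before = clash_count(decoy.structure)
    if before == 0:
        return decoy
    empty = RestraintSet(
        L=restraints.L, dist=[None] * 5, ori2d=[None] * 5,
        ori1d=[None] * 4,
        contact=_ContactChannel(np.array([], int), np.array([], int),
                                np.array([])),
        config=restraints.config)
    model = _EnergyModel(empty, weights, repulsion_scale=10.0,
                         tether=decoy.structure.coords, tether_k=0.05)
    res = _scipy_minimize(model, decoy.structure.coords.ravel(), jac=True,
                          method="L-BFGS-B", options={"maxiter": maxiter})
    xyz = res.x.reshape(restraints.L, 4, 3)
    refined = CoarseStructure(decoy.structure.sequence, xyz)
    if clash_count(refined) > before:
        return decoy
    total, terms = energy(refined, restraints, weights)
    return Decoy(structure=refined, energy=float(total), breakdown=terms,
                 converged=decoy.converged)


def fold(pred: GeometryPrediction, sequence: str, ss: np.ndarray,
         n_starts: int = 20, seed: int = 0,
         weights: EnergyWeights | None = None,
         cfg: RestraintConfig | None = None,
         opts: MinimizeOptions | None = None,
         reference=None) -> FoldResult:
    """Full folding protocol: restraints, 20 starts, staged minimization,
    clash refinement, lowest-energy selection."""
    if pred.L != len(sequence) or np.asarray(ss).shape[0] != len(sequence):
        raise ValueError("prediction / sequence / secondary structure "
                         "lengths disagree")
    weights = weights or EnergyWeights()
    restraints = potentials_from_prediction(pred, cfg, reference=reference)
    starts = generate_starts(sequence, ss, n=n_starts, seed=seed)
    decoys = []
    for st in starts:
        d = minimize(st, restraints, weights, opts)
        d = refine_clashes(d, restraints, weights)
        decoys.append(d)
    best = int(np.argmin([d.energy for d in decoys]))
    return FoldResult(best=decoys[best], decoys=decoys,
                      restraints=restraints)
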