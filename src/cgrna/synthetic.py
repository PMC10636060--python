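"""Synthetic test substrate: toy structures, oracle predictions, MSAs.

The generator emulates the inputs and intermediate products of the real
pipeline at desk scale:

* :func:`make_toy_structure` builds a coarse-grained 3D structure from a
  sequence and a nested dot-bracket: base-paired regions are placed as ideal
  A-form helices (rise 2.81 A, twist 32.7 deg/bp), unpaired regions as
  seeded self-avoiding walks steered to close the chain, with a steric
  floor of 3.2 A between non-bonded coarse atoms.
* :func:`oracle_prediction` converts a known structure into geometry
  probability distributions of controllable sharpness and noise — the
  stand-in for a trained network's output.
* :func:`synthetic_msa` emits alignments whose paired columns covary
  compensatorily (Watson-Crick / G-U maintained), the signal the coupling
  features are designed to pick up.
* :func:`make_dataset` bundles everything into training samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import features as _features
from .evalio import clash_count, dotbracket_to_pairs, pairs_to_matrix
from .geometry import (BinSpec, CoarseStructure, ORI2D_KIND, GeometryLabels,
                       compute_geometries, discretize)

__all__ = [
    "ToySpec", "OracleConfig", "GenerationError", "make_toy_structure",
    "build_from_pairs", "oracle_prediction", "synthetic_msa", "make_dataset",
    "random_spec", "A_FORM_RISE", "A_FORM_TWIST",
]

A_FORM_RISE = 2.81    # A per base pair
A_FORM_TWIST = 32.7   # degrees per base pair
_STEP = 5.8           # target consecutive P-P distance, A
_MIN_SEP = 3.25       # builder steric floor (above the 3.2 A clash cutoff)

_WC_GU = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
          ("G", "U"), ("U", "G")}
_PAIR_CHOICES = sorted(_WC_GU)


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ToySpec:
    """Sequence + nested dot-bracket + seed defining one toy RNA."""

    sequence: str
    dotbracket: str
    seed: int = 0

    def __post_init__(self):
        if len(self.sequence) != len(self.dotbracket):
            raise ValueError("sequence/structure length mismatch")
        pairs = dotbracket_to_pairs(self.dotbracket)  # raises on pseudoknots
        for i, j in pairs:
            if (self.sequence[i], self.sequence[j]) not in _WC_GU:
                raise ValueError(
                    f"pair ({i},{j}) {self.sequence[i]}-{self.sequence[j]} "
                    "is not Watson-Crick or G-U")

    @property
    def pairs(self):
        return dotbracket_to_pairs(self.dotbracket)


@dataclass(frozen=True)
class OracleConfig:
    """Controls of the synthetic geometry-prediction oracle.

    ``sigma_dist`` / ``sigma_ang``: Gaussian smearing of the true value
    (A / degrees); ``noise``: probability that a pair's (or nucleotide's)
    distributions are replaced by uniform ones.
    """

    sigma_dist: float = 1.0
    sigma_ang: float = 15.0
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.sigma_dist <= 0 or self.sigma_ang <= 0:
            raise ValueError("sharpness sigmas must be positive")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must be in [0, 1]")


# ----------------------------------------------------------------------
# ideal A-form template (coarse atoms, pair frame: helix axis = z,
# dyad axis = x; strand B = 180 deg rotation of strand A about x)

def _template() -> tuple[np.ndarray, np.ndarray]:
    c1 = np.array([7.95, 5.20, 0.0])
    n = c1 + 1.48 * np.array([0.0, -1.0, 0.0])
    ang = np.radians(45.0)
    c4 = np.array([9.4 * np.cos(ang), 9.4 * np.sin(ang), -0.9])
    ang = np.radians(55.0)
    p = np.array([8.9 * np.cos(ang), 8.9 * np.sin(ang), -2.4])
    A = np.stack([p, c4, c1, n])
    B = A * np.array([1.0, -1.0, -1.0])
    return A, B


_TPL_A, _TPL_B = _template()


def _rz(deg: float) -> np.ndarray:
    r = np.radians(deg)
    c, s = np.cos(r), np.sin(r)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def helix_pair_coords(level: int) -> tuple[np.ndarray, np.ndarray]:
    """Template coordinates of the two nucleotides of pair ``level``."""
    R = _rz(A_FORM_TWIST * level)
    dz = np.array([0.0, 0.0, A_FORM_RISE * level])
    return _TPL_A @ R.T + dz, _TPL_B @ R.T + dz


def _nt_frame_offsets() -> np.ndarray:
    """Atom offsets from P in a local frame (x = chain direction)."""
    a0, _ = helix_pair_coords(0)
    a1, _ = helix_pair_coords(1)
    x = a1[0] - a0[0]
    x /= np.linalg.norm(x)
    ref = a0[1] - a0[0]
    y = ref - (ref @ x) * x
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    basis = np.stack([x, y, z])
    return (a0 - a0[0]) @ basis.T


_NT_OFFSETS = _nt_frame_offsets()


def _rand_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _rand_rotation(rng) -> np.ndarray:
    """Uniform random rotation matrix (QR of a Gaussian matrix)."""
    M = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(M)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] *= -1
    return Q


def _align_rotation(v_from: np.ndarray, v_to: np.ndarray) -> np.ndarray:
    """Rotation taking direction v_from to direction v_to."""
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    v = np.cross(a, b)
    c = float(a @ b)
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # 180 degrees: rotate about any perpendicular axis
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 1.0, 0.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1 + c)


# ----------------------------------------------------------------------
# sequential builder

class _Builder:
    def __init__(self, L: int, pairs, rng):
        self.L = L
        self.rng = rng
        self.coords = np.full((L, 4, 3), np.nan)
        self.placed = np.zeros(L, bool)
        self.pair_of = np.full(L, -1, int)
        for i, j in pairs:
            self.pair_of[i] = j
            self.pair_of[j] = i

    # -- steric checking -------------------------------------------------
    def _clashes(self, nts: list[int], coords: np.ndarray) -> bool:
        """Would placing ``coords`` ((k,4,3)) for nucleotides ``nts``
        violate the steric floor against already-placed, non-adjacent
        nucleotides?"""
        placed_idx = np.nonzero(self.placed)[0]
        if len(placed_idx) == 0:
            return False
        pc = self.coords[placed_idx].reshape(-1, 3)
        for nt, c in zip(nts, coords):
            d = np.linalg.norm(pc[None, :, :] - c[:, None, :], axis=-1)
            d = d.reshape(4, len(placed_idx), 4)
            dmin = d.min(axis=(0, 2))
            ok = (dmin >= _MIN_SEP) | (np.abs(placed_idx - nt) <= 1)
            if not ok.all():
                return True
        return False

    def _put(self, nt: int, coords: np.ndarray):
        self.coords[nt] = coords
        self.placed[nt] = True

    # -- nucleotide placement from a P position and direction -------------
    def _nt_coords(self, p_pos, direction, up_hint) -> np.ndarray:
        x = direction / np.linalg.norm(direction)
        y = up_hint - (up_hint @ x) * x
        ny = np.linalg.norm(y)
        if ny < 1e-6:
            y = _rand_unit(self.rng)
            y -= (y @ x) * x
            ny = np.linalg.norm(y)
        y /= ny
        z = np.cross(x, y)
        basis = np.stack([x, y, z])
        return p_pos + _NT_OFFSETS @ basis

    # -- region construction ----------------------------------------------
    def build(self):
        self._region(0, self.L - 1, entry=None, target=None)
        return self.coords

    def _elements(self, a: int, b: int):
        """Scan region [a, b] into unpaired positions and stems."""
        out = []
        s = a
        while s <= b:
            e = self.pair_of[s]
            if e == -1:
                out.append(("nt", s, s))
                s += 1
            else:
                m = 1
                while (s + m <= b and self.pair_of[s + m] == e - m
                       and s + m < e - m):
                    m += 1
                out.append(("stem", s, m))
                s = e + 1
        return out

    def _steps_capacity(self, elements, k: int) -> float:
        """Rough reach (A) of elements k..end plus the closure hop."""
        cap = _STEP
        for kind, _, info in elements[k:]:
            cap += _STEP if kind == "nt" else 2.2 * _STEP
        return cap

    def _region(self, a: int, b: int, entry, target):
        """Place nucleotides of [a, b].

        ``entry``: (position, direction, up) of the preceding chain end, or
        None at the 5' terminus.  ``target``: P position the chain must
        reach after the last nucleotide (strand closure), or None.
        """
        rng = self.rng
        if entry is None:
            pos = np.zeros(3)
            direction = np.array([1.0, 0.0, 0.0])
            up = np.array([0.0, 0.0, 1.0])
        else:
            pos, direction, up = entry
        elements = self._elements(a, b) if a <= b else []

        for k, (kind, s, info) in enumerate(elements):
            if kind == "nt":
                pos, direction, up = self._walk_nt(
                    s, pos, direction, up, target,
                    self._steps_capacity(elements, k + 1), entry is None
                    and k == 0)
            else:
                pos, direction, up = self._place_stem(
                    s, info, pos, direction, up, target,
                    self._steps_capacity(elements, k + 1),
                    first=(entry is None and k == 0))
        # closure check
        if target is not None:
            gap = np.linalg.norm(pos - target)
            if not (3.0 < gap < 9.0):
                raise GenerationError(
                    f"loop closure failed: gap {gap:.2f} A")

    def _steer(self, pos, direction, up, target, capacity):
        rng = self.rng
        if target is None:
            d = direction + 0.9 * _rand_unit(rng)
        else:
            to_t = target - pos
            dist = np.linalg.norm(to_t)
            # weight on the target direction grows as slack vanishes
            need = dist / max(capacity, 1e-9)
            if need > 1.15:
                raise GenerationError("target out of reach")
            w = float(np.clip(1.6 * need - 0.3, 0.05, 0.97))
            wander = direction + 0.9 * _rand_unit(rng)
            wander /= np.linalg.norm(wander)
            d = w * to_t / max(dist, 1e-9) + (1 - w) * wander
        d /= np.linalg.norm(d)
        return d

    def _closure_point(self, pos, target):
        """A point one backbone step from ``pos`` and a valid closure hop
        (4.5-7.5 A) from ``target``, or None if geometry forbids it."""
        rng = self.rng
        dvec = target - pos
        D = np.linalg.norm(dvec)
        r2 = rng.uniform(4.5, 7.5)
        if D > _STEP + r2 - 0.05 or D < abs(_STEP - r2) + 0.05:
            return None
        dh = dvec / D
        a = (_STEP ** 2 - r2 ** 2 + D ** 2) / (2 * D)
        h2 = _STEP ** 2 - a ** 2
        if h2 <= 0:
            return None
        u = _rand_unit(rng)
        u -= (u @ dh) * dh
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            return None
        return pos + a * dh + np.sqrt(h2) * (u / nu)

    def _walk_nt(self, s, pos, direction, up, target, capacity, first):
        rng = self.rng
        last = target is not None and capacity <= _STEP * 1.01
        for _ in range(40):
            if first:
                new_pos = pos
                d = direction
            else:
                new_pos = None
                if last:
                    new_pos = self._closure_point(pos, target)
                    if new_pos is not None:
                        d = new_pos - pos
                        d /= np.linalg.norm(d)
                if new_pos is None:
                    d = self._steer(pos, direction, up, target, capacity)
                    new_pos = pos + _STEP * d
            up_j = up + 0.4 * rng.normal(size=3)
            coords = self._nt_coords(new_pos, d, up_j)
            if not self._clashes([s], coords[None]):
                self._put(s, coords)
                return new_pos, d, np.cross(d, np.cross(up_j, d))
            first = False
        raise GenerationError(f"cannot place nucleotide {s}")

    def _place_stem(self, s, m, pos, direction, up, target, capacity,
                    first=False):
        rng = self.rng
        e = self.pair_of[s]
        # template geometry of the stem
        tA = np.zeros((m, 4, 3))
        tB = np.zeros((m, 4, 3))
        for k in range(m):
            tA[k], tB[k] = helix_pair_coords(k)
        origin = tA[0, 0]          # P of the first strand-A nucleotide
        exit_vec = tB[0, 0] - origin   # to P of the closing strand-B nt

        for attempt in range(60):
            if first:
                anchor = pos
                step_dir = direction
            else:
                step_dir = self._steer(pos, direction, up, target,
                                       capacity + 2.2 * _STEP)
                anchor = pos + _STEP * step_dir
            if target is not None and attempt % 2 == 0:
                # aim the stem exit at the remaining chain's goal, with a
                # random spin about the exit axis
                goal = target - anchor
                R0 = _align_rotation(exit_vec, goal)
                ax = goal / max(np.linalg.norm(goal), 1e-9)
                th = rng.uniform(0, 2 * np.pi)
                K = np.array([[0, -ax[2], ax[1]], [ax[2], 0, -ax[0]],
                              [-ax[1], ax[0], 0]])
                R = (np.eye(3) + np.sin(th) * K
                     + (1 - np.cos(th)) * K @ K) @ R0
            else:
                R = _rand_rotation(rng)
            A = (tA - origin) @ R.T + anchor
            B = (tB - origin) @ R.T + anchor
            nts = list(range(s, s + m)) + list(range(e - m + 1, e + 1))
            coords = np.concatenate([A, B[::-1]], axis=0)
            # intra-stem connectivity is ideal by construction; check sterics
            if self._clashes(nts, coords):
                continue
            # connectivity of the closing side will be validated by the
            # enclosed region's closure test / next element's step
            for nt, c in zip(nts, coords):
                self._put(nt, c)
            # recurse into the enclosed region
            inner_a, inner_b = s + m, e - m
            entry_pos = A[m - 1, 0]
            helix_axis = R @ np.array([0.0, 0.0, 1.0])
            entry = (entry_pos, helix_axis,
                     np.cross(helix_axis, _rand_unit(rng)))
            try:
                self._region(inner_a, inner_b, entry, B[m - 1, 0])
            except GenerationError:
                # roll back the stem and retry with a new orientation
                for nt in nts:
                    self.placed[nt] = False
                    self.coords[nt] = np.nan
                for nt in range(inner_a, inner_b + 1):
                    self.placed[nt] = False
                    self.coords[nt] = np.nan
                continue
            exit_pos = B[0, 0]
            exit_dir = (exit_pos - anchor)
            exit_dir /= np.linalg.norm(exit_dir)
            return exit_pos, exit_dir, np.cross(exit_dir, _rand_unit(rng))
        raise GenerationError(f"cannot place stem at {s}")


def build_from_pairs(sequence: str, pairs, seed: int = 0,
                     max_tries: int = 80) -> CoarseStructure:
    """Build a coarse structure for ``sequence`` with the given nested
    base pairs; raises :class:`GenerationError` if no clash-free,
    chain-connected embedding is found."""
    L = len(sequence)
    pairs = sorted(_validate_nested(pairs, L))
    for attempt in range(max_tries):
        rng = np.random.default_rng(
            np.random.SeedSequence([seed & 0x7FFFFFFF, attempt]))
        builder = _Builder(L, pairs, rng)
        try:
            coords = builder.build()
        except GenerationError:
            continue
        structure = CoarseStructure(sequence, coords)
        pp = np.linalg.norm(np.diff(coords[:, 0, :], axis=0), axis=1)
        if ((pp <= 3.0) | (pp >= 9.0)).any():
            continue
        if clash_count(structure) > 0:
            continue
        return structure
    raise GenerationError(
        f"no valid embedding found in {max_tries} attempts")


def _validate_nested(pairs, L: int):
    pairs = [(min(i, j), max(i, j)) for i, j in pairs]
    seen = set()
    for i, j in pairs:
        if not (0 <= i < j < L):
            raise ValueError(f"pair ({i},{j}) out of range")
        if i in seen or j in seen:
            raise ValueError(f"position in multiple pairs: ({i},{j})")
        seen.update((i, j))
    for (i, j) in pairs:
        for (k, l) in pairs:
            if i < k < j < l:
                raise GenerationError(
                    f"pseudoknotted pairs ({i},{j}) / ({k},{l}) unsupported")
    return pairs


def make_toy_structure(spec: ToySpec) -> CoarseStructure:
    """Coarse 3D structure realizing a toy spec (seeded, deterministic)."""
    return build_from_pairs(spec.sequence, spec.pairs, seed=spec.seed)


# ----------------------------------------------------------------------
# oracle geometry predictions

def _gauss_bin_mass(true_val, edges, sigma):
    """Gaussian probability mass per bin (exact CDF differences), so the
    sigma -> 0 limit is a one-hot at the bin containing the true value."""
    from scipy.stats import norm
    z = (edges - true_val[..., None]) / sigma
    cdf = norm.cdf(z)
    return np.diff(cdf, axis=-1)


def _wrapped_gauss_bin_mass(true_val, edges, sigma):
    """Same for periodic (dihedral) bins: mass of the wrapped deviation."""
    from scipy.stats import norm
    width = edges[1] - edges[0]
    lo = (edges[:-1] - true_val[..., None] + 180.0) % 360.0 - 180.0
    z_lo = lo / sigma
    z_hi = (lo + width) / sigma
    return norm.cdf(z_hi) - norm.cdf(z_lo)


def oracle_prediction(truth: CoarseStructure, cfg: OracleConfig,
                      return_noise_mask: bool = False):
    """Geometry distributions smeared around the true geometries.

    With probability ``cfg.noise`` a pair's (nucleotide's) distributions
    are replaced by uniform ones — emulating regions the network cannot
    predict.  Corruption is drawn independently for the distance, 2D
    orientation and contact channel groups.  The contact probability is
    sigmoid(8 - d_min).  With ``return_noise_mask`` the distance-channel
    pair mask and the 1D nucleotide mask are returned alongside.
    """
    from .network import GeometryPrediction  # deferred import

    bins = BinSpec()
    vals = compute_geometries(truth)
    L = len(truth)
    rng = np.random.default_rng(cfg.seed)
    floor = 1e-6

    from scipy.stats import norm

    dist = np.zeros((5, L, L, bins.n_dist_classes))
    horizon = bins.dist_edges[-1]
    for k in range(5):
        d = vals.dist[k]
        w = _gauss_bin_mass(d, bins.dist_edges, cfg.sigma_dist)
        catch = 1.0 - norm.cdf((horizon - d) / cfg.sigma_dist)
        w = np.concatenate([w, catch[..., None]], axis=-1) + floor
        dist[k] = w / w.sum(-1, keepdims=True)

    within = vals.dist[0] < horizon
    ori2d = []
    for k in range(5):
        v = vals.ori2d[k]
        defined = within & ~np.isnan(v)
        vv = np.where(defined, v, 0.0)
        if ORI2D_KIND[k] == "dihedral":
            w = _wrapped_gauss_bin_mass(vv, bins.dihedral_edges,
                                        cfg.sigma_ang)
        else:
            w = _gauss_bin_mass(vv, bins.angle_edges, cfg.sigma_ang)
        extra = np.where(defined, 0.0, 1.0)
        w = np.concatenate([w * defined[..., None], extra[..., None]],
                           axis=-1) + floor
        ori2d.append(w / w.sum(-1, keepdims=True))

    ori1d = np.zeros((4, L, bins.n_ori1d_classes))
    for g in range(4):
        v = vals.ori1d[g]
        defined = ~np.isnan(v)
        w = _wrapped_gauss_bin_mass(np.where(defined, v, 0.0),
                                    bins.dihedral_edges, cfg.sigma_ang)
        w = w * defined[..., None]
        w = np.concatenate([w, (~defined)[..., None].astype(float)],
                           axis=-1) + floor
        ori1d[g] = w / w.sum(-1, keepdims=True)

    # contact probability from the true minimum coarse-atom distance
    flat = truth.coords.reshape(L * 4, 3)
    dat = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
    dmin = dat.reshape(L, 4, L, 4).min(axis=(1, 3))
    contact = 1.0 / (1.0 + np.exp(-(8.0 - dmin)))
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    contact[sep < 2] = 0.0

    # noise: uniform replacement, symmetric over unordered pairs; each
    # channel group (distances, 2D orientations, contacts) is corrupted
    # independently, as each is a separate prediction in the real model
    iu, ju = np.triu_indices(L, 1)

    def draw_pair_mask():
        corrupt_u = rng.random(len(iu)) < cfg.noise
        m = np.zeros((L, L), bool)
        m[iu[corrupt_u], ju[corrupt_u]] = True
        return m | m.T

    pair_mask = draw_pair_mask()          # distances (reported mask)
    ori_mask = draw_pair_mask()
    cont_mask = draw_pair_mask()
    nt_mask = rng.random(L) < cfg.noise
    if pair_mask.any():
        dist[:, pair_mask] = 1.0 / bins.n_dist_classes
    if ori_mask.any():
        for k in range(5):
            ori2d[k][ori_mask] = 1.0 / ori2d[k].shape[-1]
    if cont_mask.any():
        contact[cont_mask] = 0.5
    if nt_mask.any():
        ori1d[:, nt_mask] = 1.0 / bins.n_ori1d_classes

    pred = GeometryPrediction(dist=dist, ori2d=ori2d, ori1d=ori1d,
                              contact=contact)
    if return_noise_mask:
        return pred, pair_mask, nt_mask
    return pred


# ----------------------------------------------------------------------
# synthetic MSAs

_BASES = "ACGU"


def synthetic_msa(sequence: str, dotbracket: str, n: int,
                  mutation_rate: float = 0.2, seed: int = 0,
                  compensatory: float = 0.9, gap_rate: float = 0.02
                  ) -> list[str]:
    """``n`` aligned homolog rows; row 0 is the unmutated query.

    Paired columns mutate together (a random Watson-Crick or G-U pair) with
    probability ``compensatory``, otherwise one side mutates freely —
    producing the covariation signal of real structural alignments.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = np.random.default_rng(seed)
    pairs = dotbracket_to_pairs(dotbracket)
    paired = {i for p in pairs for i in p}
    L = len(sequence)
    rows = [sequence]
    for _ in range(n - 1):
        row = list(sequence)
        for i, j in pairs:
            if rng.random() < mutation_rate:
                if rng.random() < compensatory:
                    a, b = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
                    row[i], row[j] = a, b
                else:
                    row[i] = _BASES[rng.integers(4)]
        for i in range(L):
            if i in paired:
                continue
            if rng.random() < mutation_rate:
                row[i] = _BASES[rng.integers(4)]
            if rng.random() < gap_rate:
                row[i] = "-"
        rows.append("".join(row))
    return rows


# ----------------------------------------------------------------------
# dataset assembly

_LOOP_BASES = "ACGU"


def random_spec(rng, min_len: int = 16, max_len: int = 48) -> ToySpec:
    """A random toy RNA: one or two stems with hairpin loops, linkers and
    dangling ends, lengths within [min_len, max_len]."""
    for _ in range(200):
        two = rng.random() < 0.4
        stems = 2 if two else 1
        parts = []
        db = []

        def dangle(lo, hi):
            k = int(rng.integers(lo, hi + 1))
            parts.append("".join(_LOOP_BASES[rng.integers(4)]
                                 for _ in range(k)))
            db.append("." * k)

        dangle(0, 3)
        for _ in range(stems):
            bp = int(rng.integers(3, 7))
            loop = int(rng.integers(3, 7))
            left, right = [], []
            for _ in range(bp):
                a, b = _PAIR_CHOICES[rng.integers(len(_PAIR_CHOICES))]
                left.append(a)
                right.append(b)
            loop_seq = "".join(_LOOP_BASES[rng.integers(4)]
                               for _ in range(loop))
            parts.append("".join(left) + loop_seq
                         + "".join(reversed(right)))
            db.append("(" * bp + "." * loop + ")" * bp)
            dangle(2, 4)
        seq = "".join(parts)
        dbs = "".join(db)
        if min_len <= len(seq) <= max_len:
            return ToySpec(seq, dbs, seed=int(rng.integers(2 ** 31)))
    raise GenerationError("could not draw a spec within length bounds")


def make_dataset(n_samples: int, seed: int = 0, min_len: int = 16,
                 max_len: int = 48, msa_rows: int = 16,
                 config=None) -> list[dict]:
    """Seeded list of training samples.

    Each sample is a dict with keys ``spec``, ``structure``, ``labels``
    (GeometryLabels), ``msa`` (rows), ``ss`` (0/1 pair matrix) and
    ``features`` (FeatureBundle).
    """
    if n_samples < 1:
        raise ValueError("n_samples >= 1 required")
    rng = np.random.default_rng(seed)
    config = config or _features.FeatureConfig()
    out = []
    while len(out) < n_samples:
        spec = random_spec(rng, min_len, max_len)
        try:
            structure = make_toy_structure(spec)
        except GenerationError:
            continue
        labels = discretize(compute_geometries(structure))
        msa_rows_list = synthetic_msa(spec.sequence, spec.dotbracket,
                                      n=msa_rows,
                                      seed=int(rng.integers(2 ** 31)))
        msa = _features.Alignment(msa_rows_list)
        ss = pairs_to_matrix(spec.pairs, len(spec.sequence))
        bundle = _features.build_features(msa, ss, config)
        out.append({"spec": spec, "structure": structure, "labels": labels,
                    "msa": msa, "ss": ss, "features": bundle})
    return out
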