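"""Coarse-grained RNA representation and 1D/2D geometry computation.

Each nucleotide is reduced to four atoms: the backbone phosphate P, the
sugar atoms C4' and C1', and the glycosidic base nitrogen N (N1 for
pyrimidines C/U, N9 for purines A/G).  From these atoms the module derives
the geometries the network predicts:

* five inter-nucleotide distances (P-P, C4'-C4', C1'-C1', N-N, C4'-N);
* five 2D orientations between nucleotide pairs — one symmetric dihedral,
  two asymmetric dihedrals and two planar angles (atom quadruples below);
* four 1D backbone torsions per nucleotide — the pseudotorsions eta and
  theta plus two frame-relative torsions;
* a binary contact map (minimum coarse-atom distance < 8 A, |i-j| >= 2).

Values are discretized for training: distances into 38 bins of 1 A over
[2, 40) plus a catch-all class for >= 40 A; dihedrals into 24 bins of 15
degrees over [-180, 180); planar angles into 12 bins of 15 degrees over
[0, 180).  Each 2D orientation carries one extra "no assignment" class used
when the pair's P-P distance is beyond the 40 A horizon; the 1D torsions
carry the same extra class for chain termini where the torsion is undefined.

2D orientation atom quadruples/triples for the pair (i, j):

==========  =========================================  =========
name        atoms                                      symmetry
==========  =========================================  =========
omega       C1'(i) - N(i) - N(j) - C1'(j)              symmetric
theta_a     C4'(i) - C1'(i) - N(i) - N(j)              asymmetric
theta_b     P(i) - C4'(i) - C1'(i) - N(j)              asymmetric
phi_a       C1'(i) - N(i) - N(j)                       asymmetric
phi_b       C4'(i) - N(i) - N(j)                       asymmetric
==========  =========================================  =========

1D torsions for nucleotide i:

==========  ==============================================
eta         C4'(i-1) - P(i) - C4'(i) - P(i+1)
theta       P(i) - C4'(i) - P(i+1) - C4'(i+1)
chi         P(i) - C4'(i) - C1'(i) - N(i)
zeta        C1'(i) - C4'(i) - P(i+1) - C4'(i+1)
==========  ==============================================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ATOMS", "CoarseStructure", "GeometryValues", "BinSpec",
    "GeometryLabels", "build_frames", "compute_geometries", "discretize",
    "dihedral", "planar_angle", "CONTACT_CUTOFF", "DIST_NAMES",
    "ORI2D_NAMES", "ORI2D_KIND", "ORI1D_NAMES",
]

ATOMS = ("P", "C4'", "C1'", "N")
P, C4, C1, N = 0, 1, 2, 3

DIST_NAMES = ("P-P", "C4'-C4'", "C1'-C1'", "N-N", "C4'-N")
DIST_PAIRS = ((P, P), (C4, C4), (C1, C1), (N, N), (C4, N))

ORI2D_NAMES = ("omega", "theta_a", "theta_b", "phi_a", "phi_b")
# "dihedral" -> 24 bins, "angle" -> 12 bins
ORI2D_KIND = ("dihedral", "dihedral", "dihedral", "angle", "angle")
ORI2D_SYMMETRIC = (True, False, False, False, False)

ORI1D_NAMES = ("eta", "theta", "chi", "zeta")

#: contact horizon on the minimum coarse-atom distance, Angstrom
CONTACT_CUTOFF = 8.0
#: minimum sequence separation for a contact
CONTACT_MIN_SEP = 2
#: pairs with P-P distance beyond this are not assigned orientation classes
DIST_HORIZON = 40.0


class DegenerateFrameError(ValueError):
    """Raised when C4', C1' and N are collinear and no frame exists."""


@dataclass
class CoarseStructure:
    """A coarse-grained RNA chain.

    Parameters
    ----------
    sequence : str over ``ACGU``
    coords : (L, 4, 3) float array, Angstrom, atom order (P, C4', C1', N).
    """

    sequence: str
    coords: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        L = len(self.sequence)
        if L < 2:
            raise ValueError(f"need at least 2 nucleotides, got {L}")
        if self.coords.shape != (L, 4, 3):
            raise ValueError(
                f"coords shape {self.coords.shape} != ({L}, 4, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("non-finite coordinates")
        bad = set(self.sequence) - set("ACGU")
        if bad:
            raise ValueError(f"invalid nucleotides: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def copy(self) -> "CoarseStructure":
        return CoarseStructure(self.sequence, self.coords.copy())


@dataclass
class GeometryValues:
    """Continuous geometries of one structure.

    ``dist``: (5, L, L) A; ``ori2d``: (5, L, L) degrees with NaN where
    undefined; ``ori1d``: (4, L) degrees with NaN at termini;
    ``contact``: (L, L) 0/1.
    """

    dist: np.ndarray
    ori2d: np.ndarray
    ori1d: np.ndarray
    contact: np.ndarray


@dataclass(frozen=True)
class BinSpec:
    """Discretization grid for all geometry channels.

    38 distance bins of 1 A on [2, 40) plus one catch-all class (39 total);
    24 dihedral bins of 15 deg on [-180, 180) and 12 planar-angle bins of
    15 deg on [0, 180], each plus one no-assignment class.
    """

    dist_edges: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 41.0, 1.0))
    dihedral_edges: np.ndarray = field(
        default_factory=lambda: np.arange(-180.0, 181.0, 15.0))
    angle_edges: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 181.0, 15.0))

    @property
    def n_dist(self) -> int:          # finite bins
        return len(self.dist_edges) - 1          # 38

    @property
    def n_dist_classes(self) -> int:  # incl. catch-all
        return self.n_dist + 1                   # 39

    @property
    def n_dihedral(self) -> int:
        return len(self.dihedral_edges) - 1      # 24

    @property
    def n_angle(self) -> int:
        return len(self.angle_edges) - 1         # 12

    def dist_centers(self) -> np.ndarray:
        e = self.dist_edges
        return 0.5 * (e[:-1] + e[1:])

    def dihedral_centers(self) -> np.ndarray:
        e = self.dihedral_edges
        return 0.5 * (e[:-1] + e[1:])

    def angle_centers(self) -> np.ndarray:
        e = self.angle_edges
        return 0.5 * (e[:-1] + e[1:])

    def ori2d_classes(self, k: int) -> int:
        """Class count (incl. no-assignment class) of 2D orientation k."""
        return (self.n_dihedral if ORI2D_KIND[k] == "dihedral"
                else self.n_angle) + 1

    @property
    def n_ori1d_classes(self) -> int:
        return self.n_dihedral + 1               # 25


@dataclass
class GeometryLabels:
    """One-hot class labels plus masks, shaped to match predictions.

    ``dist``: (5, L, L) int classes in [0, 39); ``ori2d``: list of 5
    (L, L) int arrays; ``ori1d``: (4, L) int; ``contact``: (L, L) 0/1;
    ``mask2d``: (L, L) bool; ``mask1d``: (4, L) bool.
    """

    dist: np.ndarray
    ori2d: list
    ori1d: np.ndarray
    contact: np.ndarray
    mask2d: np.ndarray
    mask1d: np.ndarray


# ----------------------------------------------------------------------
# frames and primitive angle computations

def build_frames(structure: CoarseStructure) -> np.ndarray:
    """Per-nucleotide right-handed orthonormal frames, shape (L, 3, 3).

    Origin at C1'; x toward N; z along the normal of the C4'-C1'-N plane;
    rows of each (3, 3) block are the basis vectors x, y, z.
    """
    c4 = structure.coords[:, C4]
    c1 = structure.coords[:, C1]
    n = structure.coords[:, N]
    x = n - c1
    xn = np.linalg.norm(x, axis=1, keepdims=True)
    u = c4 - c1
    z = np.cross(u, x)
    zn = np.linalg.norm(z, axis=1, keepdims=True)
    bad = (xn[:, 0] < 1e-9) | (zn[:, 0] < 1e-9)
    if bad.any():
        idx = int(np.nonzero(bad)[0][0])
        raise DegenerateFrameError(
            f"collinear C4', C1', N at nucleotide {idx}")
    x = x / xn
    z = z / zn
    y = np.cross(z, x)
    return np.stack([x, y, z], axis=1)


def dihedral(p0, p1, p2, p3) -> np.ndarray:
    """Signed dihedral angle(s) in degrees in [-180, 180).

    Accepts arrays broadcastable to (..., 3).
    """
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2, axis=-1, keepdims=True))
    x = (n1 * n2).sum(-1)
    y = (m * n2).sum(-1)
    ang = np.degrees(np.arctan2(y, x))
    # map +180 to -180 to keep the half-open convention
    return np.where(ang >= 180.0, ang - 360.0, ang)


def planar_angle(p0, p1, p2) -> np.ndarray:
    """Planar angle(s) at p1 in degrees in [0, 180]."""
    u = np.asarray(p0) - np.asarray(p1)
    v = np.asarray(p2) - np.asarray(p1)
    c = (u * v).sum(-1) / (np.linalg.norm(u, axis=-1)
                           * np.linalg.norm(v, axis=-1))
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


# ----------------------------------------------------------------------

def compute_geometries(structure: CoarseStructure) -> GeometryValues:
    """All 1D/2D geometries of a coarse structure (vectorized)."""
    xyz = structure.coords
    L = len(structure)

    dist = np.zeros((5, L, L))
    for k, (a, b) in enumerate(DIST_PAIRS):
        diff = xyz[:, None, a, :] - xyz[None, :, b, :]
        dist[k] = np.sqrt((diff ** 2).sum(-1))
        np.fill_diagonal(dist[k], 0.0)

    # 2D orientations; atom indices per the module docstring
    pi = xyz[:, None, :, :]   # atoms of i, broadcast over j
    pj = xyz[None, :, :, :]   # atoms of j
    ori2d = np.empty((5, L, L))
    with np.errstate(invalid="ignore", divide="ignore"):
        # the diagonal (i == j) produces NaN and is masked below
        ori2d[0] = dihedral(pi[..., C1, :], pi[..., N, :],
                            pj[..., N, :], pj[..., C1, :])
        ori2d[1] = dihedral(pi[..., C4, :], pi[..., C1, :],
                            pi[..., N, :], pj[..., N, :])
        ori2d[2] = dihedral(pi[..., P, :], pi[..., C4, :],
                            pi[..., C1, :], pj[..., N, :])
        ori2d[3] = planar_angle(pi[..., C1, :], pi[..., N, :],
                                pj[..., N, :])
        ori2d[4] = planar_angle(pi[..., C4, :], pi[..., N, :],
                                pj[..., N, :])
    di = np.arange(L)
    ori2d[:, di, di] = np.nan  # self-pairs undefined

    # 1D torsions; NaN where a neighbouring nucleotide is missing
    ori1d = np.full((4, L), np.nan)
    p_ = xyz[:, P]
    c4_ = xyz[:, C4]
    c1_ = xyz[:, C1]
    n_ = xyz[:, N]
    if L >= 3:
        ori1d[0, 1:-1] = dihedral(c4_[:-2], p_[1:-1], c4_[1:-1], p_[2:])
    ori1d[1, :-1] = dihedral(p_[:-1], c4_[:-1], p_[1:], c4_[1:])
    ori1d[2, :] = dihedral(p_, c4_, c1_, n_)
    ori1d[3, :-1] = dihedral(c1_[:-1], c4_[:-1], p_[1:], c4_[1:])

    # contact: min over the 16 coarse-atom pairs
    flat = xyz.reshape(L * 4, 3)
    d_at = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
    d_at = d_at.reshape(L, 4, L, 4)
    dmin = d_at.min(axis=(1, 3))
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    contact = ((dmin < CONTACT_CUTOFF) & (sep >= CONTACT_MIN_SEP)).astype(
        np.int8)
    return GeometryValues(dist=dist, ori2d=ori2d, ori1d=ori1d,
                          contact=contact)


def discretize(values: GeometryValues, bins: BinSpec | None = None
               ) -> GeometryLabels:
    """Class labels from continuous geometries.

    Distances at or beyond 40 A (and below the 2 A left edge, which a valid
    structure does not produce) go to the catch-all class.  Orientation
    classes are assigned only where the pair's P-P distance is below 40 A;
    beyond the horizon the pair gets the no-assignment class.  Undefined 1D
    torsions (termini) get the no-assignment class and are masked.
    """
    bins = bins or BinSpec()
    L = values.dist.shape[1]

    dist_lab = np.empty((5, L, L), dtype=np.int64)
    for k in range(5):
        d = values.dist[k]
        cls = np.clip(np.digitize(d, bins.dist_edges) - 1, 0,
                      bins.n_dist - 1)
        dist_lab[k] = np.where(d >= bins.dist_edges[-1], bins.n_dist, cls)
    di = np.arange(L)
    dist_lab[:, di, di] = 0  # diagonal distance 0 -> masked anyway

    within = values.dist[0] < DIST_HORIZON
    mask2d = np.ones((L, L), dtype=bool)
    mask2d[di, di] = False

    ori2d_lab = []
    for k in range(5):
        v = values.ori2d[k]
        if ORI2D_KIND[k] == "dihedral":
            edges, nb = bins.dihedral_edges, bins.n_dihedral
        else:
            edges, nb = bins.angle_edges, bins.n_angle
        cls = np.clip(np.digitize(v, edges) - 1, 0, nb - 1)
        cls = np.where(within & ~np.isnan(v), cls, nb)
        ori2d_lab.append(cls.astype(np.int64))

    ori1d_lab = np.empty((4, L), dtype=np.int64)
    mask1d = ~np.isnan(values.ori1d)
    for g in range(4):
        v = values.ori1d[g]
        cls = np.clip(np.digitize(v, bins.dihedral_edges) - 1, 0,
                      bins.n_dihedral - 1)
        ori1d_lab[g] = np.where(mask1d[g], cls, bins.n_dihedral)

    return GeometryLabels(dist=dist_lab, ori2d=ori2d_lab, ori1d=ori1d_lab,
                          contact=values.contact.astype(np.int64),
                          mask2d=mask2d, mask1d=mask1d)
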