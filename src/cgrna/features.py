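"""MSA and secondary-structure features for the geometry network.

The alignment is summarized into pair features — per-column-pair mutual
information with average-product correction (APC) plus the 5x5 joint
frequency table over {A, C, G, U, -} — and concatenated with the pairing
probability matrix and a clipped relative-position encoding.  Learned
linear maps then produce the initial MSA representation (n, L, c) and pair
representation (L, L, c').
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Alignment", "FeatureConfig", "FeatureBundle",
    "compute_couplings", "neff", "build_features", "one_hot_msa",
    "ALPHABET",
]

ALPHABET = "ACGU-"
_A2I = {c: i for i, c in enumerate(ALPHABET)}
NSYM = len(ALPHABET)


class EmptyAlignmentError(ValueError):
    pass


@dataclass
class Alignment:
    """Aligned homolog rows over {A, C, G, U, -}; row 0 is the query.

    The query row must be gap-free (columns are query positions)."""

    rows: list[str]

    def __post_init__(self):
        if len(self.rows) == 0:
            raise EmptyAlignmentError("alignment has no rows")
        L = len(self.rows[0])
        for k, r in enumerate(self.rows):
            if len(r) != L:
                raise ValueError(f"row {k} length {len(r)} != {L}")
            bad = set(r) - set(ALPHABET)
            if bad:
                raise ValueError(f"row {k}: invalid symbols {sorted(bad)}")
        if "-" in self.rows[0]:
            raise ValueError("query row contains gaps; project to query "
                             "columns first")

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def L(self) -> int:
        return len(self.rows[0])

    def to_indices(self) -> np.ndarray:
        return np.array([[_A2I[c] for c in r] for r in self.rows],
                        dtype=np.int64)

    @classmethod
    def from_rows(cls, rows) -> "Alignment":
        """Build an alignment, projecting columns where row 0 has gaps."""
        rows = list(rows)
        if not rows:
            raise EmptyAlignmentError("alignment has no rows")
        keep = [k for k, c in enumerate(rows[0]) if c != "-"]
        return cls(["".join(r[k] for k in keep) for r in rows])


@dataclass
class FeatureConfig:
    """Channel sizes and the seeded linear embedding parameters."""

    msa_channels: int = 32
    pair_channels: int = 32
    pos_clip: int = 32
    seed: int = 0

    @property
    def n_pair_in(self) -> int:
        # MI+APC (1) + joint 5x5 table (25) + ss prob (1) + rel-pos one-hot
        return 1 + NSYM * NSYM + 1 + (2 * self.pos_clip + 1)

    def parameters(self) -> dict:
        """Seeded embedding matrices (the 'learned' linear maps)."""
        rng = np.random.default_rng(self.seed)
        w_msa = rng.normal(0.0, 1.0 / np.sqrt(NSYM),
                           size=(NSYM, self.msa_channels))
        w_pair = rng.normal(0.0, 1.0 / np.sqrt(self.n_pair_in),
                            size=(self.n_pair_in, self.pair_channels))
        return {"w_msa": w_msa, "w_pair": w_pair}


@dataclass
class FeatureBundle:
    """Initial representations consumed by the network."""

    msa_init: np.ndarray    # (n, L, c)
    pair_init: np.ndarray   # (L, L, c')


def one_hot_msa(msa: Alignment) -> np.ndarray:
    """(n, L, 5) one-hot encoding over A/C/G/U/gap."""
    idx = msa.to_indices()
    return np.eye(NSYM)[idx]


def compute_couplings(msa: Alignment) -> np.ndarray:
    """(L, L, 26) coupling features: APC-corrected MI + joint frequencies.

    Plug-in (maximum-likelihood) estimators from raw column counts; the
    channel is a learnable input, so no sequence reweighting or
    pseudocounts beyond a numerical floor are applied.
    """
    idx = msa.to_indices()
    n, L = idx.shape
    oh = np.eye(NSYM)[idx]                      # (n, L, 5)
    f1 = oh.mean(axis=0)                        # (L, 5)
    # joint frequencies: (L, L, 5, 5)
    f2 = np.einsum("nia,njb->ijab", oh, oh) / n
    pij = f2 + 1e-12
    pi_pj = f1[:, None, :, None] * f1[None, :, None, :] + 1e-12
    mi = (f2 * np.log(pij / pi_pj)).sum(axis=(2, 3))
    np.fill_diagonal(mi, 0.0)
    # average-product correction
    row = mi.sum(axis=1) / max(L - 1, 1)
    tot = mi.sum() / max(L * (L - 1), 1)
    apc = np.outer(row, row) / max(tot, 1e-12)
    mi_apc = mi - apc
    np.fill_diagonal(mi_apc, 0.0)
    return np.concatenate(
        [mi_apc[..., None], f2.reshape(L, L, NSYM * NSYM)], axis=-1)


def neff(msa: Alignment, identity_cutoff: float = 0.8) -> float:
    """Effective sequence count at the given identity cutoff.

    Each row is weighted by 1 / (number of rows at >= cutoff identity to
    it, itself included); identity is the match fraction over the query's
    (non-gap) columns.
    """
    idx = msa.to_indices()
    n, L = idx.shape
    same = (idx[:, None, :] == idx[None, :, :]).mean(axis=2)
    counts = (same >= identity_cutoff).sum(axis=1)
    return float((1.0 / counts).sum())


def _relpos_onehot(L: int, clip: int) -> np.ndarray:
    d = np.arange(L)[:, None] - np.arange(L)[None, :]
    d = np.clip(d, -clip, clip) + clip
    return np.eye(2 * clip + 1)[d]


def build_features(msa: Alignment, ss: np.ndarray,
                   config: FeatureConfig | None = None,
                   parameters: dict | None = None) -> FeatureBundle:
    """Initial MSA and pair representations.

    ``ss`` is the L x L pairing-probability matrix; its dimension must
    match the alignment's query length.
    """
    config = config or FeatureConfig()
    params = parameters if parameters is not None else config.parameters()
    ss = np.asarray(ss, float)
    if ss.shape != (msa.L, msa.L):
        raise ValueError(
            f"secondary-structure matrix is {ss.shape} but the query "
            f"length is {msa.L}")
    msa_init = one_hot_msa(msa) @ params["w_msa"]
    pair_in = np.concatenate(
        [compute_couplings(msa), ss[..., None],
         _relpos_onehot(msa.L, config.pos_clip)], axis=-1)
    pair_init = pair_in @ params["w_pair"]
    return FeatureBundle(msa_init=msa_init, pair_init=pair_init)
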