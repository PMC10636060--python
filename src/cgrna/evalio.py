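"""Structure evaluation metrics and file I/O.

Metrics: all-coarse-atom RMSD after optimal (Kabsch) superposition,
interaction-network fidelity (INF) and F1 over base-pair sets, and a
simplified steric-clash count on the coarse atoms.

I/O: FASTA, aligned FASTA / Stockholm alignments, dot-bracket strings,
whitespace-separated L x L pairing-probability matrices, coarse-grained PDB
files (atoms P, C4', C1', N1/N9), and npz containers for geometry
predictions and restraint sets.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from Bio import AlignIO, SeqIO

from .geometry import ATOMS, CoarseStructure

__all__ = [
    "kabsch_rmsd", "kabsch_superpose", "inf_score", "f1_ss", "clash_count",
    "read_fasta", "read_alignment", "read_dotbracket", "dotbracket_to_pairs",
    "read_ss_matrix", "write_pdb", "read_pdb_coarse",
    "save_prediction", "load_prediction",
    "save_restraints", "load_restraints",
]

CLASH_CUTOFF = 3.2  # Angstrom, coarse-atom steric overlap


# ----------------------------------------------------------------------
# metrics

def kabsch_superpose(mobile: np.ndarray, ref: np.ndarray):
    """Optimal rotation/translation of ``mobile`` (N,3) onto ``ref`` (N,3).

    Returns (transformed mobile, rmsd).
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    mc = mobile - mobile.mean(0)
    rc = ref - ref.mean(0)
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    moved = mc @ R + ref.mean(0)
    rmsd = float(np.sqrt(((moved - ref) ** 2).sum() / len(ref)))
    return moved, rmsd


def _coords_of(x) -> np.ndarray:
    if isinstance(x, CoarseStructure):
        return x.coords.reshape(-1, 3)
    return np.asarray(x, float).reshape(-1, 3)


def kabsch_rmsd(a, b) -> float:
    """All-coarse-atom RMSD of two structures after optimal superposition."""
    pa, pb = _coords_of(a), _coords_of(b)
    if pa.shape != pb.shape:
        raise ValueError(f"atom count mismatch: {pa.shape} vs {pb.shape}")
    return kabsch_superpose(pa, pb)[1]


def _normalize_pairs(pairs) -> set:
    return {(min(i, j), max(i, j)) for i, j in pairs if i != j}


def inf_score(pred_pairs, true_pairs) -> float:
    """Interaction network fidelity: sqrt(PPV * TPR) over pair sets."""
    p = _normalize_pairs(pred_pairs)
    t = _normalize_pairs(true_pairs)
    if not p or not t:
        return 0.0
    tp = len(p & t)
    ppv = tp / len(p)
    tpr = tp / len(t)
    return float(np.sqrt(ppv * tpr))


def f1_ss(pred_pairs, true_pairs) -> float:
    """F1 score over base-pair sets (0 when either set is empty)."""
    p = _normalize_pairs(pred_pairs)
    t = _normalize_pairs(true_pairs)
    if not p or not t:
        return 0.0
    tp = len(p & t)
    if tp == 0:
        return 0.0
    prec = tp / len(p)
    rec = tp / len(t)
    return float(2 * prec * rec / (prec + rec))


def clash_count(structure: CoarseStructure, cutoff: float = CLASH_CUTOFF
                ) -> int:
    """Number of coarse-atom pairs closer than ``cutoff`` between
    nucleotides separated by at least 2 in sequence."""
    L = len(structure)
    flat = structure.coords.reshape(L * 4, 3)
    d = np.linalg.norm(flat[:, None] - flat[None, :], axis=-1)
    d = d.reshape(L, 4, L, 4)
    sep = np.abs(np.arange(L)[:, None] - np.arange(L)[None, :])
    close = d < cutoff
    # count atom pairs; each unordered nucleotide pair (i < j) once
    iu = np.arange(L)
    mask = ((sep >= 2) & (iu[:, None] < iu[None, :]))[:, None, :, None]
    return int((close & mask).sum())


# ----------------------------------------------------------------------
# sequence / alignment / secondary-structure I/O

class ParseError(ValueError):
    pass


def read_fasta(path) -> dict:
    """{record id: sequence} with T mapped to U and upper-cased."""
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id] = str(rec.seq).upper().replace("T", "U")
    if not out:
        raise ParseError(f"no FASTA records in {path}")
    return out


def read_alignment(path, fmt: str | None = None):
    """Aligned rows (list of str) from aligned FASTA or Stockholm.

    Returns (rows, ss_cons) where ss_cons is the ``#=GC SS_cons`` line of a
    Stockholm file (None otherwise).  Rows are upper-case over A/C/G/U/-;
    '.' gap characters are mapped to '-'.
    """
    path = Path(path)
    if fmt is None:
        head = path.read_text().lstrip()[:11]
        fmt = "stockholm" if head.startswith("# STOCKHOLM") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    rows = [str(r.seq).upper().replace("T", "U").replace(".", "-")
            for r in aln]
    if len({len(r) for r in rows}) != 1:
        raise ParseError(f"ragged alignment in {path}")
    ss = None
    if fmt == "stockholm":
        ss = aln.column_annotations.get("secondary_structure")
    return rows, ss


def dotbracket_to_pairs(db: str) -> list[tuple[int, int]]:
    """Base pairs (i, j), i < j, from a nested dot-bracket string.

    Only '.', '(' and ')' are supported; bracket types used for pseudoknots
    ('[]{}<>', letters) raise ``ParseError``.
    """
    pairs = []
    stack = []
    for k, ch in enumerate(db):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ParseError(f"unbalanced ')' at position {k}")
            pairs.append((stack.pop(), k))
        elif ch in ".-":
            continue
        elif ch in "[]{}<>" or ch.isalpha():
            raise ParseError(
                f"pseudoknot bracket {ch!r} at position {k} is unsupported")
        else:
            raise ParseError(f"invalid character {ch!r} at position {k}")
    if stack:
        raise ParseError(f"unbalanced '(' at position {stack[-1]}")
    return sorted(pairs)


def read_dotbracket(path) -> tuple[str, str]:
    """(sequence, dot-bracket) from a two-line file (optionally with a
    leading FASTA-style header)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if lines and lines[0].startswith(">"):
        lines = lines[1:]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected sequence and structure lines")
    seq, db = lines[0].upper().replace("T", "U"), lines[1]
    if len(seq) != len(db):
        raise ParseError(
            f"{path}: sequence length {len(seq)} != structure {len(db)}")
    dotbracket_to_pairs(db)  # validates
    return seq, db


def read_ss_matrix(path, L: int | None = None) -> np.ndarray:
    """L x L pairing-probability matrix from whitespace-separated text."""
    m = np.loadtxt(str(path))
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ParseError(f"{path}: expected a square matrix, got {m.shape}")
    if L is not None and m.shape[0] != L:
        raise ParseError(f"{path}: matrix size {m.shape[0]} != length {L}")
    if (m < -1e-9).any() or (m > 1 + 1e-9).any():
        raise ParseError(f"{path}: probabilities outside [0, 1]")
    return 0.5 * (m + m.T)


def pairs_to_matrix(pairs, L: int) -> np.ndarray:
    m = np.zeros((L, L))
    for i, j in pairs:
        m[i, j] = m[j, i] = 1.0
    return m


# ----------------------------------------------------------------------
# PDB

_PURINES = set("AG")


def _atom_name(atom: str, base: str) -> str:
    if atom == "N":
        return "N9" if base in _PURINES else "N1"
    return atom


def write_pdb(structure: CoarseStructure, path, confidence=None) -> None:
    """Write a coarse structure as PDB (chain A, 1-based residues).

    ``confidence`` (optional, length L) fills the B-factor column with the
    per-nucleotide confidence c_i; 0 otherwise.
    """
    conf = np.zeros(len(structure)) if confidence is None \
        else np.asarray(confidence, float)
    lines = []
    serial = 1
    for i, base in enumerate(structure.sequence):
        for a, atom in enumerate(ATOMS):
            x, y, z = structure.coords[i, a]
            name = _atom_name(atom, base)
            lines.append(
                f"ATOM  {serial:5d} {name:^4s} {base:>3s} A{i + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{conf[i]:6.2f}"
                f"          {name[0]:>2s}")
            serial += 1
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb_coarse(path) -> CoarseStructure:
    """Read a coarse structure written by :func:`write_pdb`."""
    residues: dict[int, dict] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.startswith("ATOM"):
            continue
        try:
            name = line[12:16].strip()
            base = line[17:20].strip()
            resi = int(line[22:26])
            xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
        except ValueError as exc:
            raise ParseError(f"{path}: malformed ATOM record at line "
                             f"{ln_no}") from exc
        res = residues.setdefault(resi, {"base": base, "atoms": {}})
        key = "N" if name in ("N1", "N9") else name
        res["atoms"][key] = xyz
    if not residues:
        raise ParseError(f"{path}: no ATOM records")
    order = sorted(residues)
    seq = "".join(residues[r]["base"][-1] for r in order)
    coords = np.zeros((len(order), 4, 3))
    for k, r in enumerate(order):
        atoms = residues[r]["atoms"]
        for a, atom in enumerate(ATOMS):
            if atom not in atoms:
                raise ParseError(f"{path}: residue {r} missing atom {atom}")
            coords[k, a] = atoms[atom]
    return CoarseStructure(seq, coords)


# ----------------------------------------------------------------------
# prediction containers (npz + embedded JSON manifest)

def save_prediction(pred, path) -> None:
    """Serialize a GeometryPrediction to an ``.npz`` container."""
    arrays = {"dist": pred.dist, "contact": pred.contact,
              "ori1d": pred.ori1d}
    for k, arr in enumerate(pred.ori2d):
        arrays[f"ori2d_{k}"] = arr
    manifest = {"kind": "geometry_prediction", "L": int(pred.dist.shape[1])}
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_prediction(path):
    from .network import GeometryPrediction  # deferred: avoid cycle
    with np.load(str(path)) as z:
        ori2d = [z[f"ori2d_{k}"] for k in range(5)]
        return GeometryPrediction(dist=z["dist"], ori2d=ori2d,
                                  ori1d=z["ori1d"], contact=z["contact"])


def save_restraints(rs, path) -> None:
    """Serialize a RestraintSet: named arrays (pair indices + potential
    tables) plus a JSON manifest with thresholds and the bin grid."""
    from dataclasses import asdict
    arrays = {"contact_i": rs.contact.idx_i, "contact_j": rs.contact.idx_j,
              "contact_strength": rs.contact.strength}
    spline_meta = {}
    for group, channels in (("dist", rs.dist), ("ori2d", rs.ori2d),
                            ("ori1d", rs.ori1d)):
        for k, ch in enumerate(channels):
            if ch is None:
                continue
            arrays[f"{group}{k}_i"] = ch.idx_i
            arrays[f"{group}{k}_j"] = ch.idx_j
            arrays[f"{group}{k}_V"] = ch.spline.V
            spline_meta[f"{group}{k}"] = {
                "x0": ch.spline.x0, "dx": ch.spline.dx,
                "periodic": ch.spline.periodic,
                "left_slope": ch.spline.left_slope}
    manifest = {"kind": "restraint_set", "L": rs.L,
                "config": asdict(rs.config), "splines": spline_meta}
    arrays["manifest"] = np.frombuffer(
        json.dumps(manifest).encode(), dtype=np.uint8)
    np.savez_compressed(str(path), **arrays)


def load_restraints(path):
    from .restraints import (RestraintConfig, RestraintSet, _ContactChannel,
                             _PairChannel, _Spline)   # deferred
    with np.load(str(path)) as z:
        manifest = json.loads(bytes(z["manifest"]).decode())
        cfg = RestraintConfig(**manifest["config"])

        def channel(name):
            if f"{name}_V" not in z.files:
                return None
            meta = manifest["splines"][name]
            return _PairChannel(z[f"{name}_i"], z[f"{name}_j"],
                                _Spline(z[f"{name}_V"], meta["x0"],
                                        meta["dx"], meta["periodic"],
                                        meta["left_slope"]))

        return RestraintSet(
            L=manifest["L"],
            dist=[channel(f"dist{k}") for k in range(5)],
            ori2d=[channel(f"ori2d{k}") for k in range(5)],
            ori1d=[channel(f"ori1d{k}") for k in range(4)],
            contact=_ContactChannel(z["contact_i"], z["contact_j"],
                                    z["contact_strength"]),
            config=cfg)
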