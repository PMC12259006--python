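"""Trajectory featurization: backbone/sidechain dihedrals, distances, contacts.

The kinetic-model feature space is built from the phi/psi/chi-1 dihedral
angles of a configurable residue window.  Each angle is emitted as a
(cos, sin) pair so that the feature space is Euclidean and free of the
-180/180 wrap — the covariance estimators downstream assume this.
"""
from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .containers import EnsembleSample, FeatureDescriptor, FeatureMatrix
from .structio import Topology, Trajectory

__all__ = [
    "dihedral",
    "dihedral_trajectory",
    "featurize_dihedrals",
    "atom_distance",
    "contact_probability",
    "CHI1_GAMMA_ATOM",
]

#: standard gamma heavy atom defining chi-1 (N-CA-CB-XG) per residue type;
#: residues without a gamma heavy atom (Gly, Ala) contribute no chi-1
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "SER": "OG", "THR": "OG1", "CYS": "SG", "VAL": "CG1", "ILE": "CG1",
}

_MIN_NORM = 1e-10


def _dihedral_frames(p1, p2, p3, p4):
    """Signed torsion (degrees, IUPAC: cis = 0) for stacked frame arrays."""
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    n1n = np.linalg.norm(n1, axis=-1)
    n2n = np.linalg.norm(n2, axis=-1)
    scale = max(
        float(np.max(np.linalg.norm(b1, axis=-1))),
        float(np.max(np.linalg.norm(b3, axis=-1))),
        1.0,
    )
    if np.any(n1n < _MIN_NORM * scale) or np.any(n2n < _MIN_NORM * scale):
        raise ValueError("undefined torsion: collinear or coincident points")
    b2u = b2 / np.linalg.norm(b2, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b2u, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang <= -180.0, ang + 360.0, ang)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle in degrees in (-180, 180] for four points (Angstrom).

    Sign follows the IUPAC convention (cis/syn = 0 degrees).  Raises if the
    first or last three points are collinear (torsion undefined).
    """
    pts = [np.asarray(p, dtype=np.float64) for p in (p1, p2, p3, p4)]
    for a, b in zip(pts, pts[1:]):
        if np.linalg.norm(b - a) < _MIN_NORM:
            raise ValueError("undefined torsion: coincident consecutive points")
    return float(_dihedral_frames(*pts))


def dihedral_trajectory(traj: Trajectory, quad: Sequence[int]) -> np.ndarray:
    """Per-frame torsion (degrees) over the four atom indices in ``quad``."""
    i, j, k, l = quad
    c = traj.coords
    return _dihedral_frames(c[:, i], c[:, j], c[:, k], c[:, l])


def _residue_atom_map(top: Topology, chain: str | None):
    out: dict[tuple[str, int], dict[str, int]] = {}
    resname: dict[tuple[str, int], str] = {}
    for i, a in enumerate(top.atoms):
        if chain is not None and a.chain_id != chain:
            continue
        key = (a.chain_id, a.residue_index)
        out.setdefault(key, {})[a.name] = i
        resname.setdefault(key, a.residue_name)
    return out, resname


def featurize_dihedrals(
    traj: Trajectory,
    resid_range: tuple[int, int],
    chain: str | None = None,
) -> FeatureMatrix:
    """Compute phi/psi/chi-1 for residues in ``resid_range`` (inclusive).

    Each defined angle contributes a (cos, sin) column pair; the column order
    is residue ascending, then phi, psi, chi-1.  Angles whose atoms are absent
    (chain termini, Gly/Ala chi-1) are simply omitted.
    """
    lo, hi = resid_range
    amap, rnames = _residue_atom_map(traj.topology, chain)
    if chain is None:
        chains = sorted({c for c, _ in amap})
        if len(chains) != 1:
            raise ValueError("topology has multiple chains; pass chain=")
        chain = chains[0]
    resids = sorted(r for c, r in amap if c == chain)
    if not resids or lo > max(resids) or hi < min(resids):
        raise ValueError(f"residue range {lo}-{hi} outside topology")

    quads: list[tuple[str, str, tuple[int, int, int, int]]] = []
    for r in resids:
        if not (lo <= r <= hi):
            continue
        here = amap[(chain, r)]
        prev = amap.get((chain, r - 1), {})
        nxt = amap.get((chain, r + 1), {})
        if "C" in prev and all(n in here for n in ("N", "CA", "C")):
            quads.append((f"{chain}:{r}", "phi", (prev["C"], here["N"], here["CA"], here["C"])))
        if all(n in here for n in ("N", "CA", "C")) and "N" in nxt:
            quads.append((f"{chain}:{r}", "psi", (here["N"], here["CA"], here["C"], nxt["N"])))
        gamma = CHI1_GAMMA_ATOM.get(rnames[(chain, r)])
        if gamma and all(n in here for n in ("N", "CA", "CB", gamma)):
            quads.append(
                (f"{chain}:{r}", "chi1", (here["N"], here["CA"], here["CB"], here[gamma]))
            )
    if not quads:
        raise ValueError(f"no dihedrals defined in residue range {lo}-{hi}")

    cols: list[np.ndarray] = []
    descs: list[FeatureDescriptor] = []
    for label, kind, quad in quads:
        ang = np.radians(dihedral_trajectory(traj, quad))
        cols.append(np.cos(ang))
        cols.append(np.sin(ang))
        descs.append(FeatureDescriptor("dihedral_cos", quad, f"{kind} {label} cos"))
        descs.append(FeatureDescriptor("dihedral_sin", quad, f"{kind} {label} sin"))
    return FeatureMatrix(np.column_stack(cols), descs)


def atom_distance(traj: Trajectory, i: int, j: int) -> np.ndarray:
    """Per-frame Euclidean distance (Angstrom) between atoms ``i`` and ``j``."""
    n = traj.n_atoms
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"atom index out of range (n_atoms={n})")
    if i == j:
        raise ValueError("atom_distance requires two distinct atoms")
    return np.linalg.norm(traj.coords[:, i] - traj.coords[:, j], axis=-1)


def _heavy_indices_of_residue(top: Topology, resid: int, chain: str | None) -> np.ndarray:
    idx = [
        i
        for i, a in enumerate(top.atoms)
        if a.residue_index == resid
        and a.element != "H"
        and (chain is None or a.chain_id == chain)
    ]
    if not idx:
        raise ValueError(f"residue {resid} (chain {chain}) has no heavy atoms")
    return np.asarray(idx, dtype=np.intp)


def contact_probability(
    sample: EnsembleSample,
    trajectories: Sequence[Trajectory] | Mapping[int, Trajectory],
    resid_a: int,
    resid_b: int,
    cutoff: float = 4.5,
    chain_a: str | None = None,
    chain_b: str | None = None,
) -> float:
    """Fraction of sampled frames with min heavy-atom distance < ``cutoff``.

    The contact criterion is the minimum over all heavy-atom pairs between the
    two residues, strictly below the cutoff (default 4.5 Angstrom).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    if isinstance(trajectories, Mapping):
        trajs = dict(trajectories)
    else:
        trajs = dict(enumerate(trajectories))
    hits = 0
    entries = sample.entries
    for tid in np.unique(entries[:, 0]):
        traj = trajs[int(tid)]
        ia = _heavy_indices_of_residue(traj.topology, resid_a, chain_a)
        ib = _heavy_indices_of_residue(traj.topology, resid_b, chain_b)
        frames = entries[entries[:, 0] == tid, 1]
        ca = traj.coords[frames][:, ia]  # (m, na, 3)
        cb = traj.coords[frames][:, ib]
        d = np.linalg.norm(ca[:, :, None, :] - cb[:, None, :, :], axis=-1)
        hits += int(np.sum(d.min(axis=(1, 2)) < cutoff))
    return hits / sample.n
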