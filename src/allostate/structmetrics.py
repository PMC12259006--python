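"""Geometry engines: superposition/RMSD, solvent accessibility, secondary
structure and hydrogen bonds.

These are the primitives behind every ensemble-level figure analysis:

- **Linchpin RMSD** — a frame is superposed onto an active-state reference
  model using the C-alpha atoms of the structured RING core, then the RMSD of
  the linchpin residue's heavy atoms (matched by atom name) is measured
  without re-alignment.  Low values mean the linchpin is "primed" near its
  catalytically productive pose.
- **Bundle SASA** — the summed Shrake-Rupley solvent-accessible area of the
  sidechain heavy atoms of the hydrophobic interface residues, computed with
  any binding partner removed; high values mean an exposed, binding-competent
  ("primed") helix bundle, low values a hydrophobically collapsed one.
- **Secondary structure** — a simplified DSSP: the Kabsch-Sander
  electrostatic H-bond energy plus minimal 4-turn helix and bridge/ladder
  rules.  3-10 and pi helices are not discriminated (they fall into C), which
  is a documented divergence from full DSSP.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import EnsembleSample
from .structio import BACKBONE_NAMES, AtomSelection, Topology, Trajectory, select_atoms

__all__ = [
    "BONDI_RADII",
    "ReferenceComplexModel",
    "SecondaryStructureAssignment",
    "kabsch_transform",
    "apply_transform",
    "rmsd",
    "make_reference_model",
    "linchpin_rmsd",
    "linchpin_rmsd_profile",
    "sphere_points",
    "sasa",
    "bundle_sasa",
    "bundle_sasa_profile",
    "assign_secondary_structure",
    "structured_probability",
    "hbond_present",
]

#: Bondi van der Waals radii by element (Angstrom)
BONDI_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
    "P": 1.80, "F": 1.47, "Se": 1.90, "Zn": 1.39,
}

_HB_COUPLING = 0.084 * 332.0  # Kabsch-Sander factor, kcal/mol * Angstrom
_HB_ENERGY_CUTOFF = -0.5  # kcal/mol


# ---------------------------------------------------------------------------
# Superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_transform(
    mobile: np.ndarray,
    reference: np.ndarray,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Optimal proper rotation and translation mapping mobile onto reference.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimizes the RMSD over
    ``subset`` (all atoms if None).  Raises on fewer than 3 or collinear
    fitting points.
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    m = mobile if subset is None else mobile[subset]
    r = reference if subset is None else reference[subset]
    if m.shape != r.shape:
        raise ValueError("mobile and reference subsets differ in shape")
    if m.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    mc = m - m.mean(axis=0)
    rc = r - r.mean(axis=0)
    s = np.linalg.svd(mc, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("degenerate alignment: fitting points are collinear")
    H = mc.T @ rc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = r.mean(axis=0) - R @ m.mean(axis=0)
    return R, t


def apply_transform(coords: np.ndarray, R: np.ndarray, t: np.ndarray) -> np.ndarray:
    return coords @ R.T + t


def rmsd(
    a: np.ndarray,
    b: np.ndarray,
    subset: np.ndarray | None = None,
    align: bool = False,
    align_subset: np.ndarray | None = None,
) -> float:
    """Root-mean-square deviation (Angstrom) between coordinate sets.

    With ``align=True`` the optimal superposition is computed first, on
    ``align_subset`` if given (which may differ from the measurement
    ``subset``), otherwise on the measurement subset / all atoms.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("coordinate sets differ in shape")
    if align:
        R, t = kabsch_transform(a, b, align_subset if align_subset is not None else subset)
        a = apply_transform(a, R, t)
    da = a if subset is None else a[subset]
    db = b if subset is None else b[subset]
    return float(np.sqrt(np.mean(np.sum((da - db) ** 2, axis=-1))))


# ---------------------------------------------------------------------------
# Linchpin RMSD against an active-state reference
# ---------------------------------------------------------------------------

@dataclass
class ReferenceComplexModel:
    """Active-state reference: structure + alignment and linchpin selections.

    ``align_selection`` holds the C-alpha atoms of the structured RING core
    used for superposition; ``target_selection`` the heavy atoms of the
    linchpin residue (Lys or Arg) whose displacement is measured.
    """

    structure: Trajectory
    align_selection: AtomSelection
    target_selection: AtomSelection

    def __post_init__(self) -> None:
        if self.structure.n_frames != 1:
            raise ValueError("reference structure must be a single frame")
        if len(self.align_selection) < 3:
            raise ValueError("alignment selection needs at least 3 atoms")
        if len(self.target_selection) == 0:
            raise ValueError("target selection is empty")


def make_reference_model(
    traj: Trajectory,
    target_resid: int,
    target_chain: str | None = None,
    align_spec: str | None = None,
    ring_range: tuple[int, int] | None = None,
) -> ReferenceComplexModel:
    """Build a reference model from a single-frame structure.

    The alignment set is either an explicit selection expression or, when
    ``ring_range`` is given, the C-alpha atoms of residues assigned helix or
    sheet by :func:`assign_secondary_structure` within that range — a
    reproducible, reference-anchored reading of "the secondary structure
    elements of the RING domain"; it is frozen into the returned model.
    """
    if traj.n_frames != 1:
        raise ValueError("reference must be a single-frame trajectory")
    if ring_range is not None:
        ss = assign_secondary_structure(traj)
        structured = {
            (c, r) for (c, r), lab in zip(ss.residues, ss.labels)
            if lab in ("H", "E") and ring_range[0] <= r <= ring_range[1]
        }
        idx = [
            i for i, a in enumerate(traj.topology.atoms)
            if a.name == "CA" and (a.chain_id, a.residue_index) in structured
        ]
        align = AtomSelection(np.asarray(idx), f"CA of H/E residues in {ring_range}")
    elif align_spec is not None:
        align = select_atoms(traj.topology, align_spec)
    else:
        raise ValueError("pass align_spec or ring_range")
    tsel = "heavy" + (f" and chain {target_chain}" if target_chain else "")
    target = select_atoms(traj.topology, f"resid {target_resid} and {tsel}")
    if len(target) == 0:
        raise ValueError(f"target residue {target_resid} has no heavy atoms")
    return ReferenceComplexModel(traj, align, target)


def _match_atoms(ref_top: Topology, frame_top: Topology, indices: Iterable[int]):
    """Map reference atom indices to frame indices by (chain, resid, name)."""
    lut = {
        (a.chain_id, a.residue_index, a.name): i
        for i, a in enumerate(frame_top.atoms)
    }
    ref_idx, frame_idx = [], []
    for i in indices:
        a = ref_top.atoms[i]
        j = lut.get((a.chain_id, a.residue_index, a.name))
        if j is not None:
            ref_idx.append(i)
            frame_idx.append(j)
    return np.asarray(ref_idx, dtype=np.intp), np.asarray(frame_idx, dtype=np.intp)


def linchpin_rmsd(
    frame: Trajectory,
    ref: ReferenceComplexModel,
    frame_index: int = 0,
) -> float:
    """Displacement of the linchpin heavy atoms from the active-state pose.

    The frame is superposed onto the reference on the alignment C-alphas,
    then the RMSD over the intersection (by atom name) of the linchpin heavy
    atoms is computed with no re-alignment.  Name intersection makes the
    measure well defined for Lys -> Arg substitutions at the linchpin.
    """
    return float(linchpin_rmsd_profile(frame, ref)[frame_index])


def linchpin_rmsd_profile(traj: Trajectory, ref: ReferenceComplexModel) -> np.ndarray:
    """Per-frame linchpin RMSD over a whole trajectory."""
    ra, fa = _match_atoms(ref.structure.topology, traj.topology, ref.align_selection.indices)
    if ra.size < len(ref.align_selection):
        raise ValueError("frame is missing alignment atoms present in the reference")
    rt, ft = _match_atoms(ref.structure.topology, traj.topology, ref.target_selection.indices)
    if rt.size == 0:
        raise ValueError("no shared linchpin heavy-atom names between frame and reference")
    ref_coords = ref.structure.coords[0]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        c = traj.coords[f]
        R, t = kabsch_transform(c[fa], ref_coords[ra])
        moved = apply_transform(c[ft], R, t)
        out[f] = np.sqrt(np.mean(np.sum((moved - ref_coords[rt]) ** 2, axis=-1)))
    return out


# ---------------------------------------------------------------------------
# Shrake-Rupley solvent-accessible surface area
# ---------------------------------------------------------------------------

def sphere_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform unit-sphere points (golden-spiral construction)."""
    i = np.arange(n, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


def _atom_radii(top: Topology, radii: dict[str, float]) -> np.ndarray:
    out = np.empty(top.n_atoms)
    for i, a in enumerate(top.atoms):
        r = radii.get(a.element) or radii.get(a.element.capitalize())
        if r is None:
            raise KeyError(f"no van der Waals radius for element {a.element!r}")
        out[i] = r
    return out


def _sasa_frames(
    coords: np.ndarray,        # (F, N, 3)
    radii: np.ndarray,         # (N,)
    target: np.ndarray,        # indices into N
    probe: float,
    n_points: int,
    chunk: int = 256,
) -> np.ndarray:
    """Per-frame, per-target-atom accessible area; all N atoms are blockers."""
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    sp = sphere_points(n_points)
    expanded = radii + probe
    exp2 = expanded**2
    F = coords.shape[0]
    out = np.empty((F, target.size))
    for start in range(0, F, chunk):
        c = coords[start:start + chunk]  # (f, N, 3)
        c_sq = np.sum(c * c, axis=-1)  # (f, N)
        for k, i in enumerate(target):
            pts = c[:, i, None, :] + expanded[i] * sp[None, :, :]  # (f, P, 3)
            # squared point-to-atom distances via |p|^2 + |c|^2 - 2 p.c
            d2 = (
                np.sum(pts * pts, axis=-1)[:, :, None]
                + c_sq[:, None, :]
                - 2.0 * pts @ c.transpose(0, 2, 1)
            )
            d2[:, :, i] = np.inf  # an atom does not bury itself
            buried = np.any(d2 < exp2[None, None, :], axis=-1)  # (f, P)
            frac = 1.0 - buried.mean(axis=-1)
            out[start:start + chunk, k] = 4.0 * np.pi * expanded[i] ** 2 * frac
    return out


def sasa(
    traj: Trajectory,
    frame: int = 0,
    probe: float = 1.4,
    n_points: int = 960,
    radii: dict[str, float] | None = None,
    indices: np.ndarray | None = None,
) -> np.ndarray:
    """Shrake-Rupley per-atom solvent-accessible surface area (Angstrom^2).

    For each atom, the fraction of ``n_points`` quasi-uniform test points on
    its solvent-expanded sphere (radius r + probe) that fall inside no
    neighbour's expanded sphere, times the expanded sphere area.
    """
    r = _atom_radii(traj.topology, radii or BONDI_RADII)
    tgt = np.arange(traj.n_atoms) if indices is None else np.asarray(indices, dtype=np.intp)
    return _sasa_frames(traj.coords[frame:frame + 1], r, tgt, probe, n_points)[0]


def _interface_sidechain_indices(
    top: Topology, interface_residues: Sequence[int], chain: str | None
) -> np.ndarray:
    idx: list[int] = []
    for resid in interface_residues:
        found = [
            i for i, a in enumerate(top.atoms)
            if a.residue_index == resid
            and (chain is None or a.chain_id == chain)
            and a.element != "H"
            and a.name not in BACKBONE_NAMES
        ]
        if not any(
            a.residue_index == resid and (chain is None or a.chain_id == chain)
            for a in top.atoms
        ):
            raise ValueError(f"interface residue {resid} not in topology")
        idx.extend(found)
    return np.asarray(sorted(idx), dtype=np.intp)


def bundle_sasa(
    traj: Trajectory,
    interface_residues: Sequence[int],
    frame: int = 0,
    chain: str | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> float:
    """Summed sidechain-heavy-atom SASA of the interface residue set.

    Any binding-partner chains must be stripped from ``traj`` beforehand
    (:func:`allostate.structio.strip_chains`) so the burial reflects the
    bundle alone.
    """
    return float(
        bundle_sasa_profile(traj, interface_residues, chain=chain,
                            probe=probe, n_points=n_points)[frame]
    )


def bundle_sasa_profile(
    traj: Trajectory,
    interface_residues: Sequence[int],
    chain: str | None = None,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-frame bundle SASA over a whole trajectory (vectorized)."""
    if len(interface_residues) == 0:
        warnings.warn("empty interface residue set; bundle SASA is 0", stacklevel=2)
        return np.zeros(traj.n_frames)
    idx = _interface_sidechain_indices(traj.topology, interface_residues, chain)
    if idx.size == 0:
        warnings.warn("interface residues have no sidechain heavy atoms", stacklevel=2)
        return np.zeros(traj.n_frames)
    r = _atom_radii(traj.topology, BONDI_RADII)
    per_atom = _sasa_frames(traj.coords, r, idx, probe, n_points)
    return per_atom.sum(axis=1)


# ---------------------------------------------------------------------------
# Simplified DSSP
# ---------------------------------------------------------------------------

@dataclass
class SecondaryStructureAssignment:
    """Per-residue labels: H (alpha helix), E (sheet/bridge), C (other)."""

    residues: list[tuple[str, int]]
    labels: np.ndarray

    def fraction(self, which: str) -> float:
        return float(np.mean(self.labels == which))


def _backbone_table(top: Topology):
    table: dict[tuple[str, int], dict[str, int]] = {}
    resname: dict[tuple[str, int], str] = {}
    for i, a in enumerate(top.atoms):
        key = (a.chain_id, a.residue_index)
        if a.name in ("N", "CA", "C", "O", "H"):
            table.setdefault(key, {})[a.name] = i
        else:
            table.setdefault(key, {})
        resname.setdefault(key, a.residue_name)
    return table, resname


def assign_secondary_structure(traj: Trajectory, frame: int = 0) -> SecondaryStructureAssignment:
    """Simplified DSSP assignment for one frame.

    Backbone H-bonds use the Kabsch-Sander energy
    ``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` kcal/mol with a
    bond when ``E < -0.5``; amide hydrogens absent from the topology are
    reconstructed on the bisector of (N - C_prev) and (N - CA) at 1.01 A.
    Helix: residues i..i+3 where 4-turns (i-1 -> i+3) and (i -> i+4) both
    close.  Sheet: minimal parallel/antiparallel bridge rules.  Residues
    with missing backbone atoms are labelled C with a warning.
    """
    coords = traj.coords[frame]
    table, resname = _backbone_table(traj.topology)
    keys = sorted(table, key=lambda k: (k[0], k[1]))
    n = len(keys)
    labels = np.array(["C"] * n, dtype="<U1")

    def pos(key, name):
        i = table[key].get(name)
        return None if i is None else coords[i]

    complete = np.zeros(n, dtype=bool)
    for i, key in enumerate(keys):
        have = table[key]
        if all(name in have for name in ("N", "CA", "C", "O")):
            complete[i] = True
        else:
            warnings.warn(f"residue {key} missing backbone atoms; labelled C", stacklevel=2)

    # donor hydrogens (none for prolines or chain-initial residues)
    h_pos: list[np.ndarray | None] = [None] * n
    for i, key in enumerate(keys):
        if not complete[i] or resname[key] == "PRO":
            continue
        if "H" in table[key]:
            h_pos[i] = coords[table[key]["H"]]
            continue
        prev = (key[0], key[1] - 1)
        if prev not in table or "C" not in table[prev]:
            continue
        npos, capos = pos(key, "N"), pos(key, "CA")
        cprev = coords[table[prev]["C"]]
        d1 = npos - cprev
        d2 = npos - capos
        d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        h_pos[i] = npos + 1.01 * d / np.linalg.norm(d)

    hbond = np.zeros((n, n), dtype=bool)  # hbond[i, j]: CO of i accepts NH of j
    for i, ki in enumerate(keys):
        if not complete[i]:
            continue
        c_i, o_i = pos(ki, "C"), pos(ki, "O")
        for j, kj in enumerate(keys):
            if not complete[j] or h_pos[j] is None:
                continue
            if ki[0] == kj[0] and abs(ki[1] - kj[1]) < 2:
                continue
            n_j, hj = pos(kj, "N"), h_pos[j]
            r_on = np.linalg.norm(o_i - n_j)
            r_ch = np.linalg.norm(c_i - hj)
            r_oh = np.linalg.norm(o_i - hj)
            r_cn = np.linalg.norm(c_i - n_j)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                hbond[i, j] = True  # clash: treat as bonded per Kabsch-Sander
                continue
            e = _HB_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            hbond[i, j] = e < _HB_ENERGY_CUTOFF

    def same_chain(i, j):
        return 0 <= i < n and 0 <= j < n and keys[i][0] == keys[j][0]

    turn4 = np.zeros(n, dtype=bool)
    for i in range(n - 4):
        if same_chain(i, i + 4) and keys[i + 4][1] - keys[i][1] == 4:
            turn4[i] = hbond[i, i + 4]
    helix = np.zeros(n, dtype=bool)
    for i in range(1, n - 3):
        if turn4[i - 1] and turn4[i]:
            helix[i:i + 4] = True
    labels[helix] = "H"

    for i in range(n):
        for j in range(i + 3, n):
            if same_chain(i, j) and abs(keys[i][1] - keys[j][1]) < 3:
                continue
            para = (
                (0 <= i - 1 and j + 0 < n and hbond[i - 1, j] and i + 1 < n and hbond[j, i + 1])
                or (0 <= j - 1 and hbond[j - 1, i] and j + 1 < n and hbond[i, j + 1])
            )
            anti = (
                (hbond[i, j] and hbond[j, i])
                or (0 <= i - 1 and j + 1 < n and 0 <= j - 1 and i + 1 < n
                    and hbond[i - 1, j + 1] and hbond[j - 1, i + 1])
            )
            if para or anti:
                for k in (i, j):
                    if labels[k] == "C":
                        labels[k] = "E"
    return SecondaryStructureAssignment(keys, labels)


def structured_probability(
    sample: EnsembleSample,
    trajectories: Sequence[Trajectory],
) -> "pd.DataFrame":
    """Per-residue probability of being structured (helix or sheet).

    Computed over an equilibrium sample; repeated frames are weighted by
    their multiplicity (assignments are cached per unique frame).
    """
    import pandas as pd

    trajs = dict(enumerate(trajectories))
    uniq, counts = np.unique(sample.entries, axis=0, return_counts=True)
    acc: dict[tuple[str, int], float] = {}
    total = 0.0
    for (tid, fidx), w in zip(uniq, counts):
        ss = assign_secondary_structure(trajs[int(tid)], frame=int(fidx))
        for key, lab in zip(ss.residues, ss.labels):
            acc[key] = acc.get(key, 0.0) + w * (lab in ("H", "E"))
        total += w
    rows = [
        {"chain": c, "resid": r, "p_structured": v / total}
        for (c, r), v in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hydrogen-bond geometry
# ---------------------------------------------------------------------------

def hbond_present(
    donor: np.ndarray,
    hydrogen: np.ndarray,
    acceptor: np.ndarray,
    d_max: float = 2.5,
    angle_min: float = 120.0,
) -> bool:
    """Geometric H-bond: H...A distance < d_max and D-H...A angle > angle_min.

    The angle boundary is half-open (strictly greater passes).  Defaults
    (2.5 A, 120 degrees) are a common moderately permissive criterion.
    """
    donor = np.asarray(donor, dtype=np.float64)
    hydrogen = np.asarray(hydrogen, dtype=np.float64)
    acceptor = np.asarray(acceptor, dtype=np.float64)
    if np.linalg.norm(hydrogen - acceptor) >= d_max:
        return False
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return bool(angle > angle_min)
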