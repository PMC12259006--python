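"""Synthetic generators with planted ground truth.

Every pipeline stage is validated against data whose answer is known by
construction: discrete Markov jump dynamics with a known transition matrix,
Gaussian state emissions for the TICA/clustering/MSM chain, an ideal-helix
backbone fixture for dihedral and secondary-structure code, and a toy
"allosteric" coordinate ensemble in which a latent open/closed bundle
variable controls both interface burial (SASA) and the displacement of a
linchpin residue, with a tunable coupling and a mutation-shift parameter.

The toy linchpin displacement per frame is

    disp = max(0, delta + (1 - g * [z = open]) * base + Normal(0, sigma))

so with coupling ``g = 1`` the open (primed) bundle pulls the linchpin into
its reference pose, a positive mutation shift ``delta`` pushes it away in
both bundle states (pathogenic-like), and ``g = 0`` with negative ``delta``
gives near-identical priming in both states (hyperactive-like).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import FeatureDescriptor, FeatureMatrix
from .structio import Atom, AtomSelection, Topology, Trajectory
from .structmetrics import ReferenceComplexModel

__all__ = [
    "PlantedKinetics",
    "ToyAllostericParams",
    "ToyAllostericResult",
    "DEFAULT_SCENARIOS",
    "TOY_INTERFACE_RESIDUES",
    "sample_markov_chain",
    "emit_features",
    "generate_toy_allosteric",
    "generate_ideal_helix",
    "generate_attribution_dataset",
]


# ---------------------------------------------------------------------------
# Discrete Markov dynamics and Gaussian emissions
# ---------------------------------------------------------------------------

def _check_stochastic(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, dtype=np.float64)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("transition matrix must be square")
    if np.any(T < 0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return T


@dataclass
class PlantedKinetics:
    """A known transition matrix with per-state Gaussian feature emissions."""

    transition_matrix: np.ndarray
    means: np.ndarray        # (k, d)
    covariances: np.ndarray  # (k, d, d), SPD or zero
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = _check_stochastic(self.transition_matrix)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=np.float64))
        self.covariances = np.asarray(self.covariances, dtype=np.float64)
        k = self.transition_matrix.shape[0]
        if self.means.shape[0] != k or self.covariances.shape[0] != k:
            raise ValueError("emission count must match state count")


def sample_markov_chain(
    T: np.ndarray, n: int, seed: int, init: int | None = None
) -> np.ndarray:
    """Sample an ``n``-step realization of the chain with transition matrix T.

    The initial state is uniform unless ``init`` is given; stepping is exact
    multinomial sampling, reproducible under ``seed``.
    """
    T = _check_stochastic(T)
    if n < 1:
        raise ValueError("n must be >= 1")
    k = T.shape[0]
    rng = np.random.default_rng(seed)
    cum = np.cumsum(T, axis=1)
    states = np.empty(n, dtype=np.int64)
    s = int(rng.integers(k)) if init is None else int(init)
    states[0] = s
    u = rng.random(n - 1)
    for t in range(1, n):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        s = min(s, k - 1)  # guard against u == 1.0 rounding
        states[t] = s
    return states


def emit_features(
    dtraj: np.ndarray, planted: PlantedKinetics, seed: int | None = None
) -> FeatureMatrix:
    """Per-frame Gaussian draws from the visited state's emission model."""
    dtraj = np.asarray(dtraj, dtype=np.int64)
    k, d = planted.means.shape
    if dtraj.max() >= k:
        raise ValueError("discrete trajectory references unknown states")
    rng = np.random.default_rng(planted.seed if seed is None else seed)
    # PSD matrix square roots (handles exactly-zero covariance)
    roots = np.empty_like(planted.covariances)
    for s in range(k):
        ev, U = np.linalg.eigh(planted.covariances[s])
        if np.any(ev < -1e-10):
            raise ValueError(f"emission covariance of state {s} is not PSD")
        roots[s] = (U * np.sqrt(np.clip(ev, 0, None))) @ U.T
    z = rng.standard_normal((dtraj.size, d))
    vals = planted.means[dtraj] + np.einsum("nij,nj->ni", roots[dtraj], z)
    descs = [FeatureDescriptor("synthetic", (), f"emission_{j}") for j in range(d)]
    return FeatureMatrix(vals, descs)


# ---------------------------------------------------------------------------
# Toy allosteric coordinate ensemble
# ---------------------------------------------------------------------------

#: interface residue ids of the toy bundle (five per pseudo-helix)
TOY_INTERFACE_RESIDUES: tuple[int, ...] = tuple(range(1, 11))

#: planted mutant scenarios mirroring wild-type, loss-of-function and
#: constitutively-primed behaviour
DEFAULT_SCENARIOS: dict[str, dict[str, float]] = {
    "WT": {"mutation_shift": 0.0, "coupling": 1.0},
    "pathogenic": {"mutation_shift": 2.0, "coupling": 1.0},
    "hyperactive": {"mutation_shift": -1.0, "coupling": 0.0},
}


@dataclass
class ToyAllostericParams:
    """Parameters of the toy coupled bundle/linchpin generator.

    ``p_primed`` is the marginal probability of the open (primed) bundle
    state; ``coupling`` (g >= 0) is how strongly an open bundle pulls the
    linchpin into its reference pose; ``mutation_shift`` (Angstrom) is added
    to the linchpin displacement in both states; ``base_displacement`` is the
    unprimed linchpin offset; ``noise`` is the displacement noise SD.
    """

    n_frames: int = 5_000
    p_primed: float = 0.5
    coupling: float = 1.0
    mutation_shift: float = 0.0
    noise: float = 0.5
    base_displacement: float = 3.0
    open_angle: float = 50.0     # hinge opening of the primed bundle, degrees
    angle_noise: float = 1.0     # hinge-angle jitter SD, degrees
    jitter: float = 0.02         # isotropic coordinate jitter SD, Angstrom
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_primed < 1.0:
            raise ValueError("p_primed must be in (0, 1)")
        if self.noise <= 0:
            raise ValueError("noise must be positive")
        if self.coupling < 0:
            raise ValueError("coupling must be >= 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


_HELIX_SPACING = 3.8
_CB_OFFSET = 1.7
_HELIX_B_Y = 6.8
_HINGE_PIVOT = np.array([-3.0, 3.4, 0.0])
_LINCHPIN_DIR = np.array([0.0, -0.8, 0.6])  # unit displacement direction

# linchpin (LYS) heavy atoms in the reference (primed) pose
_LINCHPIN_ATOMS = [
    ("N", "N", (-4.0, -4.0, 0.0)),
    ("CA", "C", (-2.9, -4.9, 0.0)),
    ("C", "C", (-1.6, -4.2, 0.3)),
    ("O", "O", (-1.6, -3.0, 0.5)),
    ("CB", "C", (-3.1, -6.0, 1.1)),
    ("CG", "C", (-2.0, -7.0, 1.3)),
    ("CD", "C", (-2.3, -8.1, 2.3)),
    ("CE", "C", (-1.2, -9.1, 2.5)),
    ("NZ", "N", (-1.5, -10.2, 3.4)),
]

_SCAFFOLD_CA = [(0.0, -11.0, -6.0), (4.0, -11.0, -6.0), (2.0, -8.0, -9.0)]


def _toy_topology() -> Topology:
    atoms: list[Atom] = []
    serial = 1
    for r in range(1, 11):  # two pseudo-helices, hydrophobic sidechain beads
        for name in ("CA", "CB"):
            atoms.append(Atom(serial, name, "C", r, "LEU", "A"))
            serial += 1
    for name, element, _ in _LINCHPIN_ATOMS:
        atoms.append(Atom(serial, name, element, 15, "LYS", "A"))
        serial += 1
    for r in (20, 21, 22):
        atoms.append(Atom(serial, "CA", "C", r, "GLY", "A"))
        serial += 1
    return Topology(atoms)


def _toy_frame(hinge_angle_deg: float, linchpin_disp: float) -> np.ndarray:
    """Ideal toy coordinates at a given hinge opening and linchpin offset."""
    coords: list[np.ndarray] = []
    for k in range(5):  # helix A, fixed
        x = k * _HELIX_SPACING
        coords.append(np.array([x, 0.0, 0.0]))
        coords.append(np.array([x, _CB_OFFSET, 0.0]))
    th = np.radians(hinge_angle_deg)
    rot = np.array([[np.cos(th), -np.sin(th), 0.0],
                    [np.sin(th), np.cos(th), 0.0],
                    [0.0, 0.0, 1.0]])
    for k in range(5):  # helix B, rotated about the hinge pivot
        x = k * _HELIX_SPACING
        for y in (_HELIX_B_Y, _HELIX_B_Y - _CB_OFFSET):
            p = np.array([x, y, 0.0])
            coords.append(rot @ (p - _HINGE_PIVOT) + _HINGE_PIVOT)
    shift = linchpin_disp * _LINCHPIN_DIR / np.linalg.norm(_LINCHPIN_DIR)
    for _, _, xyz in _LINCHPIN_ATOMS:
        coords.append(np.asarray(xyz) + shift)
    for xyz in _SCAFFOLD_CA:
        coords.append(np.asarray(xyz))
    return np.array(coords)


@dataclass
class ToyAllostericResult:
    trajectory: Trajectory
    truth: pd.DataFrame
    reference: ReferenceComplexModel
    interface_residues: tuple[int, ...] = TOY_INTERFACE_RESIDUES


def toy_reference_model(params: ToyAllostericParams | None = None) -> ReferenceComplexModel:
    """Active-state reference for the toy system: open bundle, primed linchpin."""
    params = params or ToyAllostericParams()
    top = _toy_topology()
    ref = Trajectory(top, _toy_frame(params.open_angle, 0.0)[None, :, :])
    align_idx = [i for i, a in enumerate(top.atoms) if a.residue_index in (20, 21, 22)]
    target_idx = [i for i, a in enumerate(top.atoms) if a.residue_index == 15]
    return ReferenceComplexModel(
        ref,
        AtomSelection(np.asarray(align_idx), "resid 20-22 and name CA"),
        AtomSelection(np.asarray(target_idx), "resid 15 and heavy"),
    )


def generate_toy_allosteric(params: ToyAllostericParams) -> ToyAllostericResult:
    """Generate a toy ensemble with coupled bundle openness and linchpin pose.

    Per frame a latent state ``z`` (open with probability ``p_primed``) sets
    the hinge angle; the linchpin displacement follows the rule in the module
    docstring.  Returns the trajectory, a per-frame ground-truth table
    (latent state, true displacement, hinge angle) and the matching
    active-state reference model.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_frames
    z_open = rng.random(n) < params.p_primed
    angles = np.where(z_open, params.open_angle, 0.0) + rng.normal(0, params.angle_noise, n)
    disp = np.maximum(
        0.0,
        params.mutation_shift
        + (1.0 - params.coupling * z_open) * params.base_displacement
        + rng.normal(0, params.noise, n),
    )
    top = _toy_topology()
    coords = np.empty((n, top.n_atoms, 3))
    for f in range(n):
        coords[f] = _toy_frame(float(angles[f]), float(disp[f]))
    coords += rng.normal(0, params.jitter, coords.shape)
    traj = Trajectory(top, coords)
    truth = pd.DataFrame(
        {"frame": np.arange(n), "primed": z_open, "displacement": disp,
         "hinge_angle": angles}
    )
    return ToyAllostericResult(traj, truth, toy_reference_model(params))


# ---------------------------------------------------------------------------
# Ideal helix backbone fixture
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.5


def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension (NeRF) placement of atom D from A-B-C internal coords."""
    ang = np.radians(angle_deg)
    tor = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm /= np.linalg.norm(nrm)
    m = np.cross(nrm, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * nrm


def generate_ideal_helix(n_res: int, phi: float = -57.0, psi: float = -47.0) -> Trajectory:
    """Build an ideal poly-Ala backbone with the given (phi, psi) torsions.

    Standard bond lengths and angles; omega fixed trans (180 degrees); amide
    hydrogens reconstructed on the N bisector for residues after the first.
    """
    if n_res < 6:
        raise ValueError("n_res must be >= 6")
    bb: list[dict[str, np.ndarray]] = []
    ang0 = np.radians(_ANGLE_N_CA_C)
    r0 = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([_BOND_N_CA, 0.0, 0.0]),
    }
    # place C so that the N-CA-C angle is correct, in the xy plane
    r0["C"] = r0["CA"] + _BOND_CA_C * np.array(
        [np.cos(np.pi - ang0), np.sin(np.pi - ang0), 0.0]
    )
    bb.append(r0)
    for i in range(1, n_res):
        prev = bb[-1]
        n_next = _place_atom(prev["N"], prev["CA"], prev["C"], _BOND_C_N, _ANGLE_CA_C_N, psi)
        ca_next = _place_atom(prev["CA"], prev["C"], n_next, _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        c_next = _place_atom(prev["C"], n_next, ca_next, _BOND_CA_C, _ANGLE_N_CA_C, phi)
        bb.append({"N": n_next, "CA": ca_next, "C": c_next})
    # carbonyl oxygens: torsion N-CA-C-O = psi + 180
    for i, res in enumerate(bb):
        res["O"] = _place_atom(res["N"], res["CA"], res["C"], _BOND_C_O, _ANGLE_CA_C_O, psi + 180.0)
    # amide hydrogens on the (N-Cprev, N-CA) bisector
    for i in range(1, n_res):
        npos, capos = bb[i]["N"], bb[i]["CA"]
        cprev = bb[i - 1]["C"]
        d1 = npos - cprev
        d2 = npos - capos
        d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
        bb[i]["H"] = npos + 1.01 * d / np.linalg.norm(d)

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    serial = 1
    elements = {"N": "N", "CA": "C", "C": "C", "O": "O", "H": "H"}
    for i, res in enumerate(bb):
        for name in ("N", "CA", "C", "O", "H"):
            if name not in res:
                continue
            atoms.append(Atom(serial, name, elements[name], i + 1, "ALA", "A"))
            coords.append(res[name])
            serial += 1
    return Trajectory(Topology(atoms), np.array(coords)[None, :, :])


# ---------------------------------------------------------------------------
# Attribution benchmark: one informative distance among noise
# ---------------------------------------------------------------------------

def generate_attribution_dataset(
    n_frames: int = 1_000,
    n_noise: int = 50,
    shift: float = 3.0,
    noise_sd: float = 0.5,
    baseline: float = 10.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, int, list[str]]:
    """Two ensembles differing in exactly one planted inter-atomic distance.

    Returns ``(distances_a, distances_b, informative_index, names)``: each
    matrix is ``n_frames x (n_noise + 1)``; only the informative column's
    mean differs (by ``shift`` Angstrom) between the ensembles.
    """
    rng = np.random.default_rng(seed)
    d = n_noise + 1
    informative = int(rng.integers(d))
    Xa = rng.normal(baseline, noise_sd, size=(n_frames, d))
    Xb = rng.normal(baseline, noise_sd, size=(n_frames, d))
    Xb[:, informative] += shift
    names = [f"dist_{j}" for j in range(d)]
    return np.abs(Xa), np.abs(Xb), informative, names
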