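"""Structural-dynamics descriptors from protein trajectories.

Ten per-frame descriptors are computed from a (protein-only) trajectory:
radius of gyration, solvent-accessible surface area (Shrake–Rupley),
RMSD after optimal superposition against a wild-type reference, the trace of
the inertia tensor, a pairwise-energy stability surrogate, inter-residue
contact count, hydrogen-bond count, and three-state secondary-structure
fractions (helix / sheet / coil) from backbone hydrogen-bond patterns.

Per-variant model inputs are the per-frame series averaged over a stable
window of the trajectory, selected where the series have locally converged.
All distances are in Angstrom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._elements import (
    ATOMIC_MASS,
    DEFAULT_MASS,
    DEFAULT_VDW,
    ELEMENT_CHARGE,
    LJ_PARAMS,
    ROLE_CHARGE,
    VDW_RADIUS,
)

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "rg",
    "sasa",
    "rmsd",
    "inertia",
    "stability",
    "contacts",
    "hbonds",
    "helix_frac",
    "sheet_frac",
    "coil_frac",
)

BACKBONE_ROLES = ("N", "CA", "C", "O", "H", "sidechain", "none")


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    residue_index: int  # 1-based
    residue_name: str
    mass: float = 0.0
    vdw_radius: float = 0.0
    backbone_role: str = "none"

    def __post_init__(self) -> None:
        if self.mass <= 0:
            object.__setattr__(
                self, "mass", ATOMIC_MASS.get(self.element, DEFAULT_MASS)
            )
        if self.vdw_radius <= 0:
            object.__setattr__(
                self, "vdw_radius", VDW_RADIUS.get(self.element, DEFAULT_VDW)
            )
        if self.backbone_role not in BACKBONE_ROLES:
            raise ValueError(f"unknown backbone role {self.backbone_role!r}")


@dataclass
class Trajectory:
    """Topology plus per-frame coordinates (T, N, 3) in Angstrom."""

    topology: list[AtomRecord]
    frames: np.ndarray
    frame_interval_ps: float = 10.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (T, N, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError("frame atom count does not match topology")
        if not np.isfinite(self.frames).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.topology])

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.topology])


# ---------------------------------------------------------------------------
# per-frame descriptors
# ---------------------------------------------------------------------------


def radius_of_gyration(frame: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted RMS distance of atoms from their centre of mass."""
    frame = np.asarray(frame, float)
    masses = np.asarray(masses, float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * frame).sum(axis=0) / total
    sq = ((frame - com) ** 2).sum(axis=1)
    return float(np.sqrt((masses * sq).sum() / total))


def kabsch_rotation(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Optimal proper rotation and translations aligning mobile onto reference.

    Returns (R, mobile_centroid, reference_centroid) such that
    ``(mobile - mc) @ R + rc`` best fits the reference in the least-squares
    sense. A reflection in the SVD solution is corrected to keep R a proper
    rotation.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape:
        raise ValueError("selections must have identical shapes")
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mc = mobile.mean(axis=0)
    rc = reference.mean(axis=0)
    h = (mobile - mc).T @ (reference - rc)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate (collinear) geometry for superposition")
    d = np.sign(np.linalg.det(u @ vt))
    corr = np.diag([1.0, 1.0, d])
    r = u @ corr @ vt
    return r, mc, rc


def superpose_rmsd(
    frame: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> float:
    """RMSD over a selection after optimal rigid-body superposition."""
    frame = np.asarray(frame, float)
    reference = np.asarray(reference, float)
    if selection is not None:
        frame = frame[selection]
        reference = reference[selection]
    r, mc, rc = kabsch_rotation(frame, reference)
    fitted = (frame - mc) @ r + rc
    return float(np.sqrt(((fitted - reference) ** 2).sum(axis=1).mean()))


def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points via the golden-section spiral."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _molecular_frame(frame: np.ndarray) -> np.ndarray:
    """Rotation-covariant orthonormal frame from the coordinate covariance.

    Expressing the sampling grid in this frame makes the point-sampled SASA
    independent of the molecule's global orientation. Eigenvector signs are
    fixed against the centroid-to-farthest-atom vector so the frame co-rotates
    with the coordinates.
    """
    centred = frame - frame.mean(axis=0)
    if len(frame) < 2:
        return np.eye(3)
    cov = centred.T @ centred
    _, vecs = np.linalg.eigh(cov)
    far = centred[np.argmax((centred**2).sum(axis=1))]
    for k in range(3):
        s = vecs[:, k] @ far
        if s < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 0] = -vecs[:, 0]
    return vecs


def sasa_shrake_rupley(
    frame: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake–Rupley solvent-accessible surface area.

    Each atom is covered by ``n_points`` quasi-uniform points on a sphere of
    radius (vdw + probe); a point strictly inside any other atom's expanded
    sphere is buried. Returns (total, per-atom) areas in square Angstrom.
    """
    frame = np.asarray(frame, float)
    radii = np.asarray(radii, float)
    if probe < 0:
        raise ValueError("probe radius must be non-negative")
    if n_points < 12:
        raise ValueError("need at least 12 sphere points")
    if (radii <= 0).any():
        raise ValueError("van der Waals radii must be positive")
    expanded = radii + probe
    unit = _sphere_points(n_points) @ _molecular_frame(frame).T
    n = len(frame)
    per_atom = np.zeros(n)
    tree = cKDTree(frame)
    max_r = expanded.max()
    for i in range(n):
        pts = frame[i] + expanded[i] * unit
        neighbours = tree.query_ball_point(frame[i], expanded[i] + max_r)
        neighbours = [j for j in neighbours if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - frame[j]) ** 2).sum(axis=1)
            accessible &= d2 >= expanded[j] ** 2  # strictly inside is buried
        per_atom[i] = (
            accessible.sum() / n_points * 4.0 * np.pi * expanded[i] ** 2
        )
    return float(per_atom.sum()), per_atom


def inertia_tensor(frame: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """3x3 inertia tensor about the centre of mass (amu * A^2)."""
    frame = np.asarray(frame, float)
    masses = np.asarray(masses, float)
    total = masses.sum()
    if total <= 0:
        raise ValueError("total mass must be positive")
    com = (masses[:, None] * frame).sum(axis=0) / total
    rel = frame - com
    sq = (rel**2).sum(axis=1)
    eye = np.eye(3)
    tensor = (
        masses[:, None, None]
        * (sq[:, None, None] * eye - rel[:, :, None] * rel[:, None, :])
    ).sum(axis=0)
    return tensor


def inertia_scalar(frame: np.ndarray, masses: np.ndarray) -> float:
    """Trace of the inertia tensor (sum of the three principal moments)."""
    return float(np.trace(inertia_tensor(frame, masses)))


def count_contacts(
    frame: np.ndarray,
    topology: list[AtomRecord],
    cutoff: float = 5.0,
    min_seq_separation: int = 3,
) -> int:
    """Residue pairs whose closest heavy-atom distance is within the cutoff.

    Pairs (i, j) with |i - j| >= ``min_seq_separation`` count once.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    heavy = np.array([a.element != "H" for a in topology])
    coords = np.asarray(frame, float)[heavy]
    resid = np.array([a.residue_index for a in topology])[heavy]
    if len(coords) == 0:
        return 0
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return 0
    ri = resid[pairs[:, 0]]
    rj = resid[pairs[:, 1]]
    eligible = np.abs(ri - rj) >= min_seq_separation
    contact_pairs = {
        (min(a, b), max(a, b)) for a, b in zip(ri[eligible], rj[eligible])
    }
    return len(contact_pairs)


def _donor_hydrogens(
    frame: np.ndarray, topology: list[AtomRecord], bond_cutoff: float = 1.25
) -> list[tuple[int, np.ndarray]]:
    """(donor heavy atom index, H position) pairs.

    Explicit hydrogens are attached to the nearest N/O within the covalent
    cutoff; backbone amide hydrogens missing from the topology are rebuilt
    1.01 A from N, opposite the bisector of its bonded heavy neighbours
    (previous C and own CA).
    """
    coords = np.asarray(frame, float)
    heavy_no = [i for i, a in enumerate(topology) if a.element in ("N", "O")]
    pairs: list[tuple[int, np.ndarray]] = []
    donors_with_h: set[int] = set()
    for i, a in enumerate(topology):
        if a.element != "H":
            continue
        best, best_d = -1, np.inf
        for j in heavy_no:
            d = np.linalg.norm(coords[i] - coords[j])
            if d < best_d:
                best, best_d = j, d
        if best >= 0 and best_d <= bond_cutoff:
            pairs.append((best, coords[i]))
            donors_with_h.add(best)

    # rebuild missing backbone amide hydrogens
    by_res: dict[int, dict[str, int]] = {}
    for i, a in enumerate(topology):
        if a.backbone_role in ("N", "CA", "C"):
            by_res.setdefault(a.residue_index, {})[a.backbone_role] = i
    for res, atoms in by_res.items():
        n_idx = atoms.get("N")
        if n_idx is None or n_idx in donors_with_h:
            continue
        ca_idx = atoms.get("CA")
        prev = by_res.get(res - 1, {})
        c_prev = prev.get("C")
        if ca_idx is None or c_prev is None:
            continue  # chain start: no amide H
        if topology[n_idx].residue_name == "PRO":
            continue
        n = coords[n_idx]
        u1 = coords[ca_idx] - n
        u1 /= np.linalg.norm(u1)
        u2 = coords[c_prev] - n
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        norm = np.linalg.norm(bis)
        if norm < 1e-9:
            continue
        h = n - 1.01 * bis / norm
        pairs.append((n_idx, h))
    return pairs


def count_hbonds(
    frame: np.ndarray,
    topology: list[AtomRecord],
    dist_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> int:
    """Hydrogen bonds by geometric criteria.

    A donor (N/O carrying a hydrogen) and an acceptor (N/O in a different
    residue) are bonded when the donor-to-acceptor heavy-atom distance is at
    most ``dist_cutoff`` and the D-H...A angle is at least ``angle_cutoff``
    degrees.
    """
    coords = np.asarray(frame, float)
    if any(not a.element for a in topology):
        raise ValueError("topology lacks element assignments")
    acceptors = [i for i, a in enumerate(topology) if a.element in ("N", "O")]
    donors = _donor_hydrogens(frame, topology)
    cos_cut = np.cos(np.deg2rad(angle_cutoff))
    count = 0
    counted: set[tuple[int, int]] = set()
    for d_idx, h_pos in donors:
        d_res = topology[d_idx].residue_index
        for a_idx in acceptors:
            if a_idx == d_idx or topology[a_idx].residue_index == d_res:
                continue
            da = np.linalg.norm(coords[d_idx] - coords[a_idx])
            if da > dist_cutoff:
                continue
            v1 = coords[d_idx] - h_pos
            v2 = coords[a_idx] - h_pos
            n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
            if n1 < 1e-9 or n2 < 1e-9:
                continue
            cos_ang = np.dot(v1, v2) / (n1 * n2)
            # angle >= cutoff  <=>  cos(angle) <= cos(cutoff)
            if cos_ang <= cos_cut + 1e-12:
                key = (d_idx, a_idx)
                if key not in counted:
                    counted.add(key)
                    count += 1
    return count


# ---------------------------------------------------------------------------
# secondary structure (DSSP-style, 3-state)
# ---------------------------------------------------------------------------

_Q = 0.084 * 332.0  # kcal/mol * A, electrostatic H-bond energy prefactor
_HB_ENERGY_CUT = -0.5


def _backbone_indices(topology: list[AtomRecord]) -> dict[int, dict[str, int]]:
    out: dict[int, dict[str, int]] = {}
    for i, a in enumerate(topology):
        if a.backbone_role in ("N", "CA", "C", "O", "H"):
            out.setdefault(a.residue_index, {})[a.backbone_role] = i
    return out


def _bb_hbond_matrix(
    frame: np.ndarray, topology: list[AtomRecord], strict: bool
) -> tuple[np.ndarray, list[int], np.ndarray]:
    """Boolean matrix hb[i, j]: N-H of residue i donates to C=O of residue j."""
    coords = np.asarray(frame, float)
    by_res = _backbone_indices(topology)
    residues = sorted(by_res)
    missing = [
        r for r in residues if not {"N", "CA", "C", "O"} <= set(by_res[r])
    ]
    if missing:
        if strict:
            raise ValueError(f"missing backbone atoms for residues {missing}")
        warnings.warn(
            f"residues {missing} lack full backbones; assigned coil", stacklevel=2
        )
    nres = len(residues)
    ok = np.array([{"N", "CA", "C", "O"} <= set(by_res[r]) for r in residues])
    # hydrogen positions per residue (explicit or rebuilt); None at chain start
    hpos: list[np.ndarray | None] = []
    for k, r in enumerate(residues):
        atoms = by_res[r]
        if "H" in atoms:
            hpos.append(coords[atoms["H"]])
            continue
        prev = by_res.get(r - 1, {})
        if not ok[k] or "C" not in prev or topology[atoms["N"]].residue_name == "PRO":
            hpos.append(None)
            continue
        n = coords[atoms["N"]]
        u1 = coords[atoms["CA"]] - n
        u2 = coords[prev["C"]] - n
        u1 /= np.linalg.norm(u1)
        u2 /= np.linalg.norm(u2)
        bis = u1 + u2
        norm = np.linalg.norm(bis)
        hpos.append(None if norm < 1e-9 else n - 1.01 * bis / norm)

    hb = np.zeros((nres, nres), dtype=bool)
    for i in range(nres):
        if not ok[i] or hpos[i] is None:
            continue
        n = coords[by_res[residues[i]]["N"]]
        h = hpos[i]
        for j in range(nres):
            if abs(i - j) < 2 or not ok[j]:
                continue
            c = coords[by_res[residues[j]]["C"]]
            o = coords[by_res[residues[j]]["O"]]
            r_on = np.linalg.norm(o - n)
            r_ch = np.linalg.norm(c - h)
            r_oh = np.linalg.norm(o - h)
            r_cn = np.linalg.norm(c - n)
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:
                continue  # clashing geometry; no physical bond
            energy = _Q * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if energy < _HB_ENERGY_CUT:
                hb[i, j] = True
    return hb, residues, ok


def assign_secondary_structure(
    frame: np.ndarray,
    topology: list[AtomRecord],
    strict: bool = False,
) -> tuple[list[str], tuple[float, float, float]]:
    """Three-state secondary structure from backbone hydrogen-bond patterns.

    Backbone H-bonds use the DSSP electrostatic energy
    ``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` kcal/mol with a
    bond when E < -0.5. Consecutive n-turns (n = 3, 4, 5) define helices,
    bridges define sheet, everything else is coil; the 8-state scheme is
    collapsed to {H, G, I} -> helix, {E, B} -> sheet, rest -> coil.

    Returns per-residue labels ('H'/'E'/'C') and the (helix, sheet, coil)
    fractions, which always sum to 1.
    """
    hb, residues, ok = _bb_hbond_matrix(frame, topology, strict)
    nres = len(residues)
    labels = np.full(nres, "C", dtype="<U1")

    def turn(i: int, n: int) -> bool:
        # n-turn at i: C=O of i accepts from N-H of i+n
        return i + n < nres and hb[i + n, i]

    helix = np.zeros(nres, dtype=bool)
    for n in (4, 3, 5):
        for i in range(1, nres - n):
            if turn(i, n) and turn(i - 1, n):
                helix[i : i + n] = True

    sheet = np.zeros(nres, dtype=bool)
    for i in range(1, nres - 1):
        for j in range(i + 3, nres - 1):
            parallel = (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i])
            antiparallel = (hb[i, j] and hb[j, i]) or (
                hb[i + 1, j - 1] and hb[j + 1, i - 1]
            )
            if parallel or antiparallel:
                sheet[i] = sheet[j] = True

    labels[sheet & ~helix] = "E"
    labels[helix] = "H"
    labels[~ok] = "C"
    labels = labels.tolist()
    n = len(labels)
    if n == 0:
        raise ValueError("no residues with backbone atoms")
    h = labels.count("H") / n
    e = labels.count("E") / n
    c = labels.count("C") / n
    return labels, (h, e, c)


# ---------------------------------------------------------------------------
# stability surrogate
# ---------------------------------------------------------------------------

GAMMA_SASA = 0.00542  # kcal/mol/A^2 surface tension term


@dataclass
class StabilityParams:
    """Per-element LJ parameters and charges for the stability surrogate."""

    lj: dict = field(default_factory=lambda: dict(LJ_PARAMS))
    role_charge: dict = field(default_factory=lambda: dict(ROLE_CHARGE))
    element_charge: dict = field(default_factory=lambda: dict(ELEMENT_CHARGE))
    gamma: float = GAMMA_SASA

    def charge(self, atom: AtomRecord) -> float:
        if atom.backbone_role in self.role_charge:
            return self.role_charge[atom.backbone_role]
        return self.element_charge.get(atom.element, 0.0)


def stability_surrogate(
    frame: np.ndarray,
    topology: list[AtomRecord],
    params: StabilityParams | None = None,
    sasa_total: float | None = None,
    pair_cutoff: float = 12.0,
) -> float:
    """Pairwise nonbonded energy plus a surface term: a stability proxy.

    ``E = sum over pairs separated by >= 2 residues of
    4*eps*((sigma/r)^12 - (sigma/r)^6) + 332*qi*qj/(4*r*r)  +  gamma * SASA``.

    This is a monotonic stability proxy (lower is more stable), not an
    MM-GBSA free energy. Lorentz-Berthelot mixing combines per-element LJ
    parameters; the Coulomb term uses a distance-dependent dielectric 4r.
    """
    params = params or StabilityParams()
    frame = np.asarray(frame, float)
    for a in topology:
        if a.element not in params.lj:
            raise ValueError(f"no LJ parameters for element {a.element!r}")
    eps = np.array([params.lj[a.element][0] for a in topology])
    sig = np.array([params.lj[a.element][1] for a in topology])
    q = np.array([params.charge(a) for a in topology])
    resid = np.array([a.residue_index for a in topology])

    tree = cKDTree(frame)
    pairs = tree.query_pairs(pair_cutoff, output_type="ndarray")
    energy = 0.0
    if len(pairs):
        i, j = pairs[:, 0], pairs[:, 1]
        sep_ok = np.abs(resid[i] - resid[j]) >= 2
        i, j = i[sep_ok], j[sep_ok]
        if len(i):
            r = np.linalg.norm(frame[i] - frame[j], axis=1)
            e_ij = np.sqrt(eps[i] * eps[j])
            s_ij = 0.5 * (sig[i] + sig[j])
            sr6 = (s_ij / r) ** 6
            lj = 4.0 * e_ij * (sr6 * sr6 - sr6)
            coul = 332.0 * q[i] * q[j] / (4.0 * r * r)
            energy = float((lj + coul).sum())
    if sasa_total is None:
        radii = np.array([a.vdw_radius for a in topology])
        sasa_total, _ = sasa_shrake_rupley(frame, radii)
    return energy + params.gamma * sasa_total


# ---------------------------------------------------------------------------
# stable-window selection and summary
# ---------------------------------------------------------------------------


def select_stable_window(
    series_matrix: np.ndarray,
    window_fraction: float = 0.25,
    alpha: float = 0.75,
    majority_fraction: float = 0.7,
) -> tuple[int, int]:
    """Latest window where a majority of features have locally converged.

    A window of length ``max(5, floor(window_fraction * T))`` is stable for a
    feature when its standard deviation is at most ``alpha`` times that
    feature's full-series standard deviation. The latest window stable for at
    least ``ceil(majority_fraction * n_features)`` features is returned as
    inclusive (start, end) frame indices. If none qualifies, the last half of
    the trajectory is used.
    """
    m = np.asarray(series_matrix, float)
    if m.ndim == 1:
        m = m[:, None]
    t, nf = m.shape
    if t < 10:
        warnings.warn("fewer than 10 frames: using the whole series", stacklevel=2)
        return 0, t - 1
    w = max(5, int(window_fraction * t))
    full_std = m.std(axis=0)
    need = int(np.ceil(majority_fraction * nf))
    for start in range(t - w, -1, -1):
        win_std = m[start : start + w].std(axis=0)
        if (win_std <= alpha * full_std + 1e-15).sum() >= need:
            return start, start + w - 1
    return int(np.ceil(t / 2)), t - 1


@dataclass
class FeatureConfig:
    """Tunable parameters of the descriptor extraction."""

    sasa_probe: float = 1.4
    sasa_points: int = 960
    contact_cutoff: float = 5.0
    contact_min_seq_separation: int = 3
    hbond_dist_cutoff: float = 3.5
    hbond_angle_cutoff: float = 120.0
    rmsd_selection: str = "backbone"  # backbone heavy atoms
    window_fraction: float = 0.25
    window_alpha: float = 0.75
    window_majority_fraction: float = 0.7
    stability_params: StabilityParams = field(default_factory=StabilityParams)


@dataclass
class FeatureSeries:
    """Per-frame values of the ten descriptors (each series has length T)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(FEATURE_NAMES) - set(self.data.columns)
        if missing:
            raise ValueError(f"missing feature series: {sorted(missing)}")
        frac_sum = (
            self.data["helix_frac"] + self.data["sheet_frac"] + self.data["coil_frac"]
        )
        if not np.allclose(frac_sum, 1.0, atol=1e-9):
            raise ValueError("secondary-structure fractions must sum to 1")


@dataclass
class FeatureVector:
    """The ten descriptors averaged over the stable trajectory window."""

    values: dict
    window_start: int
    window_end: int

    def __post_init__(self) -> None:
        if self.window_start > self.window_end:
            raise ValueError("window_start must not exceed window_end")
        for frac in ("helix_frac", "sheet_frac", "coil_frac"):
            if not 0.0 <= self.values[frac] <= 1.0 + 1e-12:
                raise ValueError(f"{frac} outside [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series({k: self.values[k] for k in FEATURE_NAMES})


def _rmsd_selection_mask(topology: list[AtomRecord], selection: str) -> np.ndarray:
    if selection == "backbone":
        mask = np.array(
            [a.backbone_role in ("N", "CA", "C", "O") for a in topology]
        )
        if mask.sum() >= 3:
            return mask
    return np.ones(len(topology), dtype=bool)


def summarize_features(
    trajectory: Trajectory,
    reference: np.ndarray,
    config: FeatureConfig | None = None,
) -> tuple[FeatureSeries, FeatureVector]:
    """Compute all ten per-frame series, select the stable window, average.

    ``reference`` is a single (N, 3) coordinate set (the wild-type structure)
    used for the RMSD series.
    """
    config = config or FeatureConfig()
    topo = trajectory.topology
    masses = trajectory.masses
    radii = trajectory.radii
    sel = _rmsd_selection_mask(topo, config.rmsd_selection)
    rows = []
    for f in trajectory.frames:
        sasa_total, _ = sasa_shrake_rupley(
            f, radii, probe=config.sasa_probe, n_points=config.sasa_points
        )
        _, (h, e, c) = assign_secondary_structure(f, topo)
        rows.append(
            {
                "rg": radius_of_gyration(f, masses),
                "sasa": sasa_total,
                "rmsd": superpose_rmsd(f, reference, sel),
                "inertia": inertia_scalar(f, masses),
                "stability": stability_surrogate(
                    f, topo, config.stability_params, sasa_total=sasa_total
                ),
                "contacts": count_contacts(
                    f, topo, config.contact_cutoff, config.contact_min_seq_separation
                ),
                "hbonds": count_hbonds(
                    f, topo, config.hbond_dist_cutoff, config.hbond_angle_cutoff
                ),
                "helix_frac": h,
                "sheet_frac": e,
                "coil_frac": c,
            }
        )
    series = FeatureSeries(pd.DataFrame(rows, columns=list(FEATURE_NAMES)))
    if trajectory.n_frames == 1:
        start, end = 0, 0
    else:
        start, end = select_stable_window(
            series.data.to_numpy(),
            config.window_fraction,
            config.window_alpha,
            config.window_majority_fraction,
        )
    means = series.data.iloc[start : end + 1].mean()
    vector = FeatureVector(values=means.to_dict(), window_start=start, window_end=end)
    return series, vector


def zscore_scale(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, tuple[pd.Series, pd.Series]]:
    """Column-wise z-scoring; returns the scaled table and (means, stds).

    Zero-variance columns map to 0 (with a warning); the returned parameters
    allow applying the same transform to held-out data.
    """
    if len(table) == 0:
        raise ValueError("empty feature table")
    if len(table) < 2:
        raise ValueError("need at least 2 rows to scale")
    means = table.mean()
    stds = table.std(ddof=0)
    zero = stds == 0
    if zero.any():
        warnings.warn(
            f"zero-variance columns scaled to 0: {list(table.columns[zero])}",
            stacklevel=2,
        )
    safe = stds.replace(0.0, 1.0)
    scaled = (table - means) / safe
    scaled.loc[:, zero] = 0.0
    return scaled, (means, stds)


def zscore_apply(
    table: pd.DataFrame, means: pd.Series, stds: pd.Series
) -> pd.DataFrame:
    """Apply previously fitted scaling parameters to new data."""
    safe = stds.replace(0.0, 1.0)
    scaled = (table - means) / safe
    scaled.loc[:, stds == 0] = 0.0
    return scaled


def zscore_invert(
    scaled: pd.DataFrame, means: pd.Series, stds: pd.Series
) -> pd.DataFrame:
    """Invert a z-score transform (zero-variance columns return the mean)."""
    return scaled * stds + means
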