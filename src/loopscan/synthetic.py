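"""Synthetic ground-truth data generation.

Every pipeline stage is testable without external downloads because this
module generates its inputs with known ground truth:

* closed loop-conformer ensembles — an ideal-geometry backbone is built
  in torsion space (NeRF), perturbed around a native reference and
  re-closed onto the fixed C-anchor with cyclic coordinate descent
  (CCD); per-pose pseudo-energies are a linear function of the RMSD to
  the native reference plus Gaussian noise, so score/RMSD funnels have a
  known shape;
* planted polar contacts — a Bernoulli(f) subset of poses has a chosen
  atom pair adjusted into contact range, the realised subset being
  recorded, so contact-frequency estimators can be checked exactly;
* noisy kinetic datasets — Michaelis-Menten, competitive-inhibition,
  hyperbolic-binding and linear progress-curve data with multiplicative
  Gaussian noise around known parameters.

CCD is a deliberately simple, well-defined closure algorithm used here
as the ensemble sampler; it makes no claim to emulate any particular
loop-modelling protocol's conformational distribution, only to produce
valid closed ensembles with controllable spread.  Side chains are
represented by CB only; the contact statistics downstream use heavy-atom
N/O/CB distances.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as bst
from biotite.structure import AtomArray

from .numbering import LoopDefinition
from .structure import ConformerEnsemble, atom_sort_order
from .variants import DeletionVariant

logger = logging.getLogger(__name__)

# Ideal backbone geometry (Engh-Huber-style standard values)
IDEAL_GEOMETRY = {
    "n_ca": 1.458,       # A
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ca_cb": 1.521,
    "ang_n_ca_c": 111.2,  # degrees
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
    "ang_n_ca_cb": 110.4,
    "tor_c_n_ca_cb": -122.6,
    "omega": 180.0,
}

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}


class ClosureError(RuntimeError):
    """Loop generation failed to close often enough."""


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF placement: position D from atoms A-B-C plus internal coordinates.

    ``bond`` = |C-D|, ``angle_deg`` = angle(B,C,D),
    ``torsion_deg`` = dihedral(A,B,C,D).
    """
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(np.degrees(np.arctan2(y, x)))


@dataclass
class LoopGeometrySpec:
    """Geometry specification for synthetic loop construction."""

    sequence: str
    anchor_n_frame: np.ndarray | None = None   # (3,3): N,CA,C of N-anchor residue
    geometry: dict = field(default_factory=lambda: dict(IDEAL_GEOMETRY))
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("loop sequence must have at least one residue")


class BackboneChain:
    """Torsion-parameterised mainchain: anchor residue + loop N/CA/C atoms.

    The chain starts at a fixed N-anchor residue frame (its N, CA, C
    coordinates never move) and carries, per loop residue i, atoms
    N_i, CA_i, C_i, followed by a two-atom extension (N_next, CA_next)
    towards the C anchor.  The free torsions, in chain order, are::

        psi_anchor, phi_1, psi_1, ..., phi_n, psi_n

    (2n+1 torsions for n loop residues; the two extension atoms are
    placed with psi_n and a fixed omega).  Rebuilding from torsions and
    rotating about a torsion axis are the only coordinate operations, so
    bond lengths and bond angles are invariant by construction.
    """

    def __init__(
        self,
        n_res: int,
        anchor_frame: np.ndarray,
        geometry: dict | None = None,
    ):
        self.n_res = n_res
        self.anchor = np.asarray(anchor_frame, dtype=float)
        if self.anchor.shape != (3, 3):
            raise ValueError("anchor frame must be a (3,3) array of N,CA,C")
        self.geo = dict(IDEAL_GEOMETRY) if geometry is None else dict(geometry)
        self.torsions = np.zeros(2 * n_res + 1)
        # mainchain coordinate array: anchor N,CA,C + n_res*(N,CA,C) + N_next,CA_next
        self.coords = np.zeros((3 + 3 * n_res + 2, 3))
        self.coords[:3] = self.anchor

    @property
    def n_torsions(self) -> int:
        return self.torsions.size

    def _idx(self, res: int, atom: int) -> int:
        """Index of atom (0=N,1=CA,2=C) of loop residue ``res`` (0-based)."""
        return 3 + 3 * res + atom

    @property
    def extension_indices(self) -> tuple[int, int]:
        n = self._idx(self.n_res - 1, 2)
        return n + 1, n + 2

    @property
    def anchor_atom_indices(self) -> list[int]:
        """Indices of the closure anchor atoms: C_last, N_next, CA_next."""
        nn, can = self.extension_indices
        return [self._idx(self.n_res - 1, 2), nn, can]

    def rebuild(self, torsions: np.ndarray | None = None) -> None:
        """Rebuild all mobile coordinates from the torsion vector."""
        if torsions is not None:
            self.torsions = np.asarray(torsions, dtype=float).copy()
        g = self.geo
        t = self.torsions
        x = self.coords
        a, b, c = 0, 1, 2  # N,CA,C of previous residue
        ti = 0
        for r in range(self.n_res):
            # N_r from psi of previous residue
            x[self._idx(r, 0)] = place_atom(
                x[a], x[b], x[c], g["c_n"], g["ang_ca_c_n"], t[ti]
            )
            # CA_r via omega
            x[self._idx(r, 1)] = place_atom(
                x[b], x[c], x[self._idx(r, 0)],
                g["n_ca"], g["ang_c_n_ca"], g["omega"],
            )
            # C_r via phi_r
            x[self._idx(r, 2)] = place_atom(
                x[c], x[self._idx(r, 0)], x[self._idx(r, 1)],
                g["ca_c"], g["ang_n_ca_c"], t[ti + 1],
            )
            a, b, c = self._idx(r, 0), self._idx(r, 1), self._idx(r, 2)
            ti += 2
        # extension: N_next from psi_last, CA_next via omega
        nn, can = self.extension_indices
        x[nn] = place_atom(x[a], x[b], x[c], g["c_n"], g["ang_ca_c_n"], t[ti])
        x[can] = place_atom(
            x[b], x[c], x[nn], g["n_ca"], g["ang_c_n_ca"], g["omega"]
        )

    def _axis_for_torsion(self, ti: int) -> tuple[np.ndarray, np.ndarray, int]:
        """Rotation axis (point, unit vector) and first moving atom index."""
        if ti == 0:
            b, c = self.anchor[1], self.anchor[2]  # CA->C of anchor
            first_moving = 3
        else:
            res = (ti - 1) // 2
            if (ti - 1) % 2 == 0:  # phi: N->CA
                b = self.coords[self._idx(res, 0)]
                c = self.coords[self._idx(res, 1)]
                first_moving = self._idx(res, 2)
            else:  # psi: CA->C
                b = self.coords[self._idx(res, 1)]
                c = self.coords[self._idx(res, 2)]
                first_moving = self._idx(res + 1, 0) if res + 1 < self.n_res \
                    else self.extension_indices[0]
        u = c - b
        u = u / np.linalg.norm(u)
        return b, u, first_moving

    def rotate_torsion(self, ti: int, delta_deg: float) -> None:
        """Rotate all downstream atoms about torsion ``ti`` by ``delta_deg``."""
        point, u, first = self._axis_for_torsion(ti)
        theta = np.radians(delta_deg)
        moving = self.coords[first:] - point
        # Rodrigues rotation
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        rotated = (
            moving * cos_t
            + np.cross(u, moving) * sin_t
            + np.outer(moving @ u, u) * (1.0 - cos_t)
        )
        self.coords[first:] = rotated + point
        self.torsions[ti] += delta_deg

    def anchor_rmsd(self, target: np.ndarray) -> float:
        m = self.coords[self.anchor_atom_indices]
        return float(np.sqrt(((m - target) ** 2).sum(axis=1).mean()))

    def bond_vectors(self) -> np.ndarray:
        """Lengths of all consecutive mainchain bonds (invariance checks)."""
        return np.linalg.norm(np.diff(self.coords, axis=0), axis=1)


def _ccd_core(coords, axis_b, axis_c, first_moving, anchor_ids, target,
              max_iter, tol):
    """CCD sweeps over static torsion metadata; mutates ``coords`` in place.

    Returns (torsion deltas in radians, converged flag).  Written with
    scalar loops so it can be numba-compiled; the pure-Python path is the
    fallback.
    """
    n_t = axis_b.shape[0]
    n_atoms = coords.shape[0]
    deltas = np.zeros(n_t)
    tol2 = tol * tol * 3.0  # compare summed squared deviation of 3 atoms
    for _sweep in range(max_iter):
        s = 0.0
        for k in range(3):
            i = anchor_ids[k]
            dx = coords[i, 0] - target[k, 0]
            dy = coords[i, 1] - target[k, 1]
            dz = coords[i, 2] - target[k, 2]
            s += dx * dx + dy * dy + dz * dz
        if s < tol2:
            return deltas, True
        for ti in range(n_t):
            bx = coords[axis_b[ti], 0]
            by = coords[axis_b[ti], 1]
            bz = coords[axis_b[ti], 2]
            ux = coords[axis_c[ti], 0] - bx
            uy = coords[axis_c[ti], 1] - by
            uz = coords[axis_c[ti], 2] - bz
            norm = (ux * ux + uy * uy + uz * uz) ** 0.5
            ux /= norm
            uy /= norm
            uz /= norm
            first = first_moving[ti]
            a_sum = 0.0
            b_sum = 0.0
            for k in range(3):
                i = anchor_ids[k]
                if i < first:
                    continue
                rx = coords[i, 0] - bx
                ry = coords[i, 1] - by
                rz = coords[i, 2] - bz
                dot_ru = rx * ux + ry * uy + rz * uz
                px = rx - dot_ru * ux
                py = ry - dot_ru * uy
                pz = rz - dot_ru * uz
                s_len = (px * px + py * py + pz * pz) ** 0.5
                if s_len < 1e-10:
                    continue
                rhx = px / s_len
                rhy = py / s_len
                rhz = pz / s_len
                shx = uy * rhz - uz * rhy
                shy = uz * rhx - ux * rhz
                shz = ux * rhy - uy * rhx
                fx = target[k, 0] - bx
                fy = target[k, 1] - by
                fz = target[k, 2] - bz
                fdotu = fx * ux + fy * uy + fz * uz
                fpx = fx - fdotu * ux
                fpy = fy - fdotu * uy
                fpz = fz - fdotu * uz
                a_sum += s_len * (fpx * rhx + fpy * rhy + fpz * rhz)
                b_sum += s_len * (fpx * shx + fpy * shy + fpz * shz)
            if a_sum == 0.0 and b_sum == 0.0:
                continue
            theta = np.arctan2(b_sum, a_sum)
            if abs(theta) < 1e-14:
                continue
            cos_t = np.cos(theta)
            sin_t = np.sin(theta)
            for j in range(first, n_atoms):
                rx = coords[j, 0] - bx
                ry = coords[j, 1] - by
                rz = coords[j, 2] - bz
                dot = rx * ux + ry * uy + rz * uz
                crx = uy * rz - uz * ry
                cry = uz * rx - ux * rz
                crz = ux * ry - uy * rx
                omc = 1.0 - cos_t
                coords[j, 0] = bx + rx * cos_t + crx * sin_t + ux * dot * omc
                coords[j, 1] = by + ry * cos_t + cry * sin_t + uy * dot * omc
                coords[j, 2] = bz + rz * cos_t + crz * sin_t + uz * dot * omc
            deltas[ti] += theta
    s = 0.0
    for k in range(3):
        i = anchor_ids[k]
        dx = coords[i, 0] - target[k, 0]
        dy = coords[i, 1] - target[k, 1]
        dz = coords[i, 2] - target[k, 2]
        s += dx * dx + dy * dy + dz * dz
    return deltas, s < tol2


try:  # optional JIT acceleration; the pure-Python core is the fallback
    from numba import njit

    _ccd_core_fast = njit(cache=True)(_ccd_core)
except Exception:  # pragma: no cover - numba present in supported envs
    _ccd_core_fast = _ccd_core


def ccd_close(
    chain: BackboneChain,
    target: np.ndarray,
    max_iter: int = 1000,
    tol: float = 0.1,
) -> tuple[BackboneChain, bool]:
    """Close a chain onto a fixed C-anchor with cyclic coordinate descent.

    Sweeps the free torsions N-to-C; for each, applies the closed-form
    rotation angle that minimises the summed squared distance of the
    three anchor atoms (C of the last loop residue, N and CA of the next
    body residue) to their ``target`` positions.  Torsion-only moves keep
    all bond lengths and bond angles exactly invariant.

    Returns the (mutated) chain and a convergence flag: anchor-atom RMSD
    below ``tol`` within ``max_iter`` sweeps.
    """
    target = np.asarray(target, dtype=float)
    if target.shape != (3, 3):
        raise ValueError("closure target must be (3,3): C_last, N_next, CA_next")
    if chain.anchor_rmsd(target) < tol:
        return chain, True
    n_t = chain.n_torsions
    axis_b = np.empty(n_t, dtype=np.int64)
    axis_c = np.empty(n_t, dtype=np.int64)
    first_moving = np.empty(n_t, dtype=np.int64)
    for ti in range(n_t):
        if ti == 0:
            axis_b[ti], axis_c[ti], first_moving[ti] = 1, 2, 3
        else:
            res = (ti - 1) // 2
            if (ti - 1) % 2 == 0:  # phi: N->CA
                axis_b[ti] = chain._idx(res, 0)
                axis_c[ti] = chain._idx(res, 1)
                first_moving[ti] = chain._idx(res, 2)
            else:  # psi: CA->C
                axis_b[ti] = chain._idx(res, 1)
                axis_c[ti] = chain._idx(res, 2)
                first_moving[ti] = (
                    chain._idx(res + 1, 0)
                    if res + 1 < chain.n_res
                    else chain.extension_indices[0]
                )
    anchor_ids = np.asarray(chain.anchor_atom_indices, dtype=np.int64)
    deltas, converged = _ccd_core_fast(
        chain.coords, axis_b, axis_c, first_moving, anchor_ids, target,
        max_iter, tol,
    )
    chain.torsions += np.degrees(deltas)
    return chain, bool(converged)


def build_ideal_backbone(
    sequence: str, spec: LoopGeometrySpec | None = None
) -> AtomArray:
    """Extended-chain backbone (N, CA, C, O per residue, CB except Gly).

    The chain starts at the spec's N-anchor frame (default: a canonical
    frame at the origin) with extended-strand torsions (phi -140, psi 135).
    """
    if spec is None:
        spec = LoopGeometrySpec(sequence=sequence)
    if not sequence:
        raise ValueError("empty sequence")
    anchor = spec.anchor_n_frame
    if anchor is None:
        anchor = _canonical_anchor_frame(spec.geometry)
    n = len(sequence)
    chain = BackboneChain(n, anchor, spec.geometry)
    torsions = np.empty(2 * n + 1)
    torsions[0] = 135.0
    torsions[1::2] = -140.0  # phi
    torsions[2::2] = 135.0   # psi
    chain.rebuild(torsions)
    return chain_to_atom_array(
        chain, sequence, first_res_id=1, chain_id="A"
    )


def _canonical_anchor_frame(geo: dict) -> np.ndarray:
    """An N,CA,C frame at the origin with ideal internal geometry."""
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([geo["n_ca"], 0.0, 0.0])
    ang = np.radians(geo["ang_n_ca_c"])
    c = ca + geo["ca_c"] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    return np.stack([n, ca, c])


def chain_to_atom_array(
    chain: BackboneChain,
    sequence: str,
    first_res_id: int,
    chain_id: str = "A",
    res_ids: list[int] | None = None,
) -> AtomArray:
    """Render a mainchain as an AtomArray with O and CB placed analytically.

    O_i is placed anti to the following amide nitrogen (torsion psi+180);
    CB from the local N/CA/C frame.  Only loop residues are emitted, not
    the anchor or the extension atoms.
    """
    g = chain.geo
    if res_ids is None:
        res_ids = list(range(first_res_id, first_res_id + chain.n_res))
    if len(res_ids) != chain.n_res or len(sequence) != chain.n_res:
        raise ValueError("sequence / residue-id length mismatch")
    atoms = []
    x = chain.coords
    for r, (aa, rid) in enumerate(zip(sequence, res_ids)):
        n_i = x[chain._idx(r, 0)]
        ca_i = x[chain._idx(r, 1)]
        c_i = x[chain._idx(r, 2)]
        psi = chain.torsions[2 * r + 2]
        o_i = place_atom(n_i, ca_i, c_i, g["c_o"], g["ang_ca_c_o"], psi + 180.0)
        res_atoms = [("N", n_i), ("CA", ca_i), ("C", c_i), ("O", o_i)]
        if aa != "G":
            cb = place_atom(
                c_i, n_i, ca_i, g["ca_cb"], g["ang_n_ca_cb"],
                g["tor_c_n_ca_cb"],
            )
            res_atoms.append(("CB", cb))
        for name, coord in res_atoms:
            atoms.append((rid, AA3[aa], name, coord))
    arr = AtomArray(len(atoms))
    arr.coord = np.array([a[3] for a in atoms], dtype=np.float32)
    arr.chain_id = np.array([chain_id] * len(atoms))
    arr.res_id = np.array([a[0] for a in atoms], dtype=int)
    arr.res_name = np.array([a[1] for a in atoms])
    arr.atom_name = np.array([a[2] for a in atoms])
    arr.element = np.array([a[2][0] for a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    return arr


@dataclass
class SyntheticEnsembleSpec:
    """Study conditions for synthetic conformer ensembles.

    Defaults emulate the packaged example's modelling setup: 250 poses
    per variant, dihedral perturbation of 25 degrees around the native
    reference, closure tolerance 0.1 A, and pseudo-energies
    score = slope * RMSD_to_native + Normal(0, score_noise) in REU.
    """

    n_poses: int = 250
    dihedral_sigma_deg: float = 25.0
    closure_tol: float = 0.1
    max_iter: int = 1000
    score_slope: float = 1.0      # REU per Angstrom
    score_noise: float = 0.2      # REU
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_poses < 1:
            raise ValueError("n_poses must be >= 1")
        if self.closure_tol <= 0:
            raise ValueError("closure tolerance must be positive")


@dataclass
class SyntheticBody:
    """Fixed synthetic protease body shared by all poses of a scan.

    Holds the static atoms (cofactor-binding helix, C-side anchor strand,
    contact-shelf residues), the N-anchor frame the loop grows from, the
    C-anchor closure target, and the wild-type native loop torsions.
    """

    atoms: AtomArray
    anchor_n_frame: np.ndarray
    closure_target: np.ndarray
    native_torsions: dict[int, float]   # per loop residue id: (phi, psi) pairs
    helix_span: tuple[int, int]


def _rigid_residue_template(aa: str, geo: dict) -> tuple[list[str], np.ndarray]:
    """Ideal-geometry single residue (N, CA, C, O, CB) at a canonical frame."""
    frame = _canonical_anchor_frame(geo)
    n, ca, c = frame
    o = place_atom(n, ca, c, geo["c_o"], geo["ang_ca_c_o"], -45.0)
    names = ["N", "CA", "C", "O"]
    coords = [n, ca, c, o]
    if aa != "G":
        cb = place_atom(c, n, ca, geo["ca_cb"], geo["ang_n_ca_cb"],
                        geo["tor_c_n_ca_cb"])
        names.append("CB")
        coords.append(cb)
    return names, np.array(coords)


def _place_template_atom_at(
    names: list[str], coords: np.ndarray, atom: str,
    position: np.ndarray, away_from: np.ndarray,
) -> np.ndarray:
    """Translate/orient a rigid residue template so ``atom`` sits at
    ``position`` with the residue body pointing away from ``away_from``."""
    i = names.index(atom)
    centered = coords - coords[i]
    out_dir = position - away_from
    out_dir = out_dir / np.linalg.norm(out_dir)
    body_dir = centered.mean(axis=0)
    norm = np.linalg.norm(body_dir)
    if norm > 1e-9:
        body_dir = body_dir / norm
        v = np.cross(body_dir, out_dir)
        c = float(np.dot(body_dir, out_dir))
        if np.linalg.norm(v) > 1e-9:
            vx = np.array(
                [[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]]
            )
            rot = np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))
            centered = centered @ rot.T
    return centered + position


def _helix_chain(
    sequence: str, geo: dict, anchor: np.ndarray
) -> BackboneChain:
    n = len(sequence)
    chain = BackboneChain(n, anchor, geo)
    torsions = np.empty(2 * n + 1)
    torsions[0] = -47.0
    torsions[1::2] = -57.0
    torsions[2::2] = -47.0
    chain.rebuild(torsions)
    return chain


# Body layout constants for the packaged synthetic system (full-length
# numbering of the FVIIa fixture): helix 305-310, loop 311-321, C-side
# strand 322-324, contact shelf 366 (Q), 372 (G), 373 (H), 374 (F).
BODY_HELIX_SPAN = (305, 310)
BODY_HELIX_SEQ = "LMTQDC"
BODY_CSIDE_SPAN = (322, 324)
BODY_CSIDE_SEQ = "NIT"
SHELF_RESIDUES = ((366, "Q"), (372, "G"), (373, "H"), (374, "F"))
LOOP_SEQ_WT = "LQQSRKVGDSP"  # residues 311-321
LOOP_FIRST_RES = 311


def _native_wt_torsions(rng: np.random.Generator, n_res: int) -> np.ndarray:
    """Deterministic native torsion vector for the wild-type loop.

    Hairpin-like: two extended strands around a central turn, so the loop
    folds back on itself and the anchor separation stays small enough for
    heavily truncated variants to re-close onto the same body anchors.
    """
    torsions = np.empty(2 * n_res + 1)
    torsions[0] = 120.0
    mid = n_res // 2
    for r in range(n_res):
        if r == mid - 1:
            phi, psi = -60.0, -30.0    # turn position i+1
        elif r == mid:
            phi, psi = -120.0, -30.0   # turn position i+2
        else:
            phi, psi = -130.0, 135.0   # extended strand
        torsions[1 + 2 * r] = phi + rng.uniform(-8, 8)
        torsions[2 + 2 * r] = psi + rng.uniform(-8, 8)
    return torsions


def build_synthetic_body(seed: int = 0) -> SyntheticBody:
    """Construct the fixed synthetic protease body and native WT loop frame.

    Deterministic for a given seed.  The helix is built with canonical
    alpha torsions; the native wild-type loop defines the C-anchor
    closure target (positions of C321, N322, CA322) and the placement of
    the contact shelf: G372's carbonyl O sits 3.0 A from the native
    R315 backbone N (a formed hydrogen bond), H373/F374 flank the native
    D319 CB at 3.2-3.4 A.
    """
    geo = dict(IDEAL_GEOMETRY)
    rng = np.random.default_rng(seed)

    helix_anchor = _canonical_anchor_frame(geo)
    helix = _helix_chain(BODY_HELIX_SEQ, geo, helix_anchor)
    helix_arr = chain_to_atom_array(
        helix, BODY_HELIX_SEQ, first_res_id=BODY_HELIX_SPAN[0]
    )
    # loop grows from the last helix residue's N,CA,C frame
    last = helix.n_res - 1
    n_anchor = np.stack(
        [
            helix.coords[helix._idx(last, 0)],
            helix.coords[helix._idx(last, 1)],
            helix.coords[helix._idx(last, 2)],
        ]
    )

    n_loop = len(LOOP_SEQ_WT)
    native = BackboneChain(n_loop, n_anchor, geo)
    native_torsions = _native_wt_torsions(rng, n_loop)
    native.rebuild(native_torsions)
    closure_target = native.coords[native.anchor_atom_indices].copy()

    # C-side strand from the native extension frame
    nn, can = native.extension_indices
    cside_anchor = np.stack(
        [
            native.coords[native._idx(n_loop - 1, 0)],
            native.coords[native._idx(n_loop - 1, 1)],
            native.coords[native._idx(n_loop - 1, 2)],
        ]
    )
    cside = BackboneChain(len(BODY_CSIDE_SEQ), cside_anchor, geo)
    t = np.empty(2 * len(BODY_CSIDE_SEQ) + 1)
    t[0] = native_torsions[-1]
    t[1::2] = -140.0
    t[2::2] = 135.0
    cside.rebuild(t)
    cside_arr = chain_to_atom_array(
        cside, BODY_CSIDE_SEQ, first_res_id=BODY_CSIDE_SPAN[0]
    )

    native_arr = chain_to_atom_array(
        native, LOOP_SEQ_WT, first_res_id=LOOP_FIRST_RES
    )

    def native_atom(res_id: int, name: str) -> np.ndarray:
        m = (native_arr.res_id == res_id) & (native_arr.atom_name == name)
        return native_arr.coord[m][0].astype(float)

    loop_center = native_arr.coord.mean(axis=0).astype(float)
    shelf_targets = {
        366: ("CB", native_atom(317, "CB") + _unit(
            native_atom(317, "CB") - loop_center) * 3.6),
        372: ("O", native_atom(315, "N") + _unit(
            native_atom(315, "N") - loop_center) * 3.0),
        373: ("CB", native_atom(319, "CB") + _unit(
            native_atom(319, "CB") - loop_center) * 3.4),
        374: ("N", native_atom(319, "CB") + _unit(
            np.cross(native_atom(319, "CB") - loop_center,
                     np.array([0.0, 0.0, 1.0]))) * 3.2),
    }
    shelf_atoms = []
    for res_id, aa in SHELF_RESIDUES:
        names, coords = _rigid_residue_template(aa, geo)
        anchor_atom, position = shelf_targets[res_id]
        placed = _place_template_atom_at(
            names, coords, anchor_atom, position, loop_center
        )
        for name, xyz in zip(names, placed):
            shelf_atoms.append((res_id, AA3[aa], name, xyz))
    shelf_arr = AtomArray(len(shelf_atoms))
    shelf_arr.coord = np.array([a[3] for a in shelf_atoms], dtype=np.float32)
    shelf_arr.chain_id = np.array(["A"] * len(shelf_atoms))
    shelf_arr.res_id = np.array([a[0] for a in shelf_atoms], dtype=int)
    shelf_arr.res_name = np.array([a[1] for a in shelf_atoms])
    shelf_arr.atom_name = np.array([a[2] for a in shelf_atoms])
    shelf_arr.element = np.array([a[2][0] for a in shelf_atoms])
    shelf_arr.hetero = np.zeros(len(shelf_atoms), dtype=bool)

    body = helix_arr + cside_arr + shelf_arr

    # native torsion lookup per loop residue id
    nat = {}
    for r, rid in enumerate(range(LOOP_FIRST_RES, LOOP_FIRST_RES + n_loop)):
        nat[rid] = (native_torsions[1 + 2 * r], native_torsions[2 + 2 * r])
    nat["psi_anchor"] = native_torsions[0]

    return SyntheticBody(
        atoms=body,
        anchor_n_frame=n_anchor,
        closure_target=closure_target,
        native_torsions=nat,
        helix_span=BODY_HELIX_SPAN,
    )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


@dataclass
class EnsembleTruth:
    """Ground-truth record accompanying a synthetic ensemble."""

    seed: int
    native_coords: np.ndarray
    rmsd_to_native: np.ndarray
    scores_clean: np.ndarray
    closure_failures: int
    planted_contacts: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "seed": self.seed,
            "rmsd_to_native": self.rmsd_to_native.tolist(),
            "scores_clean": self.scores_clean.tolist(),
            "closure_failures": self.closure_failures,
            "planted_contacts": {
                k: {
                    "fraction_requested": v["fraction_requested"],
                    "realized_fraction": v["realized_fraction"],
                    "contact_mask": [bool(b) for b in v["contact_mask"]],
                }
                for k, v in self.planted_contacts.items()
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


def _loop_residue_ids(
    loop_def: LoopDefinition, variant: DeletionVariant | None
) -> list[int]:
    lo, hi = loop_def.rebuild_span
    ids = list(range(lo, hi + 1))
    if variant is not None:
        w = variant.window
        ids = [r for r in ids if not (w.start <= r <= w.end)]
    return ids


def _loop_sequence(
    loop_def: LoopDefinition, res_ids: list[int]
) -> str:
    return "".join(loop_def.context_residue(r) for r in res_ids)


def sample_loop_ensemble(
    spec: SyntheticEnsembleSpec,
    loop_def: LoopDefinition,
    variant: DeletionVariant | None = None,
    body: SyntheticBody | None = None,
) -> tuple[ConformerEnsemble, EnsembleTruth]:
    """Generate a closed loop-conformer ensemble with known ground truth.

    Each pose perturbs the variant's native torsions by
    Normal(0, dihedral_sigma) and re-closes onto the fixed C-anchor with
    CCD; non-closing draws are resampled.  Pseudo-energies are
    ``score_slope * RMSD_to_native + Normal(0, score_noise)``.  Residue
    numbering keeps wild-type ids with gaps at the deletion window, so
    cross-variant atom addressing stays in full-length coordinates.

    Raises :class:`ClosureError` when more than half of all closure
    attempts fail, which indicates an infeasible tolerance.
    """
    if body is None:
        body = build_synthetic_body(seed=0)
    rng = np.random.default_rng(spec.seed)
    res_ids = _loop_residue_ids(loop_def, variant)
    seq = _loop_sequence(loop_def, res_ids)
    n_res = len(res_ids)
    geo = dict(IDEAL_GEOMETRY)

    def torsion_vector(perturb: float) -> np.ndarray:
        t = np.empty(2 * n_res + 1)
        t[0] = body.native_torsions["psi_anchor"]
        for i, rid in enumerate(res_ids):
            phi, psi = body.native_torsions[rid]
            t[1 + 2 * i] = phi
            t[2 + 2 * i] = psi
        if perturb > 0:
            t = t + rng.normal(0.0, perturb, size=t.size)
        return t

    def close_from(torsions: np.ndarray) -> tuple[BackboneChain, bool]:
        chain = BackboneChain(n_res, body.anchor_n_frame, geo)
        chain.rebuild(torsions)
        return ccd_close(
            chain, body.closure_target,
            max_iter=spec.max_iter, tol=spec.closure_tol,
        )

    # variant native: WT torsion subset re-closed (deterministic)
    native_chain, ok = close_from(torsion_vector(0.0))
    attempts, failures = 1, 0 if ok else 1
    while not ok:
        native_chain, ok = close_from(torsion_vector(spec.dihedral_sigma_deg))
        attempts += 1
        if not ok:
            failures += 1
        if attempts > 50 and failures / attempts > 0.5:
            raise ClosureError(
                "could not establish a native closed conformation; "
                "increase the closure tolerance"
            )
    native_arr = chain_to_atom_array(
        native_chain, seq, first_res_id=0, res_ids=res_ids
    )

    poses = []
    rmsds = np.empty(spec.n_poses)
    for p in range(spec.n_poses):
        while True:
            chain, ok = close_from(
                torsion_vector(spec.dihedral_sigma_deg)
            )
            attempts += 1
            if ok:
                break
            failures += 1
            if attempts > 2 * spec.n_poses and failures / attempts > 0.5:
                raise ClosureError(
                    f"closure failure rate {failures/attempts:.0%} exceeds "
                    "50%; increase the closure tolerance"
                )
        loop_arr = chain_to_atom_array(
            chain, seq, first_res_id=0, res_ids=res_ids
        )
        rmsds[p] = float(
            np.sqrt(
                ((loop_arr.coord - native_arr.coord) ** 2).sum(axis=1).mean()
            )
        )
        pose = body.atoms + loop_arr
        pose = pose[atom_sort_order(pose)]
        poses.append(pose)

    scores_clean = spec.score_slope * rmsds
    scores = scores_clean + rng.normal(0.0, spec.score_noise, size=spec.n_poses)
    stack = bst.stack(poses)
    ensemble = ConformerEnsemble(
        stack=stack,
        scores=scores,
        rebuild_span=loop_def.rebuild_span,
    )
    truth = EnsembleTruth(
        seed=spec.seed,
        native_coords=native_arr.coord.copy(),
        rmsd_to_native=rmsds,
        scores_clean=scores_clean,
        closure_failures=failures,
    )
    return ensemble, truth


def plant_contact_fraction(
    ensemble: ConformerEnsemble,
    pair: tuple[tuple[int, str], tuple[int, str]],
    fraction: float,
    seed: int = 0,
    truth: EnsembleTruth | None = None,
    contact_range: tuple[float, float] = (2.8, 3.3),
    apart_range: tuple[float, float] = (4.6, 6.0),
) -> tuple[ConformerEnsemble, np.ndarray]:
    """Plant a polar contact at a known per-pose Bernoulli(f) realisation.

    For each pose, the first atom of ``pair`` is moved along the line to
    the second so the distance falls inside ``contact_range`` (contact
    poses) or ``apart_range`` (the rest).  The realised contact mask is
    returned and, when a truth record is given, stored on it.  The move
    displaces a single atom and therefore trades local ideal geometry for
    an exactly known contact fraction; it is a statistical truth-maker,
    not a physical model.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    (res_a, name_a), (res_b, name_b) = pair
    ia = ensemble.atom_index(res_a, name_a)
    ib = ensemble.atom_index(res_b, name_b)
    rng = np.random.default_rng(seed)
    n = ensemble.n_poses
    mask = rng.random(n) < fraction
    new_stack = ensemble.stack.copy()
    coords = new_stack.coord
    for p in range(n):
        b = coords[p, ib].astype(float)
        a = coords[p, ia].astype(float)
        direction = a - b
        norm = np.linalg.norm(direction)
        if norm < 1e-9:
            direction = np.array([1.0, 0.0, 0.0])
            norm = 1.0
        direction /= norm
        lo, hi = contact_range if mask[p] else apart_range
        d = rng.uniform(lo, hi)
        coords[p, ia] = b + direction * d
    planted = ConformerEnsemble(
        stack=new_stack,
        scores=ensemble.scores.copy(),
        rebuild_span=ensemble.rebuild_span,
        pose_tags=list(ensemble.pose_tags),
    )
    record = {
        "fraction_requested": float(fraction),
        "realized_fraction": float(mask.mean()),
        "contact_mask": mask,
    }
    if truth is not None:
        key = f"{res_a}.{name_a}-{res_b}.{name_b}"
        truth.planted_contacts[key] = record
    return planted, mask


def gaussian_ensemble(
    base: AtomArray | None = None,
    n_poses: int = 50,
    sigma: float = 0.5,
    seed: int = 0,
    scores: np.ndarray | None = None,
) -> ConformerEnsemble:
    """Isotropic-Gaussian test ensemble: each pose displaces every atom of a
    base structure by iid Normal(0, sigma) per axis.

    The closed-form expectation E[RMSF] -> sigma * sqrt(3) (large N) makes
    this the oracle ensemble for fluctuation statistics.
    """
    if base is None:
        base = build_ideal_backbone("QSRKVGDSP")
    rng = np.random.default_rng(seed)
    n_atoms = base.array_length()
    stacks = []
    for _ in range(n_poses):
        arr = base.copy()
        arr.coord = arr.coord + rng.normal(0, sigma, size=(n_atoms, 3)).astype(
            np.float32
        )
        stacks.append(arr)
    stack = bst.stack(stacks)
    if scores is None:
        scores = np.zeros(n_poses)
    return ConformerEnsemble(stack=stack, scores=np.asarray(scores, float))


# ---------------------------------------------------------------------------
# Kinetics generation


@dataclass
class SyntheticKineticsSpec:
    """Known-truth kinetic parameters and assay designs.

    Defaults mirror the packaged study conditions: substrate titration
    0-12.5 mM (Michaelis-Menten), competitive inhibition at 1 mM fixed
    substrate, cofactor titration 0-3 uM (hyperbolic binding), and
    10-minute linear progress curves read in the first 5 minutes.  Noise
    is multiplicative Gaussian with sigma 2%.
    """

    km_mm: float = 7.2            # mM
    kcat_s: float = 5.0           # 1/s
    ki_um: float = 60.0           # uM
    kd_um: float = 0.1            # uM
    enzyme_conc_nm: float = 50.0  # nM
    v0: float = 0.05              # baseline rate for binding titration
    vmax_binding: float = 1.0     # saturating rate for binding titration
    progress_slope: float = 2.0   # signal/min
    progress_intercept: float = 0.1
    noise_sigma: float = 0.02
    replicates: int = 2
    substrate_grid_mm: tuple = (0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.5)
    inhibitor_grid_um: tuple = (0.0, 10.0, 25.0, 50.0, 100.0, 200.0, 400.0, 800.0)
    titrant_grid_um: tuple = (0.0, 0.025, 0.05, 0.1, 0.25, 0.5, 1.0, 3.0)
    time_grid_min: tuple = tuple(float(t) / 2 for t in range(21))  # 0..10 min
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("km_mm", "kcat_s", "ki_um", "kd_um", "enzyme_conc_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def gen_kinetics(spec: SyntheticKineticsSpec) -> dict:
    """Generate the four assay datasets with embedded ground truth.

    Returns a dict with keys ``michaelis_menten``, ``competitive_ki``,
    ``binding_kd``, ``progress_curve`` (each a :class:`RateSeries`) and
    ``truth`` (the spec itself).  Rates are model predictions times
    (1 + Normal(0, noise_sigma)); replicate series share the design and
    differ only in noise.  Deterministic per seed.
    """
    from .kinetics import RateSeries

    rng = np.random.default_rng(spec.seed)

    def noisy(v: np.ndarray) -> np.ndarray:
        if spec.noise_sigma == 0:
            return v.copy()
        return v * (1.0 + rng.normal(0.0, spec.noise_sigma, size=v.shape))

    vmax = spec.kcat_s * spec.enzyme_conc_nm  # nM/s

    out: dict = {"truth": spec}

    s = np.asarray(spec.substrate_grid_mm, float)
    v_mm = vmax * s / (spec.km_mm + s)
    out["michaelis_menten"] = [
        RateSeries(
            x=s, v=noisy(v_mm), enzyme_conc=spec.enzyme_conc_nm,
            assay="michaelis_menten", replicate=r,
        )
        for r in range(spec.replicates)
    ]

    i = np.asarray(spec.inhibitor_grid_um, float)
    s_fixed = 1.0  # mM
    v_ki = vmax * s_fixed / (spec.km_mm * (1.0 + i / spec.ki_um) + s_fixed)
    out["competitive_ki"] = [
        RateSeries(
            x=i, v=noisy(v_ki), enzyme_conc=spec.enzyme_conc_nm,
            assay="competitive_ki", replicate=r,
            metadata={"s_fixed_mm": s_fixed, "km_mm": spec.km_mm},
        )
        for r in range(spec.replicates)
    ]

    t = np.asarray(spec.titrant_grid_um, float)
    v_kd = spec.v0 + (spec.vmax_binding - spec.v0) * t / (spec.kd_um + t)
    out["binding_kd"] = [
        RateSeries(
            x=t, v=noisy(v_kd), enzyme_conc=spec.enzyme_conc_nm,
            assay="binding_kd", replicate=r,
        )
        for r in range(spec.replicates)
    ]

    tm = np.asarray(spec.time_grid_min, float)
    sig = spec.progress_intercept + spec.progress_slope * tm
    out["progress_curve"] = [
        RateSeries(
            x=tm, v=noisy(sig), enzyme_conc=spec.enzyme_conc_nm,
            assay="progress_curve", replicate=r,
        )
        for r in range(spec.replicates)
    ]
    return out
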