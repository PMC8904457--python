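"""Ensemble geometry statistics for loop-conformer ensembles.

Given an ensemble of N loop conformations built on a fixed protease body,
the questions a deletion scan asks are statistical: how much does the
rebuilt loop fluctuate (RMSF around the ensemble mean structure), does
the score landscape funnel towards a coherent low-energy conformation
(score vs. RMSD-to-best plots), how often does a candidate hydrogen bond
or polar contact form (donor-acceptor distance distributions against
fixed distance windows), and how is the cofactor-binding helix tilted.

All statistics operate in the shared rigid-body frame of the ensemble:
poses are NOT re-superimposed before RMSD/RMSF, because loop rebuilding
keeps the protease body fixed.  :func:`superpose_to_body` is available
for ensembles from other sources that need to be brought into a common
frame first.

Distance conventions follow standard heavy-atom criteria: a candidate
hydrogen bond is called stable when the mean donor-acceptor (N...O)
distance lies in the 2.5-3.8 A window; distance histograms cover
2.5-4.0 A in 0.1 A bins; a polar contact is counted when the per-pose
distance is strictly below 3.5 A.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .numbering import LoopDefinition
from .structure import ConformerEnsemble, Pose, select_atoms
from .variants import DeletionVariant

logger = logging.getLogger(__name__)

HBOND_STABLE_WINDOW = (2.5, 3.8)  # A, window on the mean distance
HBOND_HIST_RANGE = (2.5, 4.0)     # A, histogram range
HBOND_HIST_BIN = 0.1              # A
CONTACT_CUTOFF = 3.5              # A, strict less-than


@dataclass
class MeanStructure:
    """Per-atom mean coordinates of an ensemble selection."""

    coords: np.ndarray            # (n_atoms, 3)
    atom_mask: np.ndarray         # mask over the ensemble atom axis

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class RMSFProfile:
    """Per-atom root-mean-square fluctuation around the mean structure."""

    per_atom: np.ndarray
    average: float
    atom_mask: np.ndarray


@dataclass
class FunnelTable:
    """Per-pose (RMSD to the lowest-scoring pose, score)."""

    table: pd.DataFrame           # columns: pose, rmsd, score
    reference_pose: int           # 0-based index of the lowest-scoring pose

    @property
    def spearman(self) -> float:
        """Spearman correlation between score and RMSD-to-reference."""
        r = spearmanr(self.table["rmsd"], self.table["score"]).statistic
        return float(r)


@dataclass
class ContactSeries:
    """Per-pose distance series for one atom pair."""

    label: str
    atom_a: tuple[int, str]
    atom_b: tuple[int, str]
    distances: np.ndarray

    def contact_frequency(self, cutoff: float = CONTACT_CUTOFF) -> float:
        return contact_frequency(self.distances, cutoff)


@dataclass
class HBondSummary:
    """Summary of one donor-acceptor distance series."""

    mean: float
    sd: float
    stable: bool
    in_range_frequency: float
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    window: tuple[float, float] = HBOND_STABLE_WINDOW
    hist_range: tuple[float, float] = HBOND_HIST_RANGE


@dataclass
class HelixAngleResult:
    """Tilt angle between a helix axis and a base vector."""

    angle_deg: float
    helix_axis: np.ndarray
    base_vector: np.ndarray
    helix_selection: tuple[int, int] = (0, 0)
    base_selections: tuple = ()


def geometric_mean(
    ensemble: ConformerEnsemble,
    residues: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
) -> MeanStructure:
    """Ensemble mean structure: per-atom arithmetic mean of coordinates.

    No re-superposition is applied; the ensemble is assumed to share a
    rigid-body frame.
    """
    mask = ensemble.selection_mask(residues, atom_names)
    coords = ensemble.coords[:, mask, :].astype(np.float64)
    return MeanStructure(coords=coords.mean(axis=0), atom_mask=mask)


def rmsf(
    ensemble: ConformerEnsemble,
    residues: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
) -> RMSFProfile:
    """Per-atom RMSF around the ensemble mean structure.

    RMSF_i = sqrt(mean_n |x_ni - <x_i>|^2).  An ensemble with fewer than
    two poses is degenerate and reports zeros.
    """
    mask = ensemble.selection_mask(residues, atom_names)
    coords = ensemble.coords[:, mask, :].astype(np.float64)
    if ensemble.n_poses < 2:
        logger.warning("RMSF of a single-pose ensemble is degenerate (0)")
        per_atom = np.zeros(coords.shape[1])
    else:
        mean = coords.mean(axis=0, keepdims=True)
        per_atom = np.sqrt(((coords - mean) ** 2).sum(axis=2).mean(axis=0))
    return RMSFProfile(
        per_atom=per_atom, average=float(per_atom.mean()), atom_mask=mask
    )


def rmsd(
    pose_a: Pose,
    pose_b: Pose,
    residues: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
) -> float:
    """RMSD between two poses over a selection, without refitting."""
    a = select_atoms(pose_a, residues, atom_names)
    b = select_atoms(pose_b, residues, atom_names)
    if a.array_length() != b.array_length():
        raise ValueError(
            f"selection size mismatch: {a.array_length()} vs {b.array_length()}"
        )
    if not (
        np.array_equal(a.res_id, b.res_id)
        and np.array_equal(a.atom_name, b.atom_name)
    ):
        raise ValueError("selections cover different atoms")
    da = a.coord.astype(np.float64)
    db = b.coord.astype(np.float64)
    return float(np.sqrt(((da - db) ** 2).sum(axis=1).mean()))


def _pairwise_rmsd_to(
    ensemble: ConformerEnsemble, ref_index: int, mask: np.ndarray
) -> np.ndarray:
    coords = ensemble.coords[:, mask, :].astype(np.float64)
    diff = coords - coords[ref_index][None, :, :]
    return np.sqrt((diff ** 2).sum(axis=2).mean(axis=1))


def funnel(
    ensemble: ConformerEnsemble,
    residues: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
) -> FunnelTable:
    """Score-vs-RMSD funnel relative to the lowest-scoring pose.

    The reference pose is the argmin of the scores (ties break to the
    lowest pose index).  RMSD is computed over the rebuilt-span heavy
    atoms by default (``residues`` falls back to the ensemble's rebuild
    span when set).
    """
    if residues is None:
        residues = ensemble.rebuild_span
    mask = ensemble.selection_mask(residues, atom_names)
    scores = ensemble.scores
    if np.allclose(scores, scores[0]):
        logger.warning("all scores equal; funnel reference set to pose 1")
    ref = int(np.argmin(scores))
    rmsds = _pairwise_rmsd_to(ensemble, ref, mask)
    table = pd.DataFrame(
        {
            "pose": np.arange(ensemble.n_poses),
            "rmsd": rmsds,
            "score": scores,
        }
    )
    return FunnelTable(table=table, reference_pose=ref)


def select_low_energy(ensemble: ConformerEnsemble, n: int) -> list[int]:
    """0-based ids of the n lowest-scoring poses, ties broken by pose index."""
    if n > ensemble.n_poses:
        raise ValueError(f"requested {n} poses from ensemble of {ensemble.n_poses}")
    order = np.lexsort((np.arange(ensemble.n_poses), ensemble.scores))
    return [int(i) for i in order[:n]]


def rmsd_group_representatives(
    ensemble: ConformerEnsemble,
    n_groups: int = 3,
    per_group: int = 5,
    residues: tuple[int, int] | None = None,
) -> list[list[int]]:
    """Low-score representatives from equal-width RMSD bins.

    Poses are binned into ``n_groups`` equal-width intervals over the
    RMSD-to-reference axis of the funnel; within each bin the
    ``per_group`` lowest-scoring poses are returned.  Empty bins yield
    empty groups (they are reported, never back-filled).  A degenerate
    RMSD range (all poses identical) collapses to a single group with a
    warning.
    """
    if n_groups * per_group > ensemble.n_poses:
        raise ValueError(
            f"{n_groups}x{per_group} representatives exceed ensemble size "
            f"{ensemble.n_poses}"
        )
    ftab = funnel(ensemble, residues=residues)
    rmsds = ftab.table["rmsd"].to_numpy()
    scores = ftab.table["score"].to_numpy()
    lo, hi = float(rmsds.min()), float(rmsds.max())
    if hi - lo < 1e-12:
        logger.warning("degenerate RMSD range; using a single group")
        order = np.lexsort((np.arange(len(scores)), scores))
        return [[int(i) for i in order[:per_group]]]
    edges = np.linspace(lo, hi, n_groups + 1)
    groups: list[list[int]] = []
    for g in range(n_groups):
        in_bin = (rmsds >= edges[g]) & (
            rmsds <= edges[g + 1] if g == n_groups - 1 else rmsds < edges[g + 1]
        )
        ids = np.flatnonzero(in_bin)
        if ids.size == 0:
            logger.warning("RMSD bin %d of %d is empty", g + 1, n_groups)
            groups.append([])
            continue
        order = np.lexsort((ids, scores[ids]))
        groups.append([int(i) for i in ids[order[:per_group]]])
    return groups


def atom_distance_series(
    ensemble: ConformerEnsemble,
    atom_a: tuple[int, str],
    atom_b: tuple[int, str],
    label: str = "",
) -> ContactSeries:
    """Per-pose Euclidean distance between two atoms, in Angstrom.

    Atoms are addressed as (full-length residue number, atom name) on the
    shared atom axis; slot resolution for deletion variants happens
    before this call (see :func:`resolve_slot_residue`).
    """
    try:
        ia = ensemble.atom_index(*atom_a)
    except KeyError:
        raise KeyError(
            f"atom {atom_a[0]}/{atom_a[1]} unresolvable in ensemble"
        ) from None
    try:
        ib = ensemble.atom_index(*atom_b)
    except KeyError:
        raise KeyError(
            f"atom {atom_b[0]}/{atom_b[1]} unresolvable in ensemble"
        ) from None
    d = np.linalg.norm(
        ensemble.coords[:, ia, :] - ensemble.coords[:, ib, :], axis=1
    )
    if not label:
        label = f"{atom_a[0]}.{atom_a[1]}-{atom_b[0]}.{atom_b[1]}"
    return ContactSeries(
        label=label, atom_a=atom_a, atom_b=atom_b, distances=d
    )


def hbond_summary(
    series: ContactSeries | np.ndarray,
    window: tuple[float, float] = HBOND_STABLE_WINDOW,
    hist_range: tuple[float, float] = HBOND_HIST_RANGE,
    bin_width: float = HBOND_HIST_BIN,
) -> HBondSummary:
    """Classify a donor-acceptor distance series.

    ``stable`` is keyed on the mean distance lying inside ``window``;
    the SD is reported but not thresholded.  ``in_range_frequency`` is
    the fraction of poses with distance inside ``hist_range`` (inclusive
    bounds), which also defines the fixed-width histogram.
    """
    d = series.distances if isinstance(series, ContactSeries) else np.asarray(series)
    if d.size == 0:
        raise ValueError("empty distance series")
    mean = float(d.mean())
    sd = float(d.std())  # population SD
    # 1e-9 tolerance absorbs float round-off at the window boundaries
    stable = window[0] - 1e-9 <= mean <= window[1] + 1e-9
    in_range = float(((d >= hist_range[0]) & (d <= hist_range[1])).mean())
    n_bins = int(round((hist_range[1] - hist_range[0]) / bin_width))
    counts, edges = np.histogram(d, bins=n_bins, range=hist_range)
    return HBondSummary(
        mean=mean,
        sd=sd,
        stable=stable,
        in_range_frequency=in_range,
        hist_counts=counts,
        hist_edges=edges,
        window=window,
        hist_range=hist_range,
    )


def contact_frequency(
    series: ContactSeries | np.ndarray, cutoff: float = CONTACT_CUTOFF
) -> float:
    """Fraction of poses with distance strictly below the cutoff."""
    d = series.distances if isinstance(series, ContactSeries) else np.asarray(series)
    if d.size == 0:
        raise ValueError("empty distance series")
    return float((d < cutoff).mean())


def resolve_slot_residue(
    variant: DeletionVariant | None,
    slot_full_number: int,
    loop_def: LoopDefinition,
) -> int:
    """Residue occupying a wild-type loop position ("slot") in a variant.

    Deletion shifts C-terminal loop residues N-ward; a contact defined at
    wild-type position p is measured, in a variant, at the residue that
    now occupies p's ordinal position counted from the N-terminal loop
    anchor.  If the truncated loop is shorter than the ordinal, the
    C-terminal anchor residue is returned with a warning.

    ``variant=None`` (or a window entirely C-terminal of the slot) is the
    identity.
    """
    lo, hi = loop_def.loop_span
    if not lo <= slot_full_number <= hi:
        raise ValueError(
            f"slot {slot_full_number} outside loop span {lo}-{hi}"
        )
    if variant is None:
        return slot_full_number
    w = variant.window
    remaining = [
        r for r in range(lo, hi + 1) if not (w.start <= r <= w.end)
    ]
    ordinal = slot_full_number - lo  # 0-based position from the N anchor
    if ordinal >= len(remaining):
        logger.warning(
            "slot %d beyond truncated loop (length %d); returning C anchor",
            slot_full_number,
            len(remaining),
        )
        return remaining[-1]
    return remaining[ordinal]


def _principal_axis(coords: np.ndarray) -> np.ndarray:
    """First principal component of a point cloud, oriented first->last."""
    coords = coords.astype(np.float64)
    centered = coords - coords.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] < 1e-9:
        raise ValueError("degenerate (coincident) atom selection")
    axis = vt[0]
    direction = coords[-1] - coords[0]
    if np.dot(axis, direction) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def helix_angle(
    pose: Pose,
    helix_residues: tuple[int, int],
    base_a: tuple[tuple[int, int], set[str]],
    base_b: tuple[tuple[int, int], set[str]],
) -> HelixAngleResult:
    """Tilt angle between a helix axis and a base vector, in degrees.

    The helix axis is the first principal component of the helix CA
    atoms, oriented N->C.  The base vector runs between the centroids of
    two atom selections (e.g. the bottom of the analysed loop and a
    reference patch on the protease body).  The result lies in [0, 180].
    """
    ca = select_atoms(pose, residues=helix_residues, atom_names={"CA"})
    if ca.array_length() < 3:
        raise ValueError(
            f"helix selection {helix_residues} has {ca.array_length()} CA "
            "atoms; need >= 3"
        )
    axis = _principal_axis(ca.coord)

    sel_a = select_atoms(pose, residues=base_a[0], atom_names=base_a[1])
    sel_b = select_atoms(pose, residues=base_b[0], atom_names=base_b[1])
    base_vec = (
        sel_b.coord.astype(np.float64).mean(axis=0)
        - sel_a.coord.astype(np.float64).mean(axis=0)
    )
    norm = np.linalg.norm(base_vec)
    if norm < 1e-9:
        raise ValueError("degenerate base selections (coincident centroids)")
    base_unit = base_vec / norm
    cosang = float(np.clip(np.dot(axis, base_unit), -1.0, 1.0))
    angle = float(np.degrees(np.arccos(cosang)))
    return HelixAngleResult(
        angle_deg=angle,
        helix_axis=axis,
        base_vector=base_unit,
        helix_selection=helix_residues,
        base_selections=(base_a, base_b),
    )


def vector_angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    """Angle between two vectors in degrees, in [0, 180]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    c = float(
        np.clip(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1)
    )
    return float(np.degrees(np.arccos(c)))


def helix_angle_from_structure(
    pdb_path,
    helix_span: tuple[int, int],
    base_a: tuple[tuple[int, int], set[str]],
    base_b: tuple[tuple[int, int], set[str]],
    chain: str | None = None,
) -> HelixAngleResult:
    """Helix tilt angle from a crystal-structure PDB file.

    Reads the first model, drops hetero atoms and hydrogens and, when
    ``chain`` is not given, auto-selects the chain that contains both the
    helix span and the base selections.  Selections are residue-id
    intervals in the file's own numbering scheme (serine-protease entries
    typically use chymotrypsin numbering, where the loop insertion
    residues share one residue id with insertion codes).
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(pdb_path)
    arr = pdb.get_structure(model=1, altloc="first")
    arr = arr[~arr.hetero & ~np.isin(arr.element, ("H", "D"))]
    if chain is None:
        for cand in np.unique(arr.chain_id):
            sub = arr[arr.chain_id == cand]
            ids = set(sub.res_id.tolist())
            needed = set(range(helix_span[0], helix_span[1] + 1))
            needed |= set(range(base_a[0][0], base_a[0][1] + 1))
            needed |= set(range(base_b[0][0], base_b[0][1] + 1))
            if needed <= ids:
                chain = str(cand)
                break
        if chain is None:
            raise ValueError(
                "no chain contains the helix span and both base selections"
            )
    arr = arr[arr.chain_id == chain]
    return helix_angle(Pose(array=arr), helix_span, base_a, base_b)


def superpose_to_body(
    ensemble: ConformerEnsemble, body_residues: tuple[int, int]
) -> ConformerEnsemble:
    """Kabsch-superimpose all poses onto pose 1 over protease-body CA atoms.

    For ensembles produced in a shared rigid frame this is a no-op; it is
    provided for ensembles from other sources.
    """
    import biotite.structure as bst

    mask = ensemble.selection_mask(residues=body_residues, atom_names={"CA"})
    ref = ensemble.stack[0]
    fitted, _ = bst.superimpose(ref, ensemble.stack, atom_mask=mask)
    return ConformerEnsemble(
        stack=fitted,
        scores=ensemble.scores.copy(),
        rebuild_span=ensemble.rebuild_span,
        pose_tags=list(ensemble.pose_tags),
    )
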