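"""Conformer-ensemble structure IO.

Loop-modelling protocols emit ensembles of poses for the same molecule:
a multi-MODEL PDB file plus a per-pose score table (Rosetta Energy Units,
REU).  This module reads and writes those ensembles with strict
atom-correspondence validation — every pose must present the identical
ordered atom set over the analysis selection — so that downstream
per-atom statistics (mean structure, RMSF, distance series) are
well-defined array operations.

Hydrogens are dropped on read everywhere: all distance criteria used in
the analyses are heavy-atom (N...O) distances.  Alternate locations keep
the first conformation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as bst
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

logger = logging.getLogger(__name__)

# Canonical intra-residue atom order: backbone, then CB, then the rest
# alphabetically.
_CANONICAL_ATOM_RANK = {"N": 0, "CA": 1, "C": 2, "O": 3, "CB": 4}

_SCORE_REMARK = "REMARK 100 POSE_SCORE"


class CorrespondenceError(ValueError):
    """Atom sets differ between poses of an ensemble."""


class FormatError(ValueError):
    """Unparseable structure or score-table input."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a pose."""

    serial: int
    name: str
    residue_number: int
    residue_name: str
    chain: str
    xyz: tuple[float, float, float]


@dataclass
class Pose:
    """A single conformation: a biotite :class:`AtomArray` plus a model id."""

    array: AtomArray
    model_id: int = 1

    def __len__(self) -> int:
        return self.array.array_length()

    def coord(self, residue_number: int, atom_name: str) -> np.ndarray:
        """Coordinate of one atom; raises ``KeyError`` if absent."""
        mask = (self.array.res_id == residue_number) & (
            self.array.atom_name == atom_name
        )
        n = int(mask.sum())
        if n == 0:
            raise KeyError(f"atom {residue_number}/{atom_name} not in pose")
        if n > 1:
            raise CorrespondenceError(
                f"atom {residue_number}/{atom_name} is not unique in pose"
            )
        return self.array.coord[mask][0]

    def records(self) -> list[AtomRecord]:
        a = self.array
        return [
            AtomRecord(
                serial=i + 1,
                name=str(a.atom_name[i]),
                residue_number=int(a.res_id[i]),
                residue_name=str(a.res_name[i]),
                chain=str(a.chain_id[i]),
                xyz=tuple(float(x) for x in a.coord[i]),
            )
            for i in range(a.array_length())
        ]


def atom_sort_order(array: AtomArray) -> np.ndarray:
    """Deterministic ordering: residue number, canonical atom-name rank, name."""
    ranks = np.array(
        [_CANONICAL_ATOM_RANK.get(n, 5) for n in array.atom_name], dtype=int
    )
    return np.lexsort((array.atom_name, ranks, array.res_id, array.chain_id))


def select_atoms(
    pose: Pose | AtomArray,
    residues: tuple[int, int] | None = None,
    atom_names: set[str] | None = None,
    chain: str | None = None,
) -> AtomArray:
    """Select atoms from a pose by residue interval and atom-name set.

    The result is sorted deterministically (residue number, then canonical
    atom-name order).  An empty selection raises ``ValueError``.
    """
    array = pose.array if isinstance(pose, Pose) else pose
    mask = np.ones(array.array_length(), dtype=bool)
    if residues is not None:
        lo, hi = residues
        mask &= (array.res_id >= lo) & (array.res_id <= hi)
    if atom_names is not None:
        mask &= np.isin(array.atom_name, sorted(atom_names))
    if chain is not None:
        mask &= array.chain_id == chain
    if not mask.any():
        raise ValueError(
            f"empty atom selection (residues={residues}, atoms={atom_names})"
        )
    sub = array[mask]
    return sub[atom_sort_order(sub)]


@dataclass
class ConformerEnsemble:
    """N poses with identical atom ordering, plus aligned per-pose scores.

    ``stack.coord`` has shape (n_poses, n_atoms, 3); ``scores`` is a float
    array of length n_poses (all zero when no score source was given).
    """

    stack: AtomArrayStack
    scores: np.ndarray
    rebuild_span: tuple[int, int] | None = None
    pose_tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (self.n_poses,):
            raise ValueError(
                f"{self.n_poses} poses but {self.scores.shape[0]} scores"
            )
        if not self.pose_tags:
            self.pose_tags = [f"pose_{i + 1}" for i in range(self.n_poses)]

    @property
    def n_poses(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    @property
    def coords(self) -> np.ndarray:
        return self.stack.coord

    def pose(self, i: int) -> Pose:
        """Pose by 0-based position."""
        return Pose(array=self.stack[i], model_id=i + 1)

    def __len__(self) -> int:
        return self.n_poses

    def selection_mask(
        self,
        residues: tuple[int, int] | None = None,
        atom_names: set[str] | None = None,
    ) -> np.ndarray:
        """Boolean mask over the shared atom axis."""
        arr = self.stack
        mask = np.ones(self.n_atoms, dtype=bool)
        if residues is not None:
            lo, hi = residues
            mask &= (arr.res_id >= lo) & (arr.res_id <= hi)
        if atom_names is not None:
            mask &= np.isin(arr.atom_name, sorted(atom_names))
        if not mask.any():
            raise ValueError(
                f"empty ensemble selection (residues={residues}, "
                f"atoms={atom_names})"
            )
        return mask

    def atom_index(self, residue_number: int, atom_name: str) -> int:
        """Index of one atom on the shared atom axis."""
        mask = (self.stack.res_id == residue_number) & (
            self.stack.atom_name == atom_name
        )
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise KeyError(
                f"atom {residue_number}/{atom_name} not in ensemble"
            )
        if idx.size > 1:
            raise CorrespondenceError(
                f"atom {residue_number}/{atom_name} not unique in ensemble"
            )
        return int(idx[0])


def _strip_hydrogens(array: AtomArray) -> AtomArray:
    mask = ~np.isin(array.element, ("H", "D"))
    return array[mask]


def _validate_correspondence(models: list[AtomArray]) -> None:
    ref = models[0]
    ref_keys = list(
        zip(ref.chain_id.tolist(), ref.res_id.tolist(), ref.atom_name.tolist())
    )
    for i, m in enumerate(models[1:], start=2):
        keys = list(
            zip(m.chain_id.tolist(), m.res_id.tolist(), m.atom_name.tolist())
        )
        if keys == ref_keys:
            continue
        n = min(len(keys), len(ref_keys))
        for j in range(n):
            if keys[j] != ref_keys[j]:
                raise CorrespondenceError(
                    f"model {i} atom {j + 1} is "
                    f"{keys[j][0]}/{keys[j][1]}/{keys[j][2]}, expected "
                    f"{ref_keys[j][0]}/{ref_keys[j][1]}/{ref_keys[j][2]}"
                )
        raise CorrespondenceError(
            f"model {i} has {len(keys)} atoms, model 1 has {len(ref_keys)}"
        )


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited score table with ``tag`` and ``reu`` columns."""
    try:
        df = pd.read_csv(path, sep=r"\s+")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse score table {path}: {exc}") from exc
    missing = {"tag", "reu"} - set(df.columns)
    if missing:
        raise FormatError(
            f"score table {path} lacks required column(s): {sorted(missing)}"
        )
    if df["tag"].duplicated().any():
        dup = df.loc[df["tag"].duplicated(), "tag"].iloc[0]
        raise FormatError(f"duplicate pose tag in score table: {dup!r}")
    return df[["tag", "reu"]]


def write_score_table(
    tags: list[str], scores: np.ndarray, path: str | Path
) -> Path:
    path = Path(path)
    df = pd.DataFrame({"tag": tags, "reu": np.asarray(scores, dtype=float)})
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")
    return path


def _read_embedded_scores(lines: list[str]) -> list[float] | None:
    vals = [
        float(line[len(_SCORE_REMARK):].strip())
        for line in lines
        if line.startswith(_SCORE_REMARK)
    ]
    return vals or None


def read_ensemble(
    pdb_path: str | Path,
    score_path: str | Path | None = None,
    rebuild_span: tuple[int, int] | None = None,
) -> ConformerEnsemble:
    """Read a multi-model PDB (plus optional score table) as an ensemble.

    Single-model files are treated as N=1.  Scores are joined strictly on
    pose tag ``pose_<model>``; a missing tag is an error.  Embedded
    ``REMARK 100 POSE_SCORE`` lines (as written by
    :func:`write_multimodel_pdb`) are used when no score table is given.
    Without any score source all scores are zero and a warning is logged.
    """
    pdb_path = Path(pdb_path)
    try:
        pdb = PDBFile.read(pdb_path)
    except Exception as exc:
        raise FormatError(f"cannot parse PDB file {pdb_path}: {exc}") from exc

    n_models = pdb.get_model_count()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = pdb.get_structure(altloc="first")
        if isinstance(stack, AtomArray):
            stack = bst.stack([stack])
        models = [stack[i] for i in range(stack.stack_depth())]
    except Exception:
        # inconsistent models: diagnose per model for a precise error
        models = []
        for i in range(1, n_models + 1):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                models.append(pdb.get_structure(model=i, altloc="first"))
    models = [_strip_hydrogens(m) for m in models]
    _validate_correspondence(models)
    stack = bst.stack(models)

    n = stack.stack_depth()
    tags = [f"pose_{i + 1}" for i in range(n)]
    if score_path is not None:
        table = read_score_table(score_path).set_index("tag")
        missing = [t for t in tags if t not in table.index]
        if missing:
            raise FormatError(
                f"score table has no entry for pose tag {missing[0]!r} "
                f"({len(missing)} missing of {n})"
            )
        scores = table.loc[tags, "reu"].to_numpy(dtype=float)
    else:
        embedded = _read_embedded_scores(pdb.lines)
        if embedded is not None:
            if len(embedded) != n:
                raise FormatError(
                    f"{len(embedded)} embedded scores for {n} models"
                )
            scores = np.asarray(embedded, dtype=float)
        else:
            logger.warning(
                "no score source for %s; all scores set to 0", pdb_path
            )
            scores = np.zeros(n)

    ens = ConformerEnsemble(
        stack=stack, scores=scores, rebuild_span=rebuild_span, pose_tags=tags
    )
    if rebuild_span is not None:
        ens.selection_mask(residues=rebuild_span)  # must be non-empty
    return ens


def write_multimodel_pdb(
    ensemble: ConformerEnsemble,
    path: str | Path,
    embed_scores: bool = True,
) -> Path:
    """Write an ensemble as a standard MODEL/ENDMDL multi-model PDB file.

    Coordinates use fixed-width PDB columns (3-decimal precision).  When
    ``embed_scores`` is set, per-pose scores are stored in
    ``REMARK 100 POSE_SCORE`` header lines, one per model in model order,
    making the file self-contained.  Serialisation is deterministic: the
    same ensemble always produces byte-identical output.
    """
    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(ensemble.stack)
    if embed_scores:
        remarks = [
            f"{_SCORE_REMARK} {s:.6f}" for s in ensemble.scores
        ]
        pdb.lines = remarks + pdb.lines
    pdb.write(path)
    return path
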