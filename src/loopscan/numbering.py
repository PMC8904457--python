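"""Dual residue numbering for serine proteases.

Trypsin-like proteases are conventionally described in chymotrypsin
(template) numbering, where loop insertions relative to chymotrypsinogen
receive letter suffixes (170A, 170B, ...).  Experimental work on a given
protease uses its own full-length numbering.  :class:`NumberingMap` holds a
bijective mapping between the two schemes over the region of interest and
supports round-trip conversion.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

AMINO_ACIDS_1 = set("ACDEFGHIKLMNPQRSTVWY")

_CHYM_RE = re.compile(r"^([0-9]+)([A-Z]?)$")


class NumberingError(KeyError):
    """Raised when a residue number or label is absent from a map."""


@dataclass(frozen=True)
class ResidueRef:
    """One residue identified in both numbering schemes.

    Parameters
    ----------
    full_number
        Position in the full-length (zymogen) sequence, 1-based.
    chym_label
        Chymotrypsin-template label, digits plus an optional insertion
        letter (e.g. ``"170A"``).
    amino_acid
        One-letter residue code, or ``"X"`` when the identity is not part
        of the packaged mapping.
    """

    full_number: int
    chym_label: str
    amino_acid: str = "X"

    def __post_init__(self) -> None:
        if self.full_number <= 0:
            raise ValueError(f"full_number must be positive, got {self.full_number}")
        if not _CHYM_RE.match(self.chym_label):
            raise ValueError(f"malformed chymotrypsin label: {self.chym_label!r}")
        if self.amino_acid != "X" and self.amino_acid not in AMINO_ACIDS_1:
            raise ValueError(f"unknown amino acid code: {self.amino_acid!r}")

    @property
    def chym_number(self) -> int:
        return int(_CHYM_RE.match(self.chym_label).group(1))

    @property
    def insertion_code(self) -> str:
        return _CHYM_RE.match(self.chym_label).group(2)


class NumberingMap:
    """Bijective full-length <-> chymotrypsin numbering map.

    The map is defined only over the residues it was constructed with;
    lookups outside that domain raise :class:`NumberingError` naming the
    offending key rather than extrapolating.
    """

    def __init__(self, entries: Iterable[ResidueRef]):
        self.entries: list[ResidueRef] = sorted(entries, key=lambda r: r.full_number)
        self._by_full: dict[int, ResidueRef] = {}
        self._by_chym: dict[str, ResidueRef] = {}
        for ref in self.entries:
            if ref.full_number in self._by_full:
                raise ValueError(f"duplicate full-length number {ref.full_number}")
            if ref.chym_label in self._by_chym:
                raise ValueError(f"duplicate chymotrypsin label {ref.chym_label}")
            self._by_full[ref.full_number] = ref
            self._by_chym[ref.chym_label] = ref

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ResidueRef]:
        return iter(self.entries)

    def __contains__(self, full_number: int) -> bool:
        return full_number in self._by_full

    def to_chymotrypsin(self, full_number: int) -> str:
        """Return the chymotrypsin label for a full-length residue number."""
        try:
            return self._by_full[full_number].chym_label
        except KeyError:
            raise NumberingError(
                f"full-length residue {full_number} is not in the numbering map"
            ) from None

    def from_chymotrypsin(self, chym_label: str) -> int:
        """Return the full-length number for a chymotrypsin label."""
        try:
            return self._by_chym[chym_label].full_number
        except KeyError:
            raise NumberingError(
                f"chymotrypsin label {chym_label!r} is not in the numbering map"
            ) from None

    def amino_acid(self, full_number: int) -> str:
        try:
            return self._by_full[full_number].amino_acid
        except KeyError:
            raise NumberingError(
                f"full-length residue {full_number} is not in the numbering map"
            ) from None


def to_chymotrypsin(full_number: int, numbering: NumberingMap) -> str:
    """Functional alias for :meth:`NumberingMap.to_chymotrypsin`."""
    return numbering.to_chymotrypsin(full_number)


def from_chymotrypsin(chym_label: str, numbering: NumberingMap) -> int:
    """Functional alias for :meth:`NumberingMap.from_chymotrypsin`."""
    return numbering.from_chymotrypsin(chym_label)


@dataclass(frozen=True)
class LoopDefinition:
    """Definition of a surface loop and its deletion-scan geometry.

    All intervals are inclusive on both ends, in full-length numbering.

    ``loop_span`` is the interval used for loop-length accounting,
    ``rebuild_span`` the interval of residues rebuilt during conformer
    modelling, and ``scan_span`` the interval eligible for deletion
    windows.  ``scan_sequence`` is the wild-type sequence of the scan
    span; ``context_sequence`` an optional surrounding fragment anchored
    at ``context_start`` used to render whole-fragment variant sequences.
    """

    loop_span: tuple[int, int]
    rebuild_span: tuple[int, int]
    scan_span: tuple[int, int]
    scan_sequence: str
    context_sequence: str = ""
    context_start: int = 0
    numbering: NumberingMap | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for name in ("loop_span", "rebuild_span", "scan_span"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is empty: {lo}-{hi}")
        if not (
            self.rebuild_span[0] <= self.scan_span[0]
            and self.scan_span[1] <= self.rebuild_span[1]
        ):
            raise ValueError("scan_span must lie inside rebuild_span")
        if len(self.scan_sequence) != self.scan_len:
            raise ValueError(
                f"scan_sequence length {len(self.scan_sequence)} does not match "
                f"scan span {self.scan_span[0]}-{self.scan_span[1]} "
                f"({self.scan_len} residues)"
            )
        if any(a not in AMINO_ACIDS_1 for a in self.scan_sequence):
            raise ValueError("scan_sequence contains non-standard residues")
        if self.context_sequence:
            lo = self.context_start
            hi = lo + len(self.context_sequence) - 1
            if not (lo <= self.scan_span[0] and self.scan_span[1] <= hi):
                raise ValueError("context_sequence does not cover the scan span")
            sub = self.context_sequence[
                self.scan_span[0] - lo : self.scan_span[1] - lo + 1
            ]
            if sub != self.scan_sequence:
                raise ValueError(
                    f"context_sequence disagrees with scan_sequence: {sub!r}"
                )

    @property
    def loop_len(self) -> int:
        return self.loop_span[1] - self.loop_span[0] + 1

    @property
    def scan_len(self) -> int:
        return self.scan_span[1] - self.scan_span[0] + 1

    @property
    def rebuild_len(self) -> int:
        return self.rebuild_span[1] - self.rebuild_span[0] + 1

    def scan_residue(self, full_number: int) -> str:
        """Wild-type residue at a position inside the scan span."""
        lo, hi = self.scan_span
        if not lo <= full_number <= hi:
            raise ValueError(f"residue {full_number} outside scan span {lo}-{hi}")
        return self.scan_sequence[full_number - lo]

    def context_residue(self, full_number: int) -> str:
        if not self.context_sequence:
            raise ValueError("loop definition has no context sequence")
        lo = self.context_start
        hi = lo + len(self.context_sequence) - 1
        if not lo <= full_number <= hi:
            raise ValueError(f"residue {full_number} outside context {lo}-{hi}")
        return self.context_sequence[full_number - lo]
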