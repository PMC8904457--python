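"""Sliding-window deletion-library enumeration.

A deletion scan moves windows of 1..k consecutive residues through the
scan span of a loop, producing one variant per (window size, start
position).  The canonical library ordering is ascending window size, then
ascending (N-to-C) start position, indexed from 1; this ordering defines
the variant numbers used in all downstream reporting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from .numbering import LoopDefinition

DEFAULT_SIZES = range(1, 7)  # sizes 1..6 give the canonical 39-variant library


class VariantError(ValueError):
    """Raised for invalid windows or library lookups."""


@dataclass(frozen=True, order=True)
class DeletionWindow:
    """A contiguous deletion of ``size`` residues starting at ``start``.

    Ordering of windows (size, then start) matches the canonical library
    ordering.
    """

    size: int
    start: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise VariantError(f"window size must be >= 1, got {self.size}")

    @property
    def end(self) -> int:
        return self.start + self.size - 1

    def validate(self, loop_def: LoopDefinition) -> None:
        lo, hi = loop_def.scan_span
        if self.start < lo or self.end > hi:
            raise VariantError(
                f"window {self.start}-{self.end} outside scan span {lo}-{hi}"
            )


@dataclass(frozen=True)
class DeletionVariant:
    """One deletion variant of the library."""

    index: int
    window: DeletionWindow
    deleted_sequence: str
    resulting_loop_length: int
    variant_sequence: str = ""

    @property
    def label(self) -> str:
        return f"del{self.window.start}-{self.window.end}"


@dataclass
class VariantLibrary:
    """Ordered deletion-variant library over one loop definition."""

    loop_def: LoopDefinition
    sizes: tuple[int, ...]
    variants: list[DeletionVariant] = field(default_factory=list)
    removed_indices: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[DeletionVariant]:
        return iter(self.variants)

    def __getitem__(self, index: int) -> DeletionVariant:
        """1-based lookup by canonical variant index."""
        for v in self.variants:
            if v.index == index:
                return v
        raise VariantError(f"no variant with index {index}")

    def by_window(self, window: DeletionWindow) -> DeletionVariant:
        for v in self.variants:
            if v.window == window:
                return v
        raise VariantError(
            f"window {window.start}-{window.end} (size {window.size}) "
            f"not in library"
        )


def apply_deletion(
    sequence: str, window: DeletionWindow, loop_def: LoopDefinition,
    sequence_start: int | None = None,
) -> str:
    """Excise a deletion window from a sequence fragment.

    ``sequence`` is anchored in full-length numbering at ``sequence_start``
    (default: the loop definition's context start).  The returned string is
    shorter by the window size.
    """
    if sequence_start is None:
        sequence_start = loop_def.context_start
    i = window.start - sequence_start
    j = window.end - sequence_start + 1
    if i < 0 or j > len(sequence):
        raise IndexError(
            f"window {window.start}-{window.end} outside sequence "
            f"({sequence_start}-{sequence_start + len(sequence) - 1})"
        )
    return sequence[:i] + sequence[j:]


def enumerate_deletions(
    loop_def: LoopDefinition, sizes: Iterable[int] = DEFAULT_SIZES
) -> VariantLibrary:
    """Enumerate the sliding-window deletion library.

    One variant per (size, start) with the window inside the scan span;
    canonical ordering is ascending size then ascending start, 1-based.
    For a 9-residue scan span and sizes {1..6} this yields the canonical
    39-variant library.
    """
    sizes = tuple(sorted(set(int(s) for s in sizes)))
    if not sizes:
        raise VariantError("empty size set")
    scan_lo, scan_hi = loop_def.scan_span
    scan_len = loop_def.scan_len
    for s in sizes:
        if s < 1:
            raise VariantError(f"window size must be >= 1, got {s}")
        if s > scan_len:
            raise VariantError(
                f"window size {s} exceeds scan span length {scan_len}"
            )
    variants: list[DeletionVariant] = []
    index = 0
    for size in sizes:
        for start in range(scan_lo, scan_hi - size + 2):
            index += 1
            window = DeletionWindow(size=size, start=start)
            deleted = loop_def.scan_sequence[
                start - scan_lo : start - scan_lo + size
            ]
            variant_seq = ""
            if loop_def.context_sequence:
                variant_seq = apply_deletion(
                    loop_def.context_sequence, window, loop_def
                )
            variants.append(
                DeletionVariant(
                    index=index,
                    window=window,
                    deleted_sequence=deleted,
                    resulting_loop_length=loop_def.loop_len - size,
                    variant_sequence=variant_seq,
                )
            )
    return VariantLibrary(loop_def=loop_def, sizes=sizes, variants=variants)


def variant_index(library: VariantLibrary, window: DeletionWindow) -> int:
    """1-based canonical index of a window within the library."""
    return library.by_window(window).index


def dedupe_identical(library: VariantLibrary) -> VariantLibrary:
    """Drop variants whose variant sequence repeats an earlier one.

    Windows over repeat-containing loops can excise identical substrings;
    the first occurrence (canonical order) is kept.  Removed canonical
    indices are recorded on the returned library.  Variants without a
    rendered sequence are never removed.
    """
    seen: set[str] = set()
    kept: list[DeletionVariant] = []
    removed: list[int] = []
    for v in library.variants:
        key = v.variant_sequence
        if key and key in seen:
            removed.append(v.index)
            continue
        if key:
            seen.add(key)
        kept.append(v)
    return VariantLibrary(
        loop_def=library.loop_def,
        sizes=library.sizes,
        variants=kept,
        removed_indices=tuple(removed),
    )


_TSV_COLUMNS = (
    "index", "size", "start", "end", "deleted_sequence", "loop_length",
)


def write_variant_outputs(
    library: VariantLibrary, out_dir: str | Path, prefix: str = "variants"
) -> dict[str, Path]:
    """Write the library as a FASTA of variant sequences and a TSV table.

    FASTA headers carry the canonical index, the deletion window in
    full-length numbering and, when a numbering map is attached, the
    chymotrypsin labels of the window bounds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fasta_path = out_dir / f"{prefix}.fasta"
    tsv_path = out_dir / f"{prefix}.tsv"

    numbering = library.loop_def.numbering
    with open(fasta_path, "w") as fh:
        for v in library.variants:
            w = v.window
            chym = ""
            if numbering is not None and w.start in numbering and w.end in numbering:
                chym = (
                    f" chym={numbering.to_chymotrypsin(w.start)}-"
                    f"{numbering.to_chymotrypsin(w.end)}"
                )
            fh.write(
                f">variant_{v.index:02d} del={w.start}-{w.end}{chym} "
                f"deleted={v.deleted_sequence} loop_length="
                f"{v.resulting_loop_length}\n"
            )
            fh.write((v.variant_sequence or v.deleted_sequence) + "\n")

    with open(tsv_path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_TSV_COLUMNS)
        for v in library.variants:
            writer.writerow(
                [
                    v.index,
                    v.window.size,
                    v.window.start,
                    v.window.end,
                    v.deleted_sequence,
                    v.resulting_loop_length,
                ]
            )
    return {"fasta": fasta_path, "tsv": tsv_path}


def read_variant_table(tsv_path: str | Path) -> list[dict]:
    """Read back the TSV variant table written by :func:`write_variant_outputs`."""
    rows: list[dict] = []
    with open(tsv_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            rows.append(
                {
                    "index": int(row["index"]),
                    "size": int(row["size"]),
                    "start": int(row["start"]),
                    "end": int(row["end"]),
                    "deleted_sequence": row["deleted_sequence"],
                    "loop_length": int(row["loop_length"]),
                }
            )
    return rows


def expected_library_size(scan_len: int, sizes: Sequence[int]) -> int:
    """Closed-form library size: sum over sizes k of (scan_len - k + 1)."""
    return sum(scan_len - k + 1 for k in set(sizes) if k <= scan_len)
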