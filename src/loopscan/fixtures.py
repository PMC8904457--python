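"""Packaged FVIIa 170-loop fixture.

Coagulation factor VIIa carries an extended, surface-exposed 170 loop
(chymotrypsin numbering 170-170I) that mediates allosteric activation by
tissue factor.  This module ships the loop definition used throughout the
package as the worked example: the 14-residue loop 308-321 in full-length
FVII numbering, the rebuilt span 311-321 and the deletion-scan span
313-321 (sequence QSRKVGDSP), together with the full<->chymotrypsin
numbering map for the residues discussed in the analyses.
"""

from __future__ import annotations

from .numbering import LoopDefinition, NumberingMap, ResidueRef

# Full-length FVII fragment covering the loop and its anchors
# (L305..E325); N322 is the N-glycan attachment site adjacent to the loop.
FVIIA_CONTEXT_SEQUENCE = "LMTQDCLQQSRKVGDSPNITE"
FVIIA_CONTEXT_START = 305

FVIIA_SCAN_SEQUENCE = "QSRKVGDSP"  # residues 313-321

_CHYM_ENTRIES = [
    (305, "163", "L"),
    (306, "164", "M"),
    (307, "165", "T"),
    (308, "166", "Q"),
    (309, "167", "D"),
    (310, "168", "C"),  # C310-C329 disulfide partner
    (311, "169", "L"),
    (312, "170", "Q"),
    (313, "170A", "Q"),
    (314, "170B", "S"),
    (315, "170C", "R"),
    (316, "170D", "K"),
    (317, "170E", "V"),
    (318, "170F", "G"),
    (319, "170G", "D"),
    (320, "170H", "S"),
    (321, "170I", "P"),
    (322, "171", "N"),
    (329, "182", "C"),
    (366, "217", "Q"),
    (372, "223", "G"),
    (373, "224", "H"),
    (374, "225", "F"),
]


def fviia_numbering_map() -> NumberingMap:
    """Full-length <-> chymotrypsin map for the FVIIa 170-loop region."""
    return NumberingMap(
        ResidueRef(full, chym, aa) for full, chym, aa in _CHYM_ENTRIES
    )


def fviia_loop_definition() -> LoopDefinition:
    """The FVIIa 170-loop deletion-scan definition.

    Loop span 308-321 (wild-type length 14), rebuild span 311-321,
    scan span 313-321 with wild-type sequence QSRKVGDSP.
    """
    return LoopDefinition(
        loop_span=(308, 321),
        rebuild_span=(311, 321),
        scan_span=(313, 321),
        scan_sequence=FVIIA_SCAN_SEQUENCE,
        context_sequence=FVIIA_CONTEXT_SEQUENCE,
        context_start=FVIIA_CONTEXT_START,
        numbering=fviia_numbering_map(),
    )


# Variant groups highlighted by the functional characterisation:
# group 1 = intermediate (2-3 residue) truncations at 315-319,
# group 2 = deep (6-residue-scale) truncations at 313-320.
GROUP1_VARIANTS = frozenset({12, 13, 14, 20, 21, 22})
GROUP2_VARIANTS = frozenset({36, 37, 39})
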