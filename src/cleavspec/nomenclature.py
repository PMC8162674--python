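"""Schechter–Berger subsite nomenclature and the amino-acid alphabet.

Substrate residues are numbered P4, P3, P2, P1 on the N-terminal side of the
scissile bond and P1', P2', P3' on the C-terminal side; cleavage occurs
between P1 and P1'.  Internally each P-label maps to an integer offset
relative to P1 (P1 -> 0, P4 -> -3, P2' -> +2), so that a residue at P-label
``lab`` of a site whose P1 sits at 1-based sequence position ``p`` is the
residue at position ``p + offset(lab)``.
"""

from __future__ import annotations

import re

#: Canonical order of the 20 proteinogenic amino acids.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
N_AA = len(ALPHABET)

#: Residue classes used for consensus derivation and primary-specificity
#: calls.  His is deliberately not counted as basic: the His6 anchor flanking
#: phage-displayed inserts would otherwise contaminate windows drawn near the
#: C-terminal end of the randomized region.
CHEMICAL_CLASSES: dict[str, frozenset[str]] = {
    "basic": frozenset("KR"),
    "acidic": frozenset("DE"),
    "aromatic": frozenset("FYW"),
    "aliphatic": frozenset("AVIL"),
    "small": frozenset("GST"),
}

#: Primary-specificity labels keyed by the P1 residue class that defines them.
SPECIFICITY_CLASSES: dict[str, frozenset[str]] = {
    "tryptase": CHEMICAL_CLASSES["basic"],
    "chymase": CHEMICAL_CLASSES["aromatic"],
    "asp-ase": CHEMICAL_CLASSES["acidic"],
    "elastase": CHEMICAL_CLASSES["aliphatic"],
}

_PLABEL_RE = re.compile(r"^P(\d+)('?)$")


def plabel_to_offset(label: str) -> int:
    """Offset of a P-label relative to P1 (P1 -> 0, P4 -> -3, P2' -> +2)."""
    m = _PLABEL_RE.match(label)
    if not m:
        raise ValueError(f"not a P-position label: {label!r}")
    k = int(m.group(1))
    if k < 1:
        raise ValueError(f"not a P-position label: {label!r}")
    return k if m.group(2) else -(k - 1)


def offset_to_plabel(offset: int) -> str:
    """Inverse of :func:`plabel_to_offset`."""
    return f"P{offset}'" if offset > 0 else f"P{1 - offset}"


def window_labels(start: str = "P4", end: str = "P3'") -> list[str]:
    """Contiguous run of P-labels from `start` to `end`, inclusive."""
    lo, hi = plabel_to_offset(start), plabel_to_offset(end)
    if lo > hi:
        raise ValueError(f"window start {start} is C-terminal of end {end}")
    return [offset_to_plabel(o) for o in range(lo, hi + 1)]


def label_offsets(labels: list[str] | tuple[str, ...]) -> list[int]:
    """Offsets of a contiguous P-label window that must contain P1."""
    offs = [plabel_to_offset(lab) for lab in labels]
    if offs != list(range(offs[0], offs[0] + len(offs))):
        raise ValueError(f"P-labels not contiguous: {labels}")
    if 0 not in offs:
        raise ValueError(f"window does not contain P1: {labels}")
    return offs


def validate_sequence(seq: str, *, allow_x: bool = False) -> None:
    """Raise ValueError if `seq` contains a letter outside the alphabet."""
    allowed = set(ALPHABET) | ({"X"} if allow_x else set())
    bad = set(seq) - allowed
    if bad:
        raise ValueError(
            f"invalid amino-acid character(s) {sorted(bad)} in {seq!r}"
        )


def encode(seq: str) -> "list[int]":
    """Encode a sequence as alphabet indices; X and unknowns map to -1."""
    return [AA_INDEX.get(aa, -1) for aa in seq]
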