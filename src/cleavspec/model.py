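"""Position-specific cleavage models.

A set of cleavage windows aligned into a fixed P-position register is
summarised as a position frequency matrix (PFM), converted into a log-odds
position weight matrix (PWM) against a background composition, reduced to a
degenerate consensus pattern, and classified into a primary specificity
(tryptase / chymase / asp-ase / elastase / dual / undetermined).

Frequencies are pseudocount-smoothed:  f = (count + a) / (n + 20 a)  with a
single scalar pseudocount ``a`` shared by all residues and positions.
Weights are log2(f / background); per-position information content is the
Kullback-Leibler divergence of the column from background, in bits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import rel_entr

from .nomenclature import (
    ALPHABET,
    AA_INDEX,
    CHEMICAL_CLASSES,
    N_AA,
    SPECIFICITY_CLASSES,
    label_offsets,
    plabel_to_offset,
)

__all__ = [
    "PositionFrequencyMatrix",
    "PositionWeightMatrix",
    "ConsensusPattern",
    "SpecificityCall",
    "build_pfm",
    "pfm_to_pwm",
    "information_content",
    "derive_consensus",
    "classify_specificity_from_pwm",
    "classify_from_class_evidence",
    "modal_window",
    "uniform_background",
]


def uniform_background() -> np.ndarray:
    return np.full(N_AA, 1.0 / N_AA)


def _check_background(background: np.ndarray | None) -> np.ndarray:
    if background is None:
        return uniform_background()
    bg = np.asarray(background, dtype=float)
    if bg.shape != (N_AA,) or np.any(bg <= 0) or abs(bg.sum() - 1.0) > 1e-9:
        raise ValueError("background must be a strictly positive 20-vector summing to 1")
    return bg


@dataclass
class PositionFrequencyMatrix:
    """Per-position residue frequencies over an ordered P-label window.

    ``frequencies[i, j]`` is the frequency of residue ``ALPHABET[j]`` at
    position ``positions[i]``.  ``raw_counts`` is None for planted (truth)
    matrices that were specified directly as frequencies.
    """

    positions: list[str]
    frequencies: np.ndarray
    raw_counts: np.ndarray | None = None
    pseudocount: float = 0.0
    n_sequences: int = 0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        w = len(self.positions)
        label_offsets(self.positions)  # validates contiguity + P1
        if self.frequencies.shape != (w, N_AA):
            raise ValueError("frequency matrix shape does not match positions")
        if not np.allclose(self.frequencies.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each frequency column must sum to 1")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.raw_counts is not None:
            self.raw_counts = np.asarray(self.raw_counts, dtype=float)
            if self.raw_counts.shape != (w, N_AA) or np.any(self.raw_counts < 0):
                raise ValueError("raw_counts must be a non-negative (width, 20) array")

    @property
    def width(self) -> int:
        return len(self.positions)

    def position_index(self, label: str) -> int:
        return self.positions.index(label)


@dataclass
class PositionWeightMatrix:
    """Log2 odds (frequency over background) per position and residue."""

    positions: list[str]
    weights: np.ndarray
    background: np.ndarray = field(default_factory=uniform_background)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.background = _check_background(self.background)
        label_offsets(self.positions)
        if self.weights.shape != (len(self.positions), N_AA):
            raise ValueError("weight matrix shape does not match positions")

    @property
    def width(self) -> int:
        return len(self.positions)

    def frequencies(self) -> np.ndarray:
        """Recover the frequency matrix: f = background * 2**weight."""
        return self.background[None, :] * np.exp2(self.weights)


@dataclass
class ConsensusPattern:
    """Degenerate per-position pattern with hard constraints.

    ``allowed[i]`` is the residue set allowed at ``positions[i]``; None means
    any residue.  Positions named in ``required`` are hard constraints.
    ``forbidden_classes`` lists (class_name, radius) pairs: no residue of the
    class may occur within ``radius`` residues of P1.  ``max_mismatches``
    bounds the number of failed non-required positions a window may have and
    still match.
    """

    positions: list[str]
    allowed: list[frozenset[str] | None]
    required: frozenset[str] = frozenset({"P1"})
    forbidden_classes: list[tuple[str, int]] = field(default_factory=list)
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        label_offsets(self.positions)
        if len(self.allowed) != len(self.positions):
            raise ValueError("allowed sets do not match positions")
        if "P1" not in self.required:
            raise ValueError("P1 must always be a required position")
        for name, radius in self.forbidden_classes:
            if name not in CHEMICAL_CLASSES:
                raise ValueError(f"unknown residue class {name!r}")
            if radius < 0:
                raise ValueError("forbidden-class radius must be >= 0")

    @property
    def width(self) -> int:
        return len(self.positions)

    # -- compact string grammar ------------------------------------------
    # "P4:[FWY] P3:D P2:. P1:D! P1':. ; forbid[DE]±3 ; mm<=1"

    def to_string(self) -> str:
        parts = []
        for lab, allow in zip(self.positions, self.allowed):
            if allow is None:
                tok = "."
            elif len(allow) == 1:
                tok = next(iter(allow))
            else:
                tok = "[" + "".join(sorted(allow, key=ALPHABET.index)) + "]"
            if lab in self.required:
                tok += "!"
            parts.append(f"{lab}:{tok}")
        clauses = [" ".join(parts)]
        for name, radius in self.forbidden_classes:
            residues = "".join(sorted(CHEMICAL_CLASSES[name], key=ALPHABET.index))
            clauses.append(f"forbid[{residues}]±{radius}")
        clauses.append(f"mm<={self.max_mismatches}")
        return " ; ".join(clauses)

    @classmethod
    def from_string(cls, text: str) -> "ConsensusPattern":
        clauses = [c.strip() for c in text.split(";")]
        if not clauses or not clauses[0]:
            raise PatternGrammarError("empty pattern", 0)
        positions: list[str] = []
        allowed: list[frozenset[str] | None] = []
        required: set[str] = set()
        for tok in clauses[0].split():
            m = re.match(r"^(P\d+'?):(\.|\[([A-Z]+)\]|[A-Z])(!?)$", tok)
            if not m:
                raise PatternGrammarError(f"bad position token {tok!r}", text.find(tok))
            lab, spec, inner, bang = m.groups()
            positions.append(lab)
            if spec == ".":
                allowed.append(None)
            elif inner is not None:
                allowed.append(frozenset(inner))
            else:
                allowed.append(frozenset(spec))
            if bang:
                required.add(lab)
        required.add("P1")
        forbidden: list[tuple[str, int]] = []
        max_mismatches = 0
        class_by_set = {v: k for k, v in CHEMICAL_CLASSES.items()}
        for clause in clauses[1:]:
            m = re.match(r"^forbid\[([A-Z]+)\](?:±|\+-)(\d+)$", clause)
            if m:
                residues = frozenset(m.group(1))
                if residues not in class_by_set:
                    raise PatternGrammarError(
                        f"forbid set {m.group(1)!r} is not a named residue class",
                        text.find(clause),
                    )
                forbidden.append((class_by_set[residues], int(m.group(2))))
                continue
            m = re.match(r"^mm<=(\d+)$", clause)
            if m:
                max_mismatches = int(m.group(1))
                continue
            raise PatternGrammarError(f"bad clause {clause!r}", text.find(clause))
        return cls(
            positions=positions,
            allowed=allowed,
            required=frozenset(required),
            forbidden_classes=forbidden,
            max_mismatches=max_mismatches,
        )


class PatternGrammarError(ValueError):
    """Raised when a consensus-pattern string cannot be parsed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at character {position})")
        self.position = position


@dataclass
class SpecificityCall:
    """Primary-specificity classification with per-class evidence in [0, 1]."""

    label: str
    evidence: dict[str, float]
    source: str

    LABELS = (
        "tryptase",
        "chymase",
        "asp-ase",
        "elastase",
        "dual(tryptase+chymase)",
        "undetermined",
    )

    def __post_init__(self) -> None:
        if self.label not in self.LABELS:
            raise ValueError(f"unknown specificity label {self.label!r}")


# ---------------------------------------------------------------------------
# operations


def build_pfm(aligned, pseudocount: float = 0.5) -> PositionFrequencyMatrix:
    """Count hard-assigned windows into a pseudocount-smoothed PFM.

    `aligned` is an AlignedCleavageSet or any object with ``window_positions``
    and ``assignments`` attributes, or a plain ``(windows, positions)`` pair.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    if hasattr(aligned, "window_positions"):
        positions = list(aligned.window_positions)
        windows = [a.window for a in aligned.assignments]
    else:
        windows, positions = aligned
        windows = list(windows)
        positions = list(positions)
    if not windows:
        raise ValueError("cannot build a matrix from an empty alignment")
    w = len(positions)
    counts = np.zeros((w, N_AA))
    for win in windows:
        if len(win) != w:
            raise ValueError(f"window {win!r} does not span {w} positions")
        for i, aa in enumerate(win):
            counts[i, AA_INDEX[aa]] += 1
    n = len(windows)
    freqs = (counts + pseudocount) / (n + N_AA * pseudocount)
    return PositionFrequencyMatrix(
        positions=positions,
        frequencies=freqs,
        raw_counts=counts,
        pseudocount=pseudocount,
        n_sequences=n,
    )


def pfm_to_pwm(
    pfm: PositionFrequencyMatrix, background: np.ndarray | None = None
) -> PositionWeightMatrix:
    """Log2-odds weights of the PFM against a background composition."""
    bg = _check_background(background)
    if np.any(pfm.frequencies == 0):
        raise ValueError(
            "zero frequencies cannot be log-transformed; rebuild the matrix "
            "with a positive pseudocount"
        )
    weights = np.log2(pfm.frequencies / bg[None, :])
    return PositionWeightMatrix(
        positions=list(pfm.positions), weights=weights, background=bg
    )


def information_content(
    pfm: PositionFrequencyMatrix, background: np.ndarray | None = None
) -> np.ndarray:
    """Per-position KL divergence from background, in bits (always >= 0)."""
    bg = _check_background(background)
    return rel_entr(pfm.frequencies, bg[None, :]).sum(axis=1) / np.log(2)


def modal_window(pfm: PositionFrequencyMatrix) -> str:
    """The position-wise modal (most frequent residue) window."""
    return "".join(ALPHABET[j] for j in np.argmax(pfm.frequencies, axis=1))


def derive_consensus(
    pfm: PositionFrequencyMatrix,
    majority_threshold: float = 0.6,
    class_threshold: float = 0.7,
    *,
    forbidden_max_frequency: float = 0.02,
    forbid_radius: int = 3,
    max_mismatches: int = 0,
    required_positions: tuple[str, ...] = ("P1",),
) -> ConsensusPattern:
    """Reduce a PFM to a degenerate per-position residue-class pattern.

    At each position the single residue with frequency >= majority_threshold
    wins; failing that, a chemical class whose summed frequency >=
    class_threshold; failing that, the position is unconstrained.  A class
    whose summed frequency stays <= ``forbidden_max_frequency`` at every
    window position is recorded as forbidden within ``forbid_radius`` of P1
    (this captures selections that strikingly exclude e.g. acidic residues
    near the scissile bond).
    """
    if not (0 < majority_threshold <= 1) or not (0 < class_threshold <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    allowed: list[frozenset[str] | None] = []
    for i in range(pfm.width):
        col = pfm.frequencies[i]
        j = int(np.argmax(col))
        if col[j] >= majority_threshold:
            allowed.append(frozenset(ALPHABET[j]))
            continue
        best_class, best_mass = None, 0.0
        for name, residues in CHEMICAL_CLASSES.items():
            mass = sum(col[AA_INDEX[aa]] for aa in residues)
            if mass > best_mass:
                best_class, best_mass = name, mass
        if best_class is not None and best_mass >= class_threshold:
            allowed.append(CHEMICAL_CLASSES[best_class])
        else:
            allowed.append(None)
    forbidden: list[tuple[str, int]] = []
    for name, residues in CHEMICAL_CLASSES.items():
        idx = [AA_INDEX[aa] for aa in residues]
        if np.max(pfm.frequencies[:, idx].sum(axis=1)) <= forbidden_max_frequency:
            forbidden.append((name, forbid_radius))
    return ConsensusPattern(
        positions=list(pfm.positions),
        allowed=allowed,
        required=frozenset(required_positions) | {"P1"},
        forbidden_classes=forbidden,
        max_mismatches=max_mismatches,
    )


def classify_from_class_evidence(
    evidence: dict[str, float],
    source: str,
    *,
    absolute_threshold: float = 0.4,
    relative_threshold: float = 0.5,
) -> SpecificityCall:
    """Shared thresholding rule for PWM- and rate-panel-derived evidence.

    Classes qualify when their evidence is at least ``relative_threshold``
    of the best class; no class reaching ``absolute_threshold`` means
    undetermined; tryptase and chymase qualifying together is called dual.
    """
    best = max(evidence, key=evidence.get)
    if evidence[best] < absolute_threshold:
        return SpecificityCall("undetermined", evidence, source)
    qualifying = {
        c for c, e in evidence.items() if e >= relative_threshold * evidence[best]
    }
    if qualifying >= {"tryptase", "chymase"}:
        return SpecificityCall("dual(tryptase+chymase)", evidence, source)
    return SpecificityCall(best, evidence, source)


def classify_specificity_from_pwm(
    pwm: PositionWeightMatrix | PositionFrequencyMatrix,
    *,
    absolute_threshold: float = 0.4,
    relative_threshold: float = 0.5,
) -> SpecificityCall:
    """Primary-specificity call from the P1 column of a specificity model."""
    if isinstance(pwm, PositionFrequencyMatrix):
        freqs = pwm.frequencies
        positions = pwm.positions
    else:
        freqs = pwm.frequencies()
        positions = pwm.positions
    if "P1" not in positions:
        raise ValueError("model has no P1 column")
    p1 = freqs[positions.index("P1")]
    evidence = {
        label: float(sum(p1[AA_INDEX[aa]] for aa in residues))
        for label, residues in SPECIFICITY_CLASSES.items()
    }
    return classify_from_class_evidence(
        evidence,
        "pwm",
        absolute_threshold=absolute_threshold,
        relative_threshold=relative_threshold,
    )


def score_window(pwm: PositionWeightMatrix, window: str) -> float:
    """Sum of per-position log2-odds weights for a window."""
    if len(window) != pwm.width:
        raise ValueError(
            f"window length {len(window)} does not match model width {pwm.width}"
        )
    total = 0.0
    for i, aa in enumerate(window):
        j = AA_INDEX.get(aa)
        if j is None:
            raise ValueError(f"cannot score ambiguous or unknown residue {aa!r}")
        total += pwm.weights[i, j]
    return float(total)


def match_pattern(pattern: ConsensusPattern, window: str) -> tuple[bool, int]:
    """Match a window against a consensus pattern.

    Returns (passes, mismatches).  The mismatch count covers every position
    whose allowed set is violated, required or not; the pass flag demands
    that all required positions match, that non-required mismatches stay
    within ``max_mismatches``, and that no forbidden-class residue occurs
    within its radius of P1.
    """
    if len(window) != pattern.width:
        raise ValueError(
            f"window length {len(window)} does not match pattern width {pattern.width}"
        )
    offsets = [plabel_to_offset(lab) for lab in pattern.positions]
    mismatches = 0
    nonrequired_mismatches = 0
    required_ok = True
    for lab, allow, aa in zip(pattern.positions, pattern.allowed, window):
        if allow is None or aa in allow:
            continue
        mismatches += 1
        if lab in pattern.required:
            required_ok = False
        else:
            nonrequired_mismatches += 1
    forbidden_hit = False
    for name, radius in pattern.forbidden_classes:
        residues = CHEMICAL_CLASSES[name]
        for off, aa in zip(offsets, window):
            if -radius <= off <= radius and aa in residues:
                forbidden_hit = True
    passes = (
        required_ok
        and nonrequired_mismatches <= pattern.max_mismatches
        and not forbidden_hit
    )
    return passes, mismatches
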