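"""Sliding a cleavage-specificity model across protein collections.

Every admissible P1 placement in every protein is evaluated either with a
log-odds PWM (score threshold) or with a degenerate consensus pattern
(mismatch budget, hard-required positions, forbidden residue classes near
the scissile bond).  Reported windows default to the octamer span P6..P2',
the convention in which near-consensus sites such as the Mucin-5B octamers
are quoted; proteins have no known flanks, so windows truncated by protein
ends (or containing X) are skipped rather than padded, and the skip count is
logged.  No significance model is attached to hits: the scan reports
qualitative near-consensus matches and per-protein counts, deliberately
without multiple-testing correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import ProteinRecord
from .model import (
    ConsensusPattern,
    PositionWeightMatrix,
    match_pattern,
    score_window,
)
from .nomenclature import (
    AA_INDEX,
    CHEMICAL_CLASSES,
    N_AA,
    label_offsets,
    plabel_to_offset,
    window_labels,
)

__all__ = ["ScanHit", "ScanOptions", "scan_proteins", "brute_force_scan",
           "score_window", "match_pattern"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScanHit:
    """A candidate cleavage site; coordinates are 1-based inclusive."""

    protein_id: str
    start: int
    end: int
    p1_position: int
    window: str
    score: float | None = None
    mismatches: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.window):
            raise ValueError("window length does not match the reported span")
        if not (self.start <= self.p1_position <= self.end):
            raise ValueError("p1_position must lie inside the reported span")


@dataclass
class ScanOptions:
    """Scan configuration.

    ``threshold`` applies in PWM mode (minimum log2-odds score).  The
    reported window spans ``report_start``..``report_end`` (default the
    octamer P6..P2') and must cover P1.  ``overlap_policy`` 'best-per-p1'
    keeps only the best-scoring window per P1 position ('all' keeps every
    one; with fixed spans there is one window per P1 either way).
    """

    threshold: float = 0.0
    report_start: str = "P6"
    report_end: str = "P2'"
    overlap_policy: str = "all"

    def __post_init__(self) -> None:
        label_offsets(window_labels(self.report_start, self.report_end))
        if self.overlap_policy not in {"all", "best-per-p1"}:
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")


def _model_offsets(model) -> list[int]:
    return [plabel_to_offset(lab) for lab in model.positions]


def scan_proteins(
    proteins: list[ProteinRecord],
    model: PositionWeightMatrix | ConsensusPattern,
    options: ScanOptions | None = None,
) -> list[ScanHit]:
    """Scan proteins with a PWM or consensus pattern; hits sorted by
    (protein_id, start)."""
    options = options or ScanOptions()
    if not proteins:
        raise ValueError("no proteins to scan")
    model_offs = np.array(_model_offsets(model))
    report_offs = np.array(
        label_offsets(window_labels(options.report_start, options.report_end))
    )
    lo = int(min(model_offs.min(), report_offs.min()))
    hi = int(max(model_offs.max(), report_offs.max()))
    pattern_mode = isinstance(model, ConsensusPattern)

    if not pattern_mode:
        weights = model.weights
    else:
        allowed_mask = np.ones((model.width, N_AA), dtype=bool)
        for i, allow in enumerate(model.allowed):
            if allow is not None:
                allowed_mask[i] = False
                for aa in allow:
                    allowed_mask[i, AA_INDEX[aa]] = True
        required_row = np.array(
            [lab in model.required for lab in model.positions], dtype=bool
        )

    hits: list[ScanHit] = []
    n_skipped_short = 0
    n_skipped_x = 0
    for prot in proteins:
        L = len(prot.sequence)
        if L < hi - lo + 1:
            n_skipped_short += 1
            continue
        seq = np.array([AA_INDEX.get(aa, -1) for aa in prot.sequence], dtype=np.int64)
        # admissible P1 positions (1-based): window and report span inside protein
        p1 = np.arange(max(1, 1 - lo), min(L, L - hi) + 1)
        if p1.size == 0:
            n_skipped_short += 1
            continue
        model_idx = (p1[:, None] - 1) + model_offs[None, :]
        report_idx = (p1[:, None] - 1) + report_offs[None, :]
        model_res = seq[model_idx]
        report_res = seq[report_idx]
        scorable = (model_res >= 0).all(axis=1) & (report_res >= 0).all(axis=1)
        n_skipped_x += int((~scorable).sum())
        if pattern_mode:
            ok_pos = allowed_mask[np.arange(model.width)[None, :], model_res]
            mm_total = (~ok_pos).sum(axis=1)
            required_ok = (ok_pos | ~required_row[None, :]).all(axis=1)
            nonreq_mm = (~ok_pos & ~required_row[None, :]).sum(axis=1)
            forbidden_hit = np.zeros(p1.size, dtype=bool)
            for name, radius in model.forbidden_classes:
                in_radius = np.abs(model_offs) <= radius
                class_idx = np.array([AA_INDEX[aa] for aa in CHEMICAL_CLASSES[name]])
                is_class = np.isin(model_res[:, in_radius], class_idx)
                forbidden_hit |= is_class.any(axis=1)
            passes = (
                scorable
                & required_ok
                & (nonreq_mm <= model.max_mismatches)
                & ~forbidden_hit
            )
            for k in np.nonzero(passes)[0]:
                p = int(p1[k])
                hits.append(
                    ScanHit(
                        protein_id=prot.id,
                        start=p + int(report_offs[0]),
                        end=p + int(report_offs[-1]),
                        p1_position=p,
                        window=prot.sequence[
                            p - 1 + report_offs[0] : p + report_offs[-1]
                        ],
                        mismatches=int(mm_total[k]),
                    )
                )
        else:
            scores = weights[np.arange(model.width)[None, :], model_res].sum(axis=1)
            passes = scorable & (scores >= options.threshold)
            for k in np.nonzero(passes)[0]:
                p = int(p1[k])
                hits.append(
                    ScanHit(
                        protein_id=prot.id,
                        start=p + int(report_offs[0]),
                        end=p + int(report_offs[-1]),
                        p1_position=p,
                        window=prot.sequence[
                            p - 1 + report_offs[0] : p + report_offs[-1]
                        ],
                        score=float(scores[k]),
                    )
                )
    if n_skipped_short:
        logger.info("skipped %d protein(s) shorter than the scan window", n_skipped_short)
    if n_skipped_x:
        logger.info("skipped %d window(s) containing X or truncated spans", n_skipped_x)
    hits.sort(key=lambda h: (h.protein_id, h.start))
    if options.overlap_policy == "best-per-p1":
        best: dict[tuple[str, int], ScanHit] = {}
        for h in hits:
            key = (h.protein_id, h.p1_position)
            cur = best.get(key)
            if cur is None or (h.score is not None and h.score > cur.score):
                best[key] = h
        hits = sorted(best.values(), key=lambda h: (h.protein_id, h.start))
    return hits


def brute_force_scan(
    proteins: list[ProteinRecord],
    model: PositionWeightMatrix | ConsensusPattern,
    options: ScanOptions | None = None,
) -> list[ScanHit]:
    """Naive per-window re-scoring oracle with identical semantics."""
    options = options or ScanOptions()
    model_offs = _model_offsets(model)
    report_offs = label_offsets(window_labels(options.report_start, options.report_end))
    pattern_mode = isinstance(model, ConsensusPattern)
    total = sum(len(p.sequence) for p in proteins)
    if total > 10**6:
        raise ValueError("brute-force scan refuses more than 1e6 residues")
    hits: list[ScanHit] = []
    for prot in proteins:
        L = len(prot.sequence)
        for p1 in range(1, L + 1):
            idxs = [p1 + o for o in model_offs]
            ridxs = [p1 + o for o in report_offs]
            if min(idxs + ridxs) < 1 or max(idxs + ridxs) > L:
                continue
            window = "".join(prot.sequence[i - 1] for i in idxs)
            report = "".join(prot.sequence[i - 1] for i in ridxs)
            if "X" in window or "X" in report:
                continue
            if pattern_mode:
                passes, mismatches = match_pattern(model, window)
                if passes:
                    hits.append(
                        ScanHit(
                            protein_id=prot.id,
                            start=ridxs[0],
                            end=ridxs[-1],
                            p1_position=p1,
                            window=report,
                            mismatches=mismatches,
                        )
                    )
            else:
                score = score_window(model, window)
                if score >= options.threshold:
                    hits.append(
                        ScanHit(
                            protein_id=prot.id,
                            start=ridxs[0],
                            end=ridxs[-1],
                            p1_position=p1,
                            window=report,
                            score=score,
                        )
                    )
    hits.sort(key=lambda h: (h.protein_id, h.start))
    return hits
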