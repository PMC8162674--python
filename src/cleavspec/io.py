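"""Readers and writers for every external representation the pipeline touches.

Formats are deliberately plain text: peptide tables (one nonamer per line, or
comma/tab-delimited with an optional count column), multi-record FASTA,
self-describing specificity-matrix files, tab-separated hit reports, and
delimited assay tables.  All genomic-style coordinates in reports are 1-based
inclusive.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO

from .nomenclature import ALPHABET, validate_sequence

__all__ = [
    "PeptideObservation",
    "ProteinRecord",
    "AbsorbanceSeries",
    "CleavageTimeCourse",
    "ParseError",
    "FormatError",
    "read_peptide_table",
    "write_peptide_table",
    "read_fasta",
    "write_fasta",
    "read_hits",
    "write_hits",
    "read_matrix",
    "write_matrix",
    "read_absorbance_table",
    "write_absorbance_table",
    "read_timecourse_table",
    "write_timecourse_table",
]

NONAMER_LENGTH = 9


class ParseError(ValueError):
    """A malformed row in a delimited or per-line input, with its row number."""

    def __init__(self, message: str, row: int):
        super().__init__(f"row {row}: {message}")
        self.row = row


class FormatError(ValueError):
    """A structurally invalid file (wrong header, missing block, ...)."""


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PeptideObservation:
    """One sequenced phage clone's randomized nonamer insert."""

    sequence: str
    count: int = 1
    label: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) != NONAMER_LENGTH:
            raise ValueError(
                f"insert must be {NONAMER_LENGTH} residues, got "
                f"{len(self.sequence)}: {self.sequence!r}"
            )
        validate_sequence(self.sequence)
        if self.count < 1:
            raise ValueError("count must be a positive integer")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence; X is allowed and treated as unscorable downstream."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        validate_sequence(self.sequence, allow_x=True)


@dataclass
class AbsorbanceSeries:
    """Chromogenic (pNA) substrate time series: replicate A405 plus a blank.

    ``replicates[r][i]`` is replicate r's reading at ``times[i]`` (minutes);
    ``blank[i]`` is the no-enzyme control at the same time point.
    """

    substrate_id: str
    substrate_sequence: str  # P4..P1 (or P3..P1) residues preceding the pNA
    times: np.ndarray
    replicates: np.ndarray
    blank: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.replicates = np.atleast_2d(np.asarray(self.replicates, dtype=float))
        self.blank = np.asarray(self.blank, dtype=float)
        if self.times.size < 2:
            raise ValueError("an absorbance series needs at least two time points")
        if self.times[0] != 0 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing and start at 0")
        if self.replicates.shape[1] != self.times.size:
            raise ValueError("replicate readings do not align with time points")
        if self.blank.shape != self.times.shape:
            raise ValueError("blank readings do not align with time points")
        validate_sequence(self.substrate_sequence)

    @property
    def n_replicates(self) -> int:
        return self.replicates.shape[0]


@dataclass
class CleavageTimeCourse:
    """Gel-based fraction-cleaved time course for a recombinant substrate."""

    substrate_name: str
    insert_sequence: str
    times: np.ndarray
    fraction_cleaved: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_cleaved = np.asarray(self.fraction_cleaved, dtype=float)
        if self.times[0] != 0:
            raise ValueError("time courses must start at t=0")
        if np.any((self.fraction_cleaved < 0) | (self.fraction_cleaved > 1)):
            raise ValueError("fraction_cleaved values must lie in [0, 1]")
        if self.fraction_cleaved.shape != self.times.shape:
            raise ValueError("fractions do not align with time points")
        validate_sequence(self.insert_sequence)


# ---------------------------------------------------------------------------
# helpers


def _open_text(source, mode: str = "r"):
    """Return (handle, needs_close) for a path or an open text stream."""
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, encoding="utf-8", newline=None), True
    return source, False


def _read_text(source) -> str:
    handle, close = _open_text(source)
    try:
        return handle.read()
    finally:
        if close:
            handle.close()


def _write_text(text: str, dest) -> str:
    if dest is not None:
        handle, close = _open_text(dest, "w")
        try:
            handle.write(text)
        finally:
            if close:
                handle.close()
    return text


# ---------------------------------------------------------------------------
# peptide tables


def read_peptide_table(source, dialect: str = "plain") -> list[PeptideObservation]:
    """Parse a peptide table; duplicates stay as separate rows.

    ``plain``: one nonamer per line.  ``delimited``: comma- or tab-separated
    ``sequence[,count[,label]]``.  Lines that are empty or start with '#' are
    skipped.  Malformed rows raise :class:`ParseError` naming the row.
    """
    if dialect not in {"plain", "delimited"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    observations: list[PeptideObservation] = []
    for row, line in enumerate(_read_text(source).splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if dialect == "plain":
            seq, count, label = line, 1, None
        else:
            fields = [f.strip() for f in (line.split("\t") if "\t" in line else line.split(","))]
            seq = fields[0]
            count, label = 1, None
            if len(fields) > 1 and fields[1]:
                try:
                    count = int(fields[1])
                except ValueError:
                    raise ParseError(f"count {fields[1]!r} is not an integer", row) from None
            if len(fields) > 2 and fields[2]:
                label = fields[2]
            if len(fields) > 3:
                raise ParseError(f"too many fields ({len(fields)})", row)
        try:
            observations.append(PeptideObservation(seq.upper(), count, label))
        except ValueError as exc:
            raise ParseError(str(exc), row) from None
    return observations


def write_peptide_table(peptides: list[PeptideObservation], dest=None) -> str:
    """Write peptides in the delimited dialect (sequence, count, label)."""
    lines = [
        "\t".join([p.sequence, str(p.count), p.label or ""]).rstrip("\t")
        for p in peptides
    ]
    return _write_text("\n".join(lines) + ("\n" if lines else ""), dest)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(source) -> list[ProteinRecord]:
    """Read a multi-record FASTA stream; wrapped lines and CRLF tolerated."""
    text = _read_text(source)
    stripped = [ln for ln in text.splitlines() if ln.strip()]
    if not stripped:
        return []
    if not stripped[0].lstrip().startswith(">"):
        raise FormatError("first non-empty line is not a FASTA header")
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).replace(" ", "").upper()
        records.append(ProteinRecord(rec.id, rec.description, seq))
    return records


def write_fasta(records: list[ProteinRecord], dest=None, width: int = 60) -> str:
    lines = []
    for rec in records:
        header = f">{rec.description}" if rec.description else f">{rec.id}"
        if rec.description and not rec.description.startswith(rec.id):
            header = f">{rec.id} {rec.description}"
        lines.append(header)
        for i in range(0, len(rec.sequence), width):
            lines.append(rec.sequence[i : i + width])
    return _write_text("\n".join(lines) + ("\n" if lines else ""), dest)


# ---------------------------------------------------------------------------
# hit reports

HIT_COLUMNS = ["protein_id", "start", "end", "p1_position", "window", "score", "mismatches"]


def write_hits(hits, dest=None) -> str:
    """Tab-delimited hit report, stably sorted by (protein_id, start).

    Scores (PWM mode) and mismatch counts (pattern mode) are mutually
    exclusive; the absent field is written as an empty cell.  Coordinates
    are 1-based inclusive.
    """
    rows = []
    for h in sorted(hits, key=lambda h: (h.protein_id, h.start)):
        rows.append(
            [
                h.protein_id,
                str(h.start),
                str(h.end),
                str(h.p1_position),
                h.window,
                "" if h.score is None else format(h.score, ".17g"),
                "" if h.mismatches is None else str(h.mismatches),
            ]
        )
    lines = ["\t".join(HIT_COLUMNS)] + ["\t".join(r) for r in rows]
    return _write_text("\n".join(lines) + "\n", dest)


def read_hits(source) -> "list":
    """Parse a hit report written by :func:`write_hits`."""
    from .scan import ScanHit  # local import to avoid a cycle

    text = _read_text(source)
    lines = [ln for ln in text.splitlines() if ln]
    if not lines or lines[0].split("\t") != HIT_COLUMNS:
        raise FormatError("hit report is missing its header row")
    hits = []
    for row, line in enumerate(lines[1:], start=2):
        f = line.split("\t")
        if len(f) != len(HIT_COLUMNS):
            raise ParseError(f"expected {len(HIT_COLUMNS)} fields, got {len(f)}", row)
        hits.append(
            ScanHit(
                protein_id=f[0],
                start=int(f[1]),
                end=int(f[2]),
                p1_position=int(f[3]),
                window=f[4],
                score=float(f[5]) if f[5] else None,
                mismatches=int(f[6]) if f[6] else None,
            )
        )
    return hits


# ---------------------------------------------------------------------------
# specificity-matrix files


def write_matrix(pfm, background=None, dest=None) -> str:
    """Self-describing text serialization of a PositionFrequencyMatrix.

    Records the alphabet order, the P-position labels, the pseudocount, the
    number of sequences, the background composition, raw counts (when the
    matrix was estimated from data) and the frequency rows.  Values round-trip
    through :func:`read_matrix` to better than 12 decimal places.
    """
    from .model import uniform_background

    bg = uniform_background() if background is None else np.asarray(background, float)
    lines = [
        "# cleavspec position frequency matrix",
        f"alphabet\t{ALPHABET}",
        "positions\t" + " ".join(pfm.positions),
        f"pseudocount\t{format(pfm.pseudocount, '.17g')}",
        f"n_sequences\t{pfm.n_sequences}",
        "background\t" + " ".join(format(x, ".17g") for x in bg),
    ]
    if pfm.raw_counts is not None:
        for lab, row in zip(pfm.positions, pfm.raw_counts):
            lines.append(f"count\t{lab}\t" + " ".join(format(x, ".17g") for x in row))
    for lab, row in zip(pfm.positions, pfm.frequencies):
        lines.append(f"freq\t{lab}\t" + " ".join(format(x, ".17g") for x in row))
    return _write_text("\n".join(lines) + "\n", dest)


def read_matrix(source):
    """Parse a matrix file; returns (PositionFrequencyMatrix, background)."""
    from .model import PositionFrequencyMatrix

    header: dict[str, str] = {}
    counts: dict[str, np.ndarray] = {}
    freqs: dict[str, np.ndarray] = {}
    background = None
    for line in _read_text(source).splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        key = fields[0]
        if key in {"alphabet", "positions", "pseudocount", "n_sequences"}:
            header[key] = fields[1]
        elif key == "background":
            background = np.array([float(x) for x in fields[1].split()])
        elif key in {"count", "freq"}:
            target = counts if key == "count" else freqs
            target[fields[1]] = np.array([float(x) for x in fields[2].split()])
        else:
            raise FormatError(f"unknown matrix-file line {key!r}")
    for required in ("alphabet", "positions", "pseudocount", "n_sequences"):
        if required not in header:
            raise FormatError(f"matrix file is missing its {required} line")
    if background is None:
        raise FormatError("matrix file is missing its background block")
    if header["alphabet"] != ALPHABET:
        raise FormatError("matrix file alphabet does not match " + ALPHABET)
    positions = header["positions"].split()
    for lab in list(counts) + list(freqs):
        if lab not in positions:
            raise FormatError(f"unknown position label {lab!r} in matrix file")
    if set(freqs) != set(positions):
        raise FormatError("matrix file is missing frequency rows")
    freq_arr = np.stack([freqs[lab] for lab in positions])
    count_arr = (
        np.stack([counts[lab] for lab in positions]) if set(counts) == set(positions) else None
    )
    pfm = PositionFrequencyMatrix(
        positions=positions,
        frequencies=freq_arr,
        raw_counts=count_arr,
        pseudocount=float(header["pseudocount"]),
        n_sequences=int(header["n_sequences"]),
    )
    return pfm, background


# ---------------------------------------------------------------------------
# assay tables


def write_absorbance_table(series_list: list[AbsorbanceSeries], dest=None) -> str:
    """Long-format table: substrate, sequence, time, replicate, A405, blank."""
    rows = []
    for s in series_list:
        for r in range(s.n_replicates):
            for i, t in enumerate(s.times):
                rows.append(
                    {
                        "substrate": s.substrate_id,
                        "sequence": s.substrate_sequence,
                        "time": t,
                        "replicate": r + 1,
                        "a405": s.replicates[r, i],
                        "blank": s.blank[i],
                    }
                )
    text = pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.10g")
    return _write_text(text, dest)


def read_absorbance_table(source) -> list[AbsorbanceSeries]:
    df = pd.read_csv(_io.StringIO(_read_text(source)), sep="\t")
    expected = {"substrate", "sequence", "time", "replicate", "a405", "blank"}
    if not expected <= set(df.columns):
        raise FormatError(f"absorbance table must have columns {sorted(expected)}")
    out = []
    for (sub, seq), grp in df.groupby(["substrate", "sequence"], sort=False):
        times = np.sort(grp["time"].unique())
        reps = np.sort(grp["replicate"].unique())
        mat = np.full((len(reps), len(times)), np.nan)
        blank = np.full(len(times), np.nan)
        t_idx = {t: i for i, t in enumerate(times)}
        r_idx = {r: i for i, r in enumerate(reps)}
        for _, row in grp.iterrows():
            mat[r_idx[row["replicate"]], t_idx[row["time"]]] = row["a405"]
            blank[t_idx[row["time"]]] = row["blank"]
        if np.any(np.isnan(mat)) or np.any(np.isnan(blank)):
            raise FormatError(f"incomplete replicate grid for substrate {sub!r}")
        out.append(AbsorbanceSeries(str(sub), str(seq), times, mat, blank))
    return out


def write_timecourse_table(courses: list[CleavageTimeCourse], dest=None) -> str:
    rows = [
        {
            "substrate": c.substrate_name,
            "insert": c.insert_sequence,
            "time": t,
            "fraction": f,
        }
        for c in courses
        for t, f in zip(c.times, c.fraction_cleaved)
    ]
    text = pd.DataFrame(rows).to_csv(sep="\t", index=False, float_format="%.10g")
    return _write_text(text, dest)


def read_timecourse_table(source) -> list[CleavageTimeCourse]:
    df = pd.read_csv(_io.StringIO(_read_text(source)), sep="\t")
    expected = {"substrate", "insert", "time", "fraction"}
    if not expected <= set(df.columns):
        raise FormatError(f"time-course table must have columns {sorted(expected)}")
    out = []
    for (sub, ins), grp in df.groupby(["substrate", "insert"], sort=False):
        grp = grp.sort_values("time")
        out.append(
            CleavageTimeCourse(
                str(sub), str(ins), grp["time"].to_numpy(), grp["fraction"].to_numpy()
            )
        )
    return out
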