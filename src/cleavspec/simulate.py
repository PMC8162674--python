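"""Synthetic inputs with the statistical structure the pipeline assumes.

Everything the analysis consumes can be generated here: planted
specificity models for the four enzyme archetypes characterised by phage
display (a poly-Arg tryptase, an Asp-P1/P3 asp-ase with aromatic P4, an
F/Y-K tryptase with a basic P3' and no acidic neighbours, and an F/Y-P1
chymase with Leu at P2'), biopanning selection dynamics over a scaled-down
nonamer library, sequenced clone samples, proteomes with planted
near-consensus sites, and noisy assay readouts.

The biopanning model: each clone's per-round cleavage (release) probability
is a logistic function of its best-register log-odds score under the planted
matrix, floored at a spontaneous release probability shared with the
no-enzyme control; released phage counts are binomial, and the released pool
is re-amplified by unbiased multinomial resampling to the library size for
the next round.  The default library holds 1e5 clones - a desk-scale
stand-in for the ~5e7-clone experimental library - and 5 selection rounds
with a final sequenced sample of 96 clones mirror the bench protocol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from scipy.special import expit

from .align import LibraryContext
from .io import (
    AbsorbanceSeries,
    CleavageTimeCourse,
    PeptideObservation,
    ProteinRecord,
)
from .model import (
    ConsensusPattern,
    PositionFrequencyMatrix,
    derive_consensus,
    modal_window,
    pfm_to_pwm,
)
from .nomenclature import (
    ALPHABET,
    AA_INDEX,
    N_AA,
    label_offsets,
    window_labels,
)

__all__ = [
    "TruthModel",
    "BiopanningConfig",
    "RoundSummary",
    "Plant",
    "PlantedSite",
    "PlantedProteome",
    "TRUTH_MODEL_NAMES",
    "DEFAULT_SUBSTRATE_PANEL",
    "make_truth_model",
    "simulate_library",
    "simulate_biopanning",
    "sample_cleaved_clones",
    "simulate_proteome",
    "simulate_assays",
    "simulate_titration",
    "best_register_scores",
]

TRUTH_MODEL_NAMES = ("polyR-tryptase", "aspase", "FK-tryptase", "FY-chymase")

#: The eleven chromogenic substrates of the bench panel (P-side residues
#: preceding the pNA leaving group; the last residue is P1).
DEFAULT_SUBSTRATE_PANEL: list[tuple[str, str]] = [
    ("Suc-AAPF-pNA", "AAPF"),
    ("Suc-LLVY-pNA", "LLVY"),
    ("Suc-AAPI-pNA", "AAPI"),
    ("Suc-AAPA-pNA", "AAPA"),
    ("Suc-AAPL-pNA", "AAPL"),
    ("Suc-AAPV-pNA", "AAPV"),
    ("Suc-VLGR-pNA", "VLGR"),
    ("Suc-GPR-pNA", "GPR"),
    ("Suc-YVAD-pNA", "YVAD"),
    ("Suc-VEID-pNA", "VEID"),
    ("Suc-IEPD-pNA", "IEPD"),
]


@dataclass
class TruthModel:
    """A planted specificity model: frequency matrix plus derived pattern."""

    name: str
    pfm: PositionFrequencyMatrix
    pattern: ConsensusPattern


@dataclass
class BiopanningConfig:
    """Parameters of the simulated selection.

    ``score_midpoint`` may be None, in which case it is placed at the
    99.9th percentile of the best-register score distribution of the
    unselected (background) library, so that only the rare strongly
    cleavable clones start the selection with a high release probability.
    """

    library_size: int = 100_000
    rounds: int = 5
    p_max: float = 0.5
    p_background: float = 0.001
    score_midpoint: float | None = None
    score_slope: float = 1.0
    sample_size: int = 96
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_background < self.p_max < 1):
            raise ValueError("need 0 < p_background < p_max < 1")
        if self.rounds < 1 or self.library_size < 1 or self.sample_size < 1:
            raise ValueError("rounds, library_size and sample_size must be >= 1")


@dataclass
class RoundSummary:
    """Counts from one selection round (enzyme aliquot vs buffer control)."""

    round: int
    released_enzyme: int
    released_control: int
    enrichment_fold: float  # NaN when the control released nothing
    top_clone_fraction: float
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class Plant:
    """One planned planted site: which protein, where P1 goes, and how the
    window is chosen ('consensus' = the modal window, 'sample' = drawn from
    the planted matrix, or an explicit window string with optional explicit
    P-labels)."""

    protein: int
    p1: int
    mode: str = "consensus"
    window: str | None = None
    positions: tuple[str, ...] | None = None


@dataclass(frozen=True)
class PlantedSite:
    protein_id: str
    p1_position: int
    window: str
    mismatches: int
    accidental: bool = False


@dataclass
class PlantedProteome:
    proteins: list[ProteinRecord]
    registry: list[PlantedSite] = field(default_factory=list)


# ---------------------------------------------------------------------------
# truth models


def _column(
    preferred: str = "",
    sharpness: float = 0.9,
    depleted: str = "",
    depleted_frequency: float = 1e-3,
) -> np.ndarray:
    """A frequency column: ``sharpness`` mass shared by the preferred set,
    near-zero mass on depleted residues, the rest spread uniformly."""
    col = np.zeros(N_AA)
    pref = [AA_INDEX[aa] for aa in preferred]
    depl = [AA_INDEX[aa] for aa in depleted if aa not in preferred]
    rest = [j for j in range(N_AA) if j not in pref and j not in depl]
    s = sharpness if pref else 0.0
    for j in pref:
        col[j] = s / len(pref)
    for j in depl:
        col[j] = depleted_frequency
    remainder = 1.0 - s - depleted_frequency * len(depl)
    for j in rest:
        col[j] = remainder / len(rest)
    return col


def make_truth_model(
    name: str,
    sharpness: float = 0.9,
    positions: list[str] | None = None,
) -> TruthModel:
    """Planted model for one of the four named enzyme archetypes.

    ``sharpness`` is the fraction of column mass placed on the preferred
    residue set of each informative position; the remaining mass is spread
    uniformly.  In the sharpness -> 1/20 limit every column is uniform and
    the derived pattern is all-'any'.
    """
    if not (0 < sharpness <= 1):
        raise ValueError("sharpness must lie in (0, 1]")
    positions = positions or window_labels("P4", "P3'")
    prefs: dict[str, str]
    depleted = ""
    if name == "polyR-tryptase":
        prefs = {"P2": "R", "P1": "R", "P1'": "R"}
    elif name == "aspase":
        prefs = {"P4": "FYW", "P3": "D", "P1": "D", "P6": "E"}
    elif name == "FK-tryptase":
        prefs = {"P2": "FY", "P1": "K", "P3'": "RK"}
        depleted = "DE"
    elif name == "FY-chymase":
        prefs = {"P1": "FY", "P2'": "L"}
    else:
        raise ValueError(
            f"unknown truth model {name!r}; choose from {TRUTH_MODEL_NAMES}"
        )
    freqs = np.stack(
        [
            _column(prefs.get(lab, ""), sharpness, depleted=depleted)
            for lab in positions
        ]
    )
    pfm = PositionFrequencyMatrix(positions=list(positions), frequencies=freqs)
    pattern = derive_consensus(pfm)
    return TruthModel(name=name, pfm=pfm, pattern=pattern)


# ---------------------------------------------------------------------------
# libraries and scoring


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_library(
    n: int, composition: np.ndarray | None = None, seed=0
) -> list[PeptideObservation]:
    """Independent nonamers drawn from a residue composition (default uniform)."""
    if n < 1:
        raise ValueError("library size must be >= 1")
    rng = _as_rng(seed)
    comp = np.full(N_AA, 1.0 / N_AA) if composition is None else np.asarray(composition)
    draws = rng.choice(N_AA, size=(n, 9), p=comp / comp.sum())
    return [PeptideObservation("".join(ALPHABET[j] for j in row)) for row in draws]


def _encode_inserts(inserts: list[str], context: LibraryContext) -> np.ndarray:
    """(n, len(extended)) alphabet indices of flank+insert+flank."""
    ext = [context.extend(s) for s in inserts]
    return np.array([[AA_INDEX[aa] for aa in e] for e in ext], dtype=np.int64)


def best_register_scores(
    inserts: list[str],
    pwm,
    context: LibraryContext | None = None,
) -> np.ndarray:
    """Best log2-odds window score over the 9 admissible registers per insert."""
    context = context or LibraryContext()
    offs = label_offsets(pwm.positions)
    enc = _encode_inserts(inserts, context)
    W = len(offs)
    nf = len(context.n_flank)
    # 0-based extended index of each (register, window position)
    reg_idx = np.array(
        [[nf + i + o for o in offs] for i in range(9)], dtype=np.int64
    )
    if reg_idx.min() < 0 or reg_idx.max() >= enc.shape[1]:
        raise ValueError("model window does not fit the flanked insert")
    res = enc[:, reg_idx]  # (n, 9, W)
    scores = pwm.weights[np.arange(W)[None, None, :], res].sum(axis=2)
    return scores.max(axis=1)


# ---------------------------------------------------------------------------
# biopanning


def simulate_biopanning(
    config: BiopanningConfig,
    truth: TruthModel,
    library: list[PeptideObservation] | None = None,
    context: LibraryContext | None = None,
) -> tuple[list[RoundSummary], list[PeptideObservation]]:
    """Simulate rounds of cleavage selection on an immobilised phage library.

    Returns per-round summaries (release counts with enzyme and with buffer
    control, their ratio as the enrichment fold, and the top-clone fraction
    of the released pool) and the sequenced sample of clones drawn from the
    final released pool.  All randomness flows from ``config.seed``.
    """
    context = context or LibraryContext()
    rng = np.random.default_rng(config.seed)
    if library is None:
        library = simulate_library(config.library_size, seed=rng)
    inserts = [p.sequence for p in library]
    pwm = pfm_to_pwm(truth.pfm)
    scores = best_register_scores(inserts, pwm, context)
    midpoint = config.score_midpoint
    if midpoint is None:
        midpoint = float(np.quantile(scores, 0.999))
    # logistic link between best-register score and cleavage probability
    link = expit(config.score_slope * (scores - midpoint))
    p_cleave = config.p_background + (config.p_max - config.p_background) * link

    counts = np.zeros(len(inserts), dtype=np.int64)
    base = np.array([p.count for p in library], dtype=np.int64)
    counts += base
    # top up or trim to the configured library size
    total0 = counts.sum()
    if total0 != config.library_size:
        counts = rng.multinomial(config.library_size, counts / total0)

    summaries: list[RoundSummary] = []
    sequenced: list[PeptideObservation] = []
    released = None
    for rnd in range(1, config.rounds + 1):
        released = rng.binomial(counts, p_cleave)
        control = int(rng.binomial(counts, config.p_background).sum())
        total_rel = int(released.sum())
        fold = total_rel / control if control > 0 else math.nan
        top = float(released.max() / total_rel) if total_rel > 0 else 0.0
        flagged = control == 0 or total_rel == 0
        note = ""
        if control == 0:
            note = "control released nothing; enrichment fold undefined"
        if total_rel == 0:
            note = "extinction: no phages released by the enzyme"
        summaries.append(
            RoundSummary(rnd, total_rel, control, fold, top, flagged, note)
        )
        if total_rel == 0:
            return summaries, []
        if rnd < config.rounds:
            counts = rng.multinomial(config.library_size, released / total_rel)
    sample = rng.multinomial(config.sample_size, released / released.sum())
    for i in np.nonzero(sample)[0]:
        for _ in range(int(sample[i])):
            sequenced.append(PeptideObservation(inserts[i]))
    return summaries, sequenced


def sample_cleaved_clones(
    truth: TruthModel,
    n: int,
    seed=0,
    context: LibraryContext | None = None,
) -> tuple[list[PeptideObservation], list[int]]:
    """Idealized post-selection sample: windows drawn from the planted matrix.

    Each clone gets a register drawn uniformly from those that keep the full
    model window inside the randomized insert, window residues drawn from the
    planted frequency columns, and the remaining insert positions drawn
    uniformly.  Returns the clones and their true P1 indices (1-based, within
    the flanked sequence), the ground truth for register-recovery checks.
    """
    rng = _as_rng(seed)
    context = context or LibraryContext()
    offs = label_offsets(truth.pfm.positions)
    lo_i = max(1, 1 - offs[0])
    hi_i = min(9, 9 - offs[-1])
    if lo_i > hi_i:
        raise ValueError("model window is too wide to fit inside the insert")
    clones: list[PeptideObservation] = []
    true_p1: list[int] = []
    nf = len(context.n_flank)
    for _ in range(n):
        i = int(rng.integers(lo_i, hi_i + 1))
        insert = list(rng.choice(N_AA, size=9))
        for pos, off in enumerate(offs):
            aa = rng.choice(N_AA, p=truth.pfm.frequencies[pos])
            insert[i - 1 + off] = aa
        clones.append(PeptideObservation("".join(ALPHABET[j] for j in insert)))
        true_p1.append(nf + i)
    return clones, true_p1


# ---------------------------------------------------------------------------
# proteomes


def simulate_proteome(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (300, 800),
    composition: np.ndarray | None = None,
    truth: TruthModel | None = None,
    planting_plan: list[Plant] | None = None,
    seed=0,
) -> PlantedProteome:
    """A synthetic proteome of i.i.d.-composition proteins with planted sites.

    Planted windows are spliced over the background at recorded coordinates;
    overlapping plants are an error.  After planting, accidental background
    matches to the planted pattern are detected with the exhaustive scanner
    and appended to the registry flagged as accidental.
    """
    from .scan import ScanOptions, brute_force_scan

    rng = _as_rng(seed)
    comp = np.full(N_AA, 1.0 / N_AA) if composition is None else np.asarray(composition)
    comp = comp / comp.sum()
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_proteins)
    seqs = [
        list(rng.choice(N_AA, size=int(L), p=comp)) for L in lengths
    ]
    registry: list[PlantedSite] = []
    occupied: dict[int, set[int]] = {}
    consensus = modal_window(truth.pfm) if truth is not None else None
    for plant in planting_plan or []:
        if plant.window is not None:
            window = plant.window
            positions = list(plant.positions) if plant.positions else (
                list(truth.pfm.positions) if truth else None
            )
            if positions is None or len(positions) != len(window):
                raise ValueError("explicit planted windows need matching P-labels")
        elif truth is None:
            raise ValueError("planting without an explicit window needs a truth model")
        elif plant.mode == "consensus":
            window, positions = consensus, list(truth.pfm.positions)
        elif plant.mode == "sample":
            window = "".join(
                ALPHABET[rng.choice(N_AA, p=truth.pfm.frequencies[i])]
                for i in range(truth.pfm.width)
            )
            positions = list(truth.pfm.positions)
        else:
            raise ValueError(f"unknown planting mode {plant.mode!r}")
        offs = label_offsets(positions)
        seq = seqs[plant.protein]
        idxs = [plant.p1 - 1 + o for o in offs]
        if idxs[0] < 0 or idxs[-1] >= len(seq):
            raise ValueError(
                f"planted window does not fit protein {plant.protein} "
                f"(length {len(seq)}) at P1={plant.p1}"
            )
        used = occupied.setdefault(plant.protein, set())
        if used & set(idxs):
            raise ValueError(
                f"overlapping plants in protein {plant.protein} at P1={plant.p1}"
            )
        used.update(idxs)
        for j, aa in zip(idxs, window):
            seq[j] = AA_INDEX[aa]
        mismatches = (
            sum(a != b for a, b in zip(window, consensus)) if consensus else 0
        )
        registry.append(
            PlantedSite(f"synprot{plant.protein + 1}", plant.p1, window, mismatches)
        )
    proteins = [
        ProteinRecord(
            f"synprot{i + 1}",
            f"synprot{i + 1} synthetic background protein",
            "".join(ALPHABET[j] for j in seq),
        )
        for i, seq in enumerate(seqs)
    ]
    if truth is not None:
        planned = {(s.protein_id, s.p1_position) for s in registry}
        opts = ScanOptions(
            report_start=truth.pfm.positions[0], report_end=truth.pfm.positions[-1]
        )
        for hit in brute_force_scan(proteins, truth.pattern, opts):
            if (hit.protein_id, hit.p1_position) not in planned:
                registry.append(
                    PlantedSite(
                        hit.protein_id,
                        hit.p1_position,
                        hit.window,
                        hit.mismatches,
                        accidental=True,
                    )
                )
    return PlantedProteome(proteins=proteins, registry=registry)


# ---------------------------------------------------------------------------
# assays


def _panel_scores(truth: TruthModel, panel) -> list[tuple[str, str, float]]:
    """(id, sequence, score - best attainable score) per panel substrate.

    A pNA substrate exposes only the non-prime side: its last residue is P1
    and earlier residues fill P2, P3, ... .  The score deficit (in bits,
    <= 0) is measured against the best window the scored positions allow.
    """
    pwm = pfm_to_pwm(truth.pfm)
    out = []
    for sub_id, seq in panel:
        labels = [f"P{len(seq) - i}" for i in range(len(seq))]
        missing = [lab for lab in labels if lab not in pwm.positions]
        if missing:
            raise ValueError(f"model lacks positions {missing} for substrate {seq!r}")
        rows = [pwm.positions.index(lab) for lab in labels]
        score = sum(pwm.weights[r, AA_INDEX[aa]] for r, aa in zip(rows, seq))
        s_max = sum(pwm.weights[r].max() for r in rows)
        out.append((sub_id, seq, score - s_max))
    return out


def simulate_assays(
    truth: TruthModel,
    substrate_panel: list[tuple[str, str]] | None = None,
    timecourse_substrates: list[tuple[str, str]] | None = None,
    seed=0,
    *,
    noise_sd: float = 1e-4,
    rate_max: float = 0.002,
    times: tuple[float, ...] = (0, 20, 40, 60, 120, 180, 240, 300, 360),
    n_replicates: int = 3,
    baseline: float = 0.04,
    tc_noise_sd: float = 0.02,
    k_max: float = 0.05,
    tc_times: tuple[float, ...] = (0, 15, 45, 150),
) -> tuple[list[AbsorbanceSeries], list[CleavageTimeCourse]]:
    """Noisy chromogenic series and gel time courses under a planted model.

    Each substrate's planted initial rate is ``rate_max`` scaled down by
    2 to the power of its log-odds deficit from the best substrate the
    scored positions allow; absorbance grows linearly at that rate over a
    constant baseline with Gaussian noise, in triplicate, next to a
    no-enzyme blank.  Gel time courses use a first-order planted rate scaled
    the same way from the insert's best register score.
    """
    rng = _as_rng(seed)
    panel = substrate_panel or DEFAULT_SUBSTRATE_PANEL
    series: list[AbsorbanceSeries] = []
    t = np.asarray(times, dtype=float)
    for sub_id, seq, deficit in _panel_scores(truth, panel):
        rate = rate_max * 2.0 ** max(deficit, -30.0)
        reps = (
            baseline
            + rate * t[None, :]
            + rng.normal(0.0, noise_sd, size=(n_replicates, t.size))
        )
        blank = baseline + rng.normal(0.0, noise_sd, size=t.size)
        series.append(AbsorbanceSeries(sub_id, seq, t, reps, blank))

    courses: list[CleavageTimeCourse] = []
    if timecourse_substrates:
        pwm = pfm_to_pwm(truth.pfm)
        s_max = float(pwm.weights.max(axis=1).sum())
        tct = np.asarray(tc_times, dtype=float)
        for name, insert in timecourse_substrates:
            score = float(best_register_scores([insert], pwm)[0])
            k = k_max * 2.0 ** max(score - s_max, -30.0)
            f = 1.0 - np.exp(-k * tct)
            f = f + rng.normal(0.0, tc_noise_sd, size=tct.size)
            f[tct == 0] = 0.0
            courses.append(
                CleavageTimeCourse(name, insert, tct, np.clip(f, 0.0, 1.0))
            )
    return series, courses


def simulate_titration(
    fold: float,
    amounts: np.ndarray | None = None,
    seed=0,
    *,
    potency: float = 0.5,
    noise_sd: float = 0.02,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Two enzyme-titration curves whose equal-cleavage amounts differ by
    ``fold`` (enzyme B needs ``fold`` times more enzyme than A)."""
    if fold <= 0:
        raise ValueError("fold must be positive")
    rng = _as_rng(seed)
    if amounts is None:
        amounts = np.geomspace(1e-3, 1e4, 30)
    amounts = np.asarray(amounts, dtype=float)

    def curve(strength: float) -> np.ndarray:
        f = 1.0 - np.exp(-strength * amounts)
        f = f + rng.normal(0.0, noise_sd, size=amounts.size)
        return np.clip(f, 0.0, 1.0)

    return (amounts, curve(potency)), (amounts, curve(potency / fold))
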