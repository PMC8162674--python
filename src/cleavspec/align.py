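"""Inferring the cleavage register of phage-selected nonamers.

Each selected phage clone displays a randomized nonamer inside the fixed
capsid context ``PGG(X)9HHHHHH``; the protease cleaved somewhere inside the
insert, but sequencing only reveals the insert, not the scissile bond.  This
module recovers the register: for every peptide it infers which insert
position was P1 and extracts the corresponding P4..P3' window, so that all
clones can be stacked into a single position-specific model.

The model is one-cleavage-site-per-sequence: a peptide's window residues are
drawn from the position frequency matrix, everything else from background;
window positions that fall in the fixed flanks carry no register information
and are masked out of the likelihood.  Registers are latent and estimated by
expectation-maximization (the same machinery as one-occurrence-per-sequence
motif discovery) from nine deterministic single-offset starts plus a seeded
random multi-start; each run is polished by classification EM and exact
coordinate ascent, and coherent-shift restarts guard against gauge-copy
local optima.  The best completed-data penalized log-likelihood found is
reported (directly comparable to the exhaustive oracle); the hard
assignments are then gauge-fixed, by a P1 anchor from substrate-assay
evidence when available, else by centring (see ``_canonicalize_shift``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp, xlogy
from sklearn.base import BaseEstimator

from .io import PeptideObservation
from .model import PositionFrequencyMatrix, build_pfm, _check_background
from .nomenclature import AA_INDEX, N_AA, label_offsets, window_labels

__all__ = [
    "LibraryContext",
    "RegisterAssignment",
    "AlignedCleavageSet",
    "RegisterAligner",
    "candidate_registers",
    "align_registers",
    "brute_force_alignment",
]

INSERT_LENGTH = 9


@dataclass(frozen=True)
class LibraryContext:
    """Fixed capsid residues flanking the randomized nonamer insert."""

    n_flank: str = "PGG"
    c_flank: str = "HHHHHH"

    def __post_init__(self) -> None:
        for flank in (self.n_flank, self.c_flank):
            if any(aa not in AA_INDEX for aa in flank):
                raise ValueError(f"flank {flank!r} contains a non-amino-acid letter")

    def extend(self, insert: str) -> str:
        return self.n_flank + insert + self.c_flank


@dataclass
class RegisterAssignment:
    """One peptide's inferred cleavage register.

    ``p1_index`` is the 1-based position of the P1 residue within the
    extended sequence n_flank + insert + c_flank.
    """

    peptide: PeptideObservation
    p1_index: int
    window: str
    posterior: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.posterior <= 1.0 + 1e-12):
            raise ValueError("posterior must lie in [0, 1]")


@dataclass
class AlignedCleavageSet:
    """All peptides hard-assigned to registers, plus the learned model."""

    assignments: list[RegisterAssignment]
    window_positions: list[str]
    objective: float
    iterations: int
    pfm: PositionFrequencyMatrix | None = None
    posterior_entropy: np.ndarray | None = None


def candidate_registers(
    peptide: PeptideObservation | str,
    context: LibraryContext | None = None,
    window_positions: list[str] | None = None,
) -> list[tuple[int, str]]:
    """All admissible (p1_index, window) placements for one peptide.

    P1 is restricted to the insert positions: cleavage within the fixed
    flanks is identical across clones and cannot have been selected for.
    Window positions falling outside the insert are read from the flanks.
    """
    context = context or LibraryContext()
    positions = window_positions or window_labels()
    offsets = label_offsets(positions)
    insert = peptide.sequence if isinstance(peptide, PeptideObservation) else peptide
    extended = context.extend(insert)
    out: list[tuple[int, str]] = []
    for i in range(1, len(insert) + 1):
        p1 = len(context.n_flank) + i
        lo, hi = p1 + offsets[0], p1 + offsets[-1]
        if lo < 1 or hi > len(extended):
            raise ValueError(
                f"window {positions[0]}..{positions[-1]} does not fit the "
                f"extended sequence for P1 at insert position {i}; use a "
                "narrower window or longer flanks"
            )
        out.append((p1, extended[lo - 1 : hi]))
    return out


def _insert_mask(context: LibraryContext, offsets: list[int]) -> np.ndarray:
    """(9, W) flags: does window position w fall inside the randomized insert
    when P1 sits at insert position r+1?

    The capsid flanks are fixed constants shared by every clone, so residues
    a window reads from a flank carry no information about where cleavage
    occurred; only insert positions enter the register likelihood.  (They do
    still appear in extracted windows and hence in reported count matrices.)
    """
    mask = np.zeros((INSERT_LENGTH, len(offsets)), dtype=bool)
    for r in range(INSERT_LENGTH):
        for w, off in enumerate(offsets):
            mask[r, w] = 1 <= r + 1 + off <= INSERT_LENGTH
    return mask


def _completed_objective(
    counts: np.ndarray, pseudocount: float, log_bg_sum: float
) -> float:
    """Penalized completed-data log-likelihood for hard-assignment counts.

    sum over informative window residues of log f/bg plus the Dirichlet
    penalty pseudocount * sum log f, with f the pseudocount-smoothed (MAP)
    frequencies implied by the counts.  Columns may hold different totals
    because flank-masked positions contribute nothing.  This is the quantity
    both the EM polish and the exhaustive oracle maximize, so the two are
    directly comparable.
    """
    denom = counts.sum(axis=1) + N_AA * pseudocount
    logf = np.log((counts + pseudocount) / denom[:, None])
    return float(((counts + pseudocount) * logf).sum() - log_bg_sum)


def _polish(enc, mask, log_bg, theta, pc):
    """Classification-EM to a local optimum of the completed objective.

    Alternates per-peptide argmax register assignment (ties toward the most
    N-terminal P1) with MAP re-estimation of the frequency matrix; both steps
    are ascent steps on the completed penalized log-likelihood.
    """
    n, R, W = enc.shape
    z = None
    for _ in range(100):
        s = RegisterAligner._register_scores(enc, mask, np.log(theta), log_bg)
        z_new = np.argmax(np.isclose(s, s.max(axis=1, keepdims=True)), axis=1)
        if z is not None and np.array_equal(z, z_new):
            break
        z = z_new
        counts = RegisterAligner._hard_counts(enc, mask, z)
        denom = counts.sum(axis=1) + N_AA * pc
        theta = (counts + pc) / denom[:, None]
    obj = _hard_objective(enc, mask, z, log_bg, pc)
    return z, theta, obj


def _masked_onehot(enc, mask):
    """Flank-masked one-hot count vectors per (peptide, register)."""
    n, R, W = enc.shape
    onehot = np.zeros((n, R, W, N_AA), dtype=np.int8)
    ii, rr, ww = np.meshgrid(np.arange(n), np.arange(R), np.arange(W), indexing="ij")
    onehot[ii, rr, ww, enc] = 1
    onehot *= mask[None, :, :, None]
    return onehot


def _coordinate_ascent(onehot, log_bg_win, z, pc, best_improvement=False):
    """Exact single-peptide coordinate ascent on the completed objective.

    Repeatedly moves one peptide at a time to the register that maximizes
    the joint completed objective (with all other assignments fixed) until
    no move improves it.  Strictly stronger than classification EM, which
    scores candidates under a matrix that still contains the moving
    peptide's own counts.
    """
    n, R, W, _ = onehot.shape
    z = z.copy()
    counts = onehot[np.arange(n), z].sum(axis=0).astype(float)
    bg = float(log_bg_win[np.arange(n), z].sum())
    current = _completed_objective(counts, pc, bg)

    def move_objectives(i):
        base = counts - onehot[i, z[i]]
        base_bg = bg - log_bg_win[i, z[i]]
        cand = base[None, :, :] + onehot[i]  # (R, W, 20)
        denom = cand.sum(axis=2) + N_AA * pc
        logf = np.log((cand + pc) / denom[:, :, None])
        objs = ((cand + pc) * logf).sum(axis=(1, 2)) - (base_bg + log_bg_win[i])
        return objs

    def apply(i, r, obj):
        nonlocal counts, bg, current
        counts = counts - onehot[i, z[i]] + onehot[i, r]
        bg = bg - float(log_bg_win[i, z[i]]) + float(log_bg_win[i, r])
        z[i] = r
        current = float(obj)

    if best_improvement:
        # take the single best improving move per iteration: slower, but the
        # path cannot be dragged off a basin by an early mediocre move
        for _ in range(100 * n):
            best_move = None
            for i in range(n):
                objs = move_objectives(i)
                r = int(np.argmax(objs))
                if objs[r] > current + 1e-10 and (
                    best_move is None or objs[r] > best_move[2]
                ):
                    best_move = (i, r, float(objs[r]))
            if best_move is None:
                break
            apply(*best_move)
        return z, current

    for _ in range(50):
        improved = False
        for i in range(n):
            objs = move_objectives(i)
            r = int(np.argmax(objs))
            if objs[r] > current + 1e-10:
                apply(i, r, objs[r])
                improved = True
        if not improved:
            break
    return z, current


def _pair_ascent(onehot, log_bg_win, z, pc):
    """Joint two-peptide moves on the completed objective (small n only).

    Noise-dominated instances have optima reachable only by moving two
    peptides together; with n <= 8 the 81 joint register choices per pair
    are cheap to scan exhaustively.
    """
    n, R, W, _ = onehot.shape
    z = z.copy()
    counts = onehot[np.arange(n), z].sum(axis=0).astype(float)
    bg = float(log_bg_win[np.arange(n), z].sum())
    current = _completed_objective(counts, pc, bg)
    ra, rb = np.divmod(np.arange(R * R), R)
    for _ in range(20):
        improved = False
        for i in range(n):
            for j in range(i + 1, n):
                base = counts - onehot[i, z[i]] - onehot[j, z[j]]
                base_bg = bg - log_bg_win[i, z[i]] - log_bg_win[j, z[j]]
                cand = base[None] + onehot[i, ra] + onehot[j, rb]  # (81, W, 20)
                denom = cand.sum(axis=2) + N_AA * pc
                logf = np.log((cand + pc) / denom[:, :, None])
                objs = ((cand + pc) * logf).sum(axis=(1, 2)) - (
                    base_bg + log_bg_win[i, ra] + log_bg_win[j, rb]
                )
                k = int(np.argmax(objs))
                if objs[k] > current + 1e-10:
                    z[i], z[j] = int(ra[k]), int(rb[k])
                    counts = base + onehot[i, z[i]] + onehot[j, z[j]]
                    bg = base_bg + float(log_bg_win[i, z[i]] + log_bg_win[j, z[j]])
                    current = float(objs[k])
                    improved = True
        if not improved:
            break
    return z, current


def _gauge_fix(enc, mask, z, log_bg, pc, p1_col=0, anchor_idx=()):
    """Gauge-fix a hard assignment, then re-polish within the chosen gauge.

    Returns (z, theta).  The polished assignment's own completed objective
    may sit slightly below the unconstrained optimum: the gauge convention
    (anchor or centring) deliberately trades a few hundredths of a nat per
    peptide for an identifiable P1 placement.
    """
    z = _canonicalize_shift(enc, mask, z, log_bg, pc, p1_col, anchor_idx)
    counts = RegisterAligner._hard_counts(enc, mask, z)
    denom = counts.sum(axis=1) + N_AA * pc
    theta = (counts + pc) / denom[:, None]
    z, theta, _ = _polish(enc, mask, log_bg, theta, pc)
    return z, theta


def _hard_objective(enc, mask, z, log_bg, pc):
    """Completed objective of a hard assignment vector."""
    counts = RegisterAligner._hard_counts(enc, mask, z)
    n = enc.shape[0]
    bg_sum = float(
        sum((log_bg[enc[i, z[i], :]] * mask[z[i]]).sum() for i in range(n))
    )
    return _completed_objective(counts, pc, bg_sum)


def _canonicalize_shift(
    enc,
    mask,
    z,
    log_bg,
    pc,
    p1_col: int = 0,
    anchor_idx: tuple[int, ...] = (),
    tol_per_peptide: float = 0.25,
):
    """Resolve the coherent register-shift gauge freedom.

    The one-site-per-sequence likelihood is near-invariant to shifting every
    assignment by the same offset whenever the motif's informative columns
    stay inside the window (e.g. a poly-Arg run reads identically at P2-P1'
    and P1-P2'); residual differences between such gauge copies are a
    fraction of a nat per peptide, whereas pushing a genuinely informative
    column out of the window costs on the order of a nat per peptide.
    Shifts within ``tol_per_peptide`` nats per peptide of the best shift are
    therefore treated as gauge copies of one motif.

    Phage inserts alone cannot say which gauge copy carries the true
    scissile bond - the experimental analogue is that substrate assays, not
    phage display, ultimately place P1.  Among tied gauges the rule is:
    if a P1 anchor (a residue class known from a substrate assay to occupy
    P1) is supplied, pick the gauge putting the most anchor mass in the P1
    column; otherwise pick the gauge whose mean cleavage position sits
    closest to the centre of the randomized insert, the symmetric default.
    """
    n, R, _ = enc.shape
    center = (R - 1) / 2.0
    candidates = []
    for s in range(-(R - 1), R):
        # stray assignments that a coherent shift would push past the insert
        # are clamped, then the whole candidate is re-polished so that a few
        # stragglers cannot misprice an otherwise coherent gauge
        zs = np.clip(z + s, 0, R - 1)
        counts = RegisterAligner._hard_counts(enc, mask, zs)
        denom = counts.sum(axis=1) + N_AA * pc
        theta = (counts + pc) / denom[:, None]
        zs, _, obj = _polish(enc, mask, log_bg, theta, pc)
        candidates.append((s, zs, obj))
    best_obj = max(obj for _, _, obj in candidates)
    tol = tol_per_peptide * n
    tied = [(s, zs) for s, zs, obj in candidates if obj >= best_obj - tol]

    def centring(item):
        s, zs = item
        return (abs(float(np.mean(zs)) - center), abs(s), s)

    if anchor_idx:
        def anchor_mass(item):
            counts = RegisterAligner._hard_counts(enc, mask, item[1])
            return float(counts[p1_col, list(anchor_idx)].sum())

        tied.sort(key=lambda t: (-anchor_mass(t),) + centring(t))
    else:
        tied.sort(key=centring)
    return tied[0][1]


class RegisterAligner(BaseEstimator):
    """EM estimator for cleavage registers of phage-selected nonamers.

    Parameters
    ----------
    window_start, window_end : P-labels bounding the modelled window
        (default P4..P3'; anything from P6 to P4' fits the default flanks
        except at the outermost insert positions).
    pseudocount : Dirichlet-style smoothing added per residue per column.
    background : residue background composition (None = uniform 1/20).
    max_iter, tol : EM stopping rule (absolute objective improvement).
    n_starts : number of random restarts in addition to the nine
        deterministic single-offset starts.
    seed : seeds the restart generator; fixed seed means bit-identical fits.

    Fitted attributes
    -----------------
    pfm_ : learned PositionFrequencyMatrix (from the final hard assignments)
    assignments_ : list of RegisterAssignment, one per peptide
    objective_ : best completed-data penalized log-likelihood found
        (natural log).  The reported assignments are subsequently
        gauge-fixed (see ``p1_anchor``), so their own completed objective
        can sit marginally below this optimum.
    objective_path_ : per-iteration soft-EM objective of the winning start
    posteriors_ : (n_peptides, 9) register posteriors under the final model
    posterior_entropy_ : per-peptide entropy (nats) of those posteriors;
        large values flag peptides whose cleavage position is genuinely
        ambiguous rather than confidently assigned.
    """

    def __init__(
        self,
        window_start: str = "P4",
        window_end: str = "P3'",
        pseudocount: float = 0.5,
        background=None,
        max_iter: int = 500,
        tol: float = 1e-9,
        n_starts: int = 10,
        seed: int = 0,
        context: LibraryContext | None = None,
        p1_anchor: str | None = None,
    ):
        self.window_start = window_start
        self.window_end = window_end
        self.pseudocount = pseudocount
        self.background = background
        self.max_iter = max_iter
        self.tol = tol
        self.n_starts = n_starts
        self.seed = seed
        self.context = context
        self.p1_anchor = p1_anchor

    # -- internal ---------------------------------------------------------

    def _prepare(self, peptides):
        peptides = [
            p if isinstance(p, PeptideObservation) else PeptideObservation(p)
            for p in peptides
        ]
        context = self.context or LibraryContext()
        positions = window_labels(self.window_start, self.window_end)
        cands = [candidate_registers(p, context, positions) for p in peptides]
        # encoded windows: (n, R, W) alphabet indices
        enc = np.array(
            [[[AA_INDEX[aa] for aa in win] for _, win in c] for c in cands],
            dtype=np.int64,
        )
        p1s = np.array([[p1 for p1, _ in c] for c in cands], dtype=np.int64)
        return peptides, context, positions, cands, enc, p1s

    @staticmethod
    def _hard_counts(enc, mask, z):
        """Flank-masked residue counts for hard assignments z."""
        n, R, W = enc.shape
        counts = np.zeros((W, N_AA))
        for r in range(R):
            rows = np.nonzero(z == r)[0]
            if rows.size == 0:
                continue
            cols = np.nonzero(mask[r])[0]
            np.add.at(counts, (cols[None, :], enc[rows[:, None], r, cols[None, :]]), 1.0)
        return counts

    @staticmethod
    def _register_scores(enc, mask, log_theta, log_bg):
        """s[i, r] = masked window log-odds under frequencies exp(log_theta)."""
        W = enc.shape[2]
        lo = log_theta - log_bg[None, :]
        vals = lo[np.arange(W)[None, None, :], enc]  # (n, R, W)
        return (vals * mask[None, :, :]).sum(axis=2)

    def _soft_em(self, enc, mask, log_bg, rng, init):
        """One EM run; returns (theta, objective_path)."""
        n, R, W = enc.shape
        pc = self.pseudocount

        def _map_theta(counts):
            denom = counts.sum(axis=1) + N_AA * pc
            return (counts + pc) / denom[:, None]

        if isinstance(init, int):
            # deterministic start: align every peptide at one common offset
            counts = self._hard_counts(enc, mask, np.full(n, init))
            theta = _map_theta(counts)
        else:
            theta = rng.dirichlet(np.ones(N_AA), size=W)
        path = []
        prev = -np.inf
        for _ in range(self.max_iter):
            s = self._register_scores(enc, mask, np.log(theta), log_bg)
            lse = logsumexp(s, axis=1)
            obj = float(lse.sum() - n * np.log(R) + pc * np.log(theta).sum())
            path.append(obj)
            resp = np.exp(s - lse[:, None])
            counts = np.zeros((W, N_AA))
            for r in range(R):
                cols = np.nonzero(mask[r])[0]
                np.add.at(
                    counts,
                    (cols[None, :], enc[:, r, cols]),
                    resp[:, r][:, None],
                )
            theta = _map_theta(counts)
            if obj - prev < self.tol and len(path) > 1:
                break
            prev = obj
        return theta, np.array(path)

    def _cem_polish(self, enc, mask, log_bg, theta):
        return _polish(enc, mask, log_bg, theta, self.pseudocount)

    # -- estimator API ----------------------------------------------------

    def fit(self, X, y=None):
        """Infer registers for a list of peptides (strings or observations)."""
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.pseudocount <= 0:
            raise ValueError("EM alignment requires a positive pseudocount")
        peptides, context, positions, cands, enc, p1s = self._prepare(X)
        if len(peptides) < 2:
            raise ValueError("register alignment needs at least two peptides")
        bg = _check_background(self.background)
        log_bg = np.log(bg)
        mask = _insert_mask(context, label_offsets(positions))
        rng = np.random.default_rng(self.seed)
        onehot = _masked_onehot(enc, mask)
        log_bg_win = (log_bg[enc] * mask[None, :, :]).sum(axis=2)
        best = None
        inits = list(range(enc.shape[1])) + ["random"] * self.n_starts
        for init in inits:
            theta, path = self._soft_em(enc, mask, log_bg, rng, init)
            z, theta_h, obj = self._cem_polish(enc, mask, log_bg, theta)
            z, obj = _coordinate_ascent(onehot, log_bg_win, z, self.pseudocount)
            if best is None or obj > best[0] + 1e-12:
                best = (obj, z, path)
        # extra hard restarts: coordinate ascent from random assignments
        for _ in range(self.n_starts):
            z0 = rng.integers(0, enc.shape[1], size=enc.shape[0])
            z, obj = _coordinate_ascent(onehot, log_bg_win, z0, self.pseudocount)
            if obj > best[0] + 1e-12:
                best = (obj, z, best[2])
        # coherent-shift moves: restart ascent from every clamped global
        # shift of the incumbent (gauge copies are separated by moves no
        # single-peptide step can make)
        R = enc.shape[1]
        incumbent = best[1]
        for s in range(-(R - 1), R):
            if s == 0:
                continue
            z0 = np.clip(incumbent + s, 0, R - 1)
            z, obj = _coordinate_ascent(
                onehot,
                log_bg_win,
                z0,
                self.pseudocount,
                # the costlier basin-preserving move order pays off only on
                # small instances, where single peptides steer the matrix
                best_improvement=enc.shape[0] <= 12,
            )
            if obj > best[0] + 1e-12:
                best = (obj, z, best[2])
        if enc.shape[0] <= 8:
            z, obj = _pair_ascent(onehot, log_bg_win, best[1], self.pseudocount)
            if obj > best[0] + 1e-12:
                best = (obj, z, best[2])
        obj, z, path = best
        anchor_idx = tuple(AA_INDEX[aa] for aa in (self.p1_anchor or ""))
        z, theta = _gauge_fix(
            enc, mask, z, log_bg, self.pseudocount,
            p1_col=positions.index("P1"), anchor_idx=anchor_idx,
        )

        n, R, W = enc.shape
        windows = [cands[i][z[i]][1] for i in range(n)]
        self.pfm_ = build_pfm((windows, positions), pseudocount=self.pseudocount)
        s = self._register_scores(enc, mask, np.log(theta), log_bg)
        self.posteriors_ = np.exp(s - logsumexp(s, axis=1)[:, None])
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = xlogy(self.posteriors_, self.posteriors_)
        self.posterior_entropy_ = -plogp.sum(axis=1)
        self.assignments_ = [
            RegisterAssignment(
                peptide=peptides[i],
                p1_index=int(p1s[i, z[i]]),
                window=windows[i],
                posterior=float(min(self.posteriors_[i, z[i]], 1.0)),
            )
            for i in range(n)
        ]
        self.objective_ = obj
        self.objective_path_ = path
        self.n_iter_ = len(path)
        self.window_positions_ = positions
        return self

    def predict(self, X):
        """Most likely p1_index for each new peptide under the fitted model."""
        if not hasattr(self, "pfm_"):
            raise RuntimeError("RegisterAligner is not fitted")
        peptides, context, positions, cands, enc, p1s = self._prepare(X)
        bg = _check_background(self.background)
        mask = _insert_mask(context, label_offsets(positions))
        s = self._register_scores(
            enc, mask, np.log(self.pfm_.frequencies), np.log(bg)
        )
        z = np.argmax(np.isclose(s, s.max(axis=1, keepdims=True)), axis=1)
        return p1s[np.arange(len(peptides)), z]

    def to_aligned_set(self) -> AlignedCleavageSet:
        return AlignedCleavageSet(
            assignments=self.assignments_,
            window_positions=self.window_positions_,
            objective=self.objective_,
            iterations=self.n_iter_,
            pfm=self.pfm_,
            posterior_entropy=self.posterior_entropy_,
        )


def align_registers(
    peptides,
    context: LibraryContext | None = None,
    **params,
) -> AlignedCleavageSet:
    """Functional wrapper over :class:`RegisterAligner`."""
    aligner = RegisterAligner(context=context, **params)
    aligner.fit(peptides)
    return aligner.to_aligned_set()


def brute_force_alignment(
    peptides,
    context: LibraryContext | None = None,
    window_start: str = "P4",
    window_end: str = "P3'",
    pseudocount: float = 0.5,
    background=None,
    max_peptides: int = 8,
    p1_anchor: str | None = None,
) -> AlignedCleavageSet:
    """Exhaustive test oracle: globally optimal joint register assignment.

    Enumerates every joint hard assignment (9^n combinations) and reports
    the global maximum of the same completed-data penalized log-likelihood
    that :class:`RegisterAligner` maximizes, breaking ties toward the
    lexicographically smallest (most N-terminal) register vector.  The
    returned hard assignments are gauge-fixed with the same convention as
    the estimator, so the two are comparable both by objective and by
    assignment.
    """
    peptides = [
        p if isinstance(p, PeptideObservation) else PeptideObservation(p)
        for p in peptides
    ]
    if len(peptides) > max_peptides:
        raise ValueError(
            f"brute force refuses more than {max_peptides} peptides "
            f"(got {len(peptides)}: 9^n register combinations)"
        )
    context = context or LibraryContext()
    positions = window_labels(window_start, window_end)
    cands = [candidate_registers(p, context, positions) for p in peptides]
    enc = np.array(
        [[[AA_INDEX[aa] for aa in win] for _, win in c] for c in cands], dtype=np.int64
    )
    n, R, W = enc.shape
    bg = _check_background(background)
    mask = _insert_mask(context, label_offsets(positions))
    log_bg_win = (np.log(bg)[enc] * mask[None, :, :]).sum(axis=2)  # (n, R)
    pc = pseudocount
    # tables: h[c] = (c+pc) log(c+pc); H2[m] = -(m + 20 pc) log(m + 20 pc)
    # so that sum_cols sum_aa (c+pc) log((c+pc)/(m_col+20pc)) decomposes as
    # sum h[counts] + sum H2[column totals]
    c_range = np.arange(n + 1, dtype=float) + pc
    h = c_range * np.log(c_range)
    m_range = np.arange(n + 1, dtype=float) + N_AA * pc
    H2 = -(m_range) * np.log(m_range)
    onehot = _masked_onehot(enc, mask)

    total = R**n
    best_obj, best_combo = -np.inf, None
    chunk = 20000
    for lo in range(0, total, chunk):
        idx = np.arange(lo, min(lo + chunk, total))
        # lexicographic enumeration without materializing all 9^n combos
        zc = np.stack(np.unravel_index(idx, (R,) * n), axis=1)  # (C, n)
        counts = onehot[np.arange(n)[None, :], zc].sum(axis=1)  # (C, W, 20)
        col_totals = counts.sum(axis=2)  # (C, W)
        obj = (
            h[counts].sum(axis=(1, 2))
            + H2[col_totals].sum(axis=1)
            - log_bg_win[np.arange(n)[None, :], zc].sum(axis=1)
        )
        k = int(np.argmax(obj))
        if obj[k] > best_obj + 1e-15:
            best_obj, best_combo = float(obj[k]), zc[k]
    anchor_idx = tuple(AA_INDEX[aa] for aa in (p1_anchor or ""))
    z, _ = _gauge_fix(
        enc, mask, np.asarray(best_combo), np.log(bg), pc,
        p1_col=positions.index("P1"), anchor_idx=anchor_idx,
    )
    windows = [cands[i][z[i]][1] for i in range(n)]
    pfm = build_pfm((windows, positions), pseudocount=pseudocount)
    assignments = [
        RegisterAssignment(
            peptide=peptides[i],
            p1_index=cands[i][z[i]][0],
            window=windows[i],
            posterior=1.0,
        )
        for i in range(n)
    ]
    return AlignedCleavageSet(
        assignments=assignments,
        window_positions=positions,
        objective=best_obj,
        iterations=1,
        pfm=pfm,
    )
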