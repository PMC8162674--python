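"""Quantitative readings from substrate assays.

Two experimental designs are supported.  Chromogenic (pNA) substrate panels
give absorbance-vs-time series in triplicate with a no-enzyme blank; the
blank-subtracted initial slope per substrate, grouped by the P1 residue
class, yields a primary-specificity call.  Gel-based time courses of
recombinant two-domain reporter substrates give the fraction cleaved at a
few time points; a single-exponential first-order fit f(t) = 1 - exp(-k t)
summarises each course, and cleavage efficiencies are compared as rate
ratios or - mirroring bench practice when rates saturate - as the ratio of
enzyme amounts needed to reach the same extent of cleavage (titration
equivalence).  Only ratio-level statements are supported: no
substrate-concentration series exist in this design, so Michaelis-Menten
constants are out of reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .io import AbsorbanceSeries, CleavageTimeCourse
from .model import classify_from_class_evidence, SpecificityCall
from .nomenclature import SPECIFICITY_CLASSES

__all__ = [
    "InitialRate",
    "CleavageRate",
    "FoldDifference",
    "initial_rate",
    "classify_specificity_from_rates",
    "fit_first_order",
    "fold_difference_by_rate",
    "titration_equivalence",
]


@dataclass(frozen=True)
class InitialRate:
    """Blank-subtracted initial slope in absorbance units per minute."""

    substrate_id: str
    rate: float
    sd: float
    n_replicates: int

    def __post_init__(self) -> None:
        if self.sd < 0 or self.n_replicates < 1:
            raise ValueError("sd must be >= 0 and n_replicates >= 1")


@dataclass(frozen=True)
class CleavageRate:
    """First-order cleavage rate (per minute) with its fit residual."""

    substrate_name: str
    k: float
    residual: float

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError("a first-order rate cannot be negative")


@dataclass(frozen=True)
class FoldDifference:
    numerator_id: str
    denominator_id: str
    fold: float
    method: str  # 'rate-ratio' or 'titration'

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold differences must be positive")


def initial_rate(
    series: AbsorbanceSeries, fit_window: tuple[float, float] = (0.0, 60.0)
) -> InitialRate:
    """Per-replicate OLS slope of blank-subtracted A405 over the fit window.

    The rate is the mean of the replicate slopes and ``sd`` their standard
    deviation; negative slopes are reported as-is.  The default window
    (0-60 min) covers the early time points where pNA release is linear.
    """
    lo, hi = fit_window
    mask = (series.times >= lo) & (series.times <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"fewer than two time points inside the fit window {fit_window}"
        )
    t = series.times[mask]
    slopes = []
    for r in range(series.n_replicates):
        y = series.replicates[r, mask] - series.blank[mask]
        slopes.append(np.polyfit(t, y, 1)[0])
    slopes = np.asarray(slopes)
    sd = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0
    return InitialRate(
        substrate_id=series.substrate_id,
        rate=float(np.mean(slopes)),
        sd=sd,
        n_replicates=len(slopes),
    )


def classify_specificity_from_rates(
    panel: list[tuple[str, InitialRate]],
    *,
    detection_floor: float | None = None,
    absolute_threshold: float = 0.4,
    relative_threshold: float = 0.5,
) -> SpecificityCall:
    """Primary-specificity call from a chromogenic substrate panel.

    ``panel`` pairs each substrate's P-side sequence (P4..P1 or P3..P1; the
    last residue is P1) with its measured initial rate.  Substrates are
    grouped by the class of their P1 residue; each class's activity is its
    best blank-subtracted rate, normalized by the panel maximum, and the
    same thresholds as the PWM-based call are applied.  If no class rises
    above the detection floor (default three times the pooled replicate
    standard deviation) the call is undetermined.
    """
    if not panel:
        raise ValueError("empty substrate panel")
    class_rate: dict[str, float] = {label: 0.0 for label in SPECIFICITY_CLASSES}
    covered: set[str] = set()
    for seq, rate in panel:
        p1 = seq[-1]
        label = next(
            (lb for lb, res in SPECIFICITY_CLASSES.items() if p1 in res), None
        )
        if label is None:
            raise ValueError(
                f"substrate {seq!r} has P1 residue {p1!r} outside the known "
                "specificity classes (basic/aromatic/acidic/aliphatic)"
            )
        covered.add(label)
        class_rate[label] = max(class_rate[label], max(rate.rate, 0.0))
    if len(covered) < 2:
        raise ValueError("panel must cover at least two P1 classes")
    if detection_floor is None:
        pooled_sd = float(np.sqrt(np.mean([r.sd**2 for _, r in panel])))
        detection_floor = 3.0 * pooled_sd
    peak = max(class_rate.values())
    if peak <= detection_floor or peak <= 0:
        return SpecificityCall(
            "undetermined", {c: 0.0 for c in class_rate}, "rate-panel"
        )
    evidence = {c: v / peak for c, v in class_rate.items()}
    return classify_from_class_evidence(
        evidence,
        "rate-panel",
        absolute_threshold=absolute_threshold,
        relative_threshold=relative_threshold,
    )


def fit_first_order(
    tc: CleavageTimeCourse, k_max: float = 10.0, eps: float = 1e-3
) -> CleavageRate:
    """Least-squares fit of f(t) = 1 - exp(-k t) over k in [0, k_max].

    Fractions exactly equal to 1 are shrunk to 1 - eps before fitting
    (a fully converted band carries no rate information beyond a lower
    bound).  An all-zero course returns k = 0 rather than an error.
    """
    t = tc.times
    f = np.minimum(tc.fraction_cleaved, 1.0 - eps)
    if np.count_nonzero(t > 0) < 2:
        raise ValueError("need at least two nonzero time points")
    if np.all(tc.fraction_cleaved == 0):
        return CleavageRate(tc.substrate_name, 0.0, 0.0)

    def sse(k: float) -> float:
        return float(np.sum((f - (1.0 - np.exp(-k * t))) ** 2))

    # the loss is flat to machine precision once exp(-k t) underflows, which
    # strands interval methods on the plateau; seed with a log-spaced grid
    # and refine locally around the best bracket
    grid = np.concatenate([[0.0], np.geomspace(1e-6, k_max, 200)])
    best = int(np.argmin([sse(k) for k in grid]))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        k = float(lo)
    else:
        res = minimize_scalar(
            sse, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12}
        )
        k = float(res.x)
        if sse(float(grid[best])) < sse(k):
            k = float(grid[best])
    return CleavageRate(tc.substrate_name, k, sse(k))


def fold_difference_by_rate(a: CleavageRate, b: CleavageRate) -> FoldDifference:
    """Ratio of first-order rates, a over b."""
    if b.k <= 0:
        raise ZeroDivisionError(
            f"rate of {b.substrate_name!r} is zero; fold differences against "
            "an uncleaved substrate need the titration method"
        )
    return FoldDifference(
        numerator_id=a.substrate_name,
        denominator_id=b.substrate_name,
        fold=a.k / b.k,
        method="rate-ratio",
    )


def titration_equivalence(
    curve_a: tuple[np.ndarray, np.ndarray],
    curve_b: tuple[np.ndarray, np.ndarray],
    target_fraction: float = 0.5,
) -> FoldDifference:
    """How much more of enzyme B than enzyme A reaches the same cleavage.

    Each curve is (enzyme amounts, fraction cleaved), monotone
    non-decreasing in amount; the amount reaching ``target_fraction`` is
    found by piecewise-linear interpolation on log-amount, and the fold is
    amount_b / amount_a (>1 when A is the stronger activity).  Small noise
    is tolerated by taking the running maximum of each curve before
    interpolating.
    """

    def invert(amounts, fractions, name):
        amounts = np.asarray(amounts, dtype=float)
        fractions = np.maximum.accumulate(np.asarray(fractions, dtype=float))
        if np.any(amounts <= 0) or np.any(np.diff(amounts) <= 0):
            raise ValueError("enzyme amounts must be positive and increasing")
        if not (fractions[0] <= target_fraction <= fractions[-1]):
            raise ValueError(
                f"target fraction {target_fraction} is not bracketed by curve "
                f"{name} (achievable range {fractions[0]:.3g}-{fractions[-1]:.3g})"
            )
        return float(np.exp(np.interp(target_fraction, fractions, np.log(amounts))))

    amount_a = invert(*curve_a, "a")
    amount_b = invert(*curve_b, "b")
    return FoldDifference(
        numerator_id="a", denominator_id="b", fold=amount_b / amount_a, method="titration"
    )
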