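# Methods

This note documents the statistical models, algorithms, numerical choices
and known limitations behind `cleavspec`. Notation: substrate positions
P4…P1 | P1′…P3′ (Schechter–Berger), cleavage between P1 and P1′; the 20
proteinogenic residues in the fixed order `ACDEFGHIKLMNPQRSTVWY`.

## Register alignment (`cleavspec.align`)

**Model.** Each sequenced phage clone carries a random nonamer insert in
the fixed capsid context `PGG(X)9HHHHHH`. Conditional on its latent
register r (the insert position of P1, restricted to the nine insert
positions — cleavage in the fixed flanks is identical across clones and
cannot be selected for), the residues of the P-position window are drawn
from the frequency matrix f, the remaining insert residues from the
background b (default uniform 1/20, overridable). Window positions that
fall in a flank are fixed constants shared by every clone: they appear in
the *extracted* window (and hence in reported count matrices — the reason
His is excluded from the "basic" residue class), but they are masked out
of the register likelihood. Without this masking the constant His tag is a
degenerate global optimum: three perfectly conserved columns beat any real
motif.

**Estimation.** Columns are smoothed with a scalar pseudocount a (default
0.5 per residue per column, a Jeffreys-style choice), giving MAP column
frequencies (c + a)/(m + 20a) with column-specific totals m (flank-masked
positions contribute nothing). The objective is the completed-data
penalized log-likelihood

    J(z) = Σ_cols Σ_aa (c + a) log f̂  −  Σ_clones Σ_masked-window log b,

maximized over hard assignments z. Search: soft EM (register posteriors ∝
masked window log-odds; MAP M-step; the penalized marginal objective is
non-decreasing per iteration and is exposed as `objective_path_`) from
nine deterministic single-offset starts plus `n_starts` seeded random
starts; each run is hardened by classification EM and exact
single-peptide coordinate ascent; coherent-shift restarts and (for n ≤ 8)
exhaustive two-peptide moves guard against gauge-copy and noise local
optima. `brute_force_alignment` enumerates all 9^n assignments and is the
certification oracle for n ≤ 8; the estimator attains its optimum to
1e-9 on random small instances in the test suite.

**Register gauge.** When the informative motif is narrower than the
window, shifting every assignment coherently is a near-symmetry of J
(residual differences are fractions of a nat per clone, and the masked
objective even mildly *rewards* edge-shifted gauges because masked
residues escape the per-residue overfit cost — the same holds for the
collapsed Dirichlet-multinomial marginal, which we verified numerically
before settling on the MAP form). The absolute P1 placement is therefore
not identifiable from inserts alone; experimentally it is fixed by
substrate assays, not by phage display. `_canonicalize_shift` treats
gauges within 0.25 nats/clone of the best (each candidate re-polished, so
a few stray assignments cannot misprice a coherent gauge) as copies of
one motif and picks among them: by maximal P1-column mass on the
`p1_anchor` residue class when one is supplied (e.g. `DE` after a
chromogenic panel calls an asp-ase), else by centring the mean cleavage
position in the insert — the symmetric default matching a library with no
positional preference. The reported `objective` is the best optimum found
*before* gauge fixing, so it is directly comparable to the oracle; the
gauge convention costs at most the tolerance. Per-clone register
uncertainty is reported as the entropy of the register posterior
(`posterior_entropy_`); enzymes whose motif genuinely underdetermines the
scissile bond show high entropy rather than a false certainty.

**Degeneracies worth knowing.** Self-overlapping motifs (a poly-Arg run)
leave individual clones with exactly tied registers whenever a chance
extra Arg extends the run (~10% of clones at uniform background), capping
exact register recovery near 95% regardless of model sharpness. Ties in
per-clone assignments break toward the most N-terminal register.

## Specificity models (`cleavspec.model`)

PFM: f = (counts + a)/(n + 20a) from hard-assigned windows. PWM: log2
f/b; information content: per-column KL divergence from b in bits.
Consensus derivation per position: a single residue with frequency ≥ 0.6
(majority_threshold) wins; else a chemical class — basic {K,R}, acidic
{D,E}, aromatic {F,Y,W}, aliphatic {A,V,I,L}, small {G,S,T} — with summed
frequency ≥ 0.7 (class_threshold); else unconstrained. A class whose mass
stays ≤ 0.02 at *every* window position is recorded as forbidden within
±3 residues of P1, capturing selections that strikingly exclude e.g.
acidic residues near the scissile bond. P1 is always a hard-required
position. Patterns serialize to a compact grammar
(`P4:[FWY] P3:D P2:. P1:D! … ; forbid[DE]±3 ; mm<=1`) that parses back
losslessly.

Primary-specificity calls map P1-column mass onto the four P1 classes
(tryptase basic, chymase aromatic, asp-ase acidic, elastase aliphatic).
A class qualifies at ≥ 0.5 of the best class; no class reaching 0.4 means
undetermined; tryptase and chymase qualifying together is called dual —
thresholds chosen so the four planted archetypes and their dual/absent
variants reproduce the verbal bench calls, and both are configurable.

## Assay kinetics (`cleavspec.kinetics`)

Initial rates: per-replicate ordinary-least-squares slope of
blank-subtracted A405 over a fit window (default 0–60 min, the early
points where pNA release is linear; configurable); the rate is the
replicate mean, its sd the replicate scatter; negative slopes are not
clamped. The rate-panel classifier groups substrates by the class of
their P1 residue (the last residue before the pNA leaving group), takes
each class's best rate normalized by the panel maximum, and applies the
same thresholds as the PWM call; everything below a detection floor
(default 3× the pooled replicate sd) is undetermined.

Gel time courses are summarized by a single-exponential first-order fit
f(t) = 1 − exp(−kt), k ∈ [0, 10 min⁻¹]: substrate excess over enzyme is
uncharacterized in this design, and the reported quantities are only
ratio-level fold differences, which this model supports. The SSE is flat
to machine precision once exp(−kt) underflows, so the 1-D fit seeds from
a 200-point log-spaced grid and refines the bracketing interval
(xatol 1e-12); fractions equal to 1 are shrunk to 1 − 1e-3; an all-zero
course returns k = 0. Fold differences are rate ratios when both rates
are positive, else titration equivalence: the enzyme amount reaching a
target cleavage fraction by piecewise-linear interpolation on log-amount
(running-maximum smoothing tolerates small noise), fold =
amount_b/amount_a. No Michaelis–Menten constants are estimated — no
substrate-concentration series exist in this design.

## Proteome scanning (`cleavspec.scan`)

Every admissible P1 placement is evaluated; both the model window and the
reported span (default the octamer P6…P2′, the convention in which
near-consensus sites are quoted) must lie inside the protein — proteins
have no known flanks, so truncated windows are skipped, not padded, and
skip counts (including windows containing X) are logged. Coordinates are
1-based inclusive. PWM mode thresholds the summed log2-odds; pattern mode
enforces required positions, a mismatch budget over non-required
positions, and forbidden classes within their radius of P1. Hits sort by
(protein_id, start); `brute_force_scan` re-scores every window naively
and the two agree exactly on randomized suites. No significance model is
attached (no E-values, deliberately no multiple-testing correction): the
scan reports qualitative near-consensus matches and per-protein counts.

## Synthetic data (`cleavspec.simulate`)

**Planted models.** Four archetypes with `sharpness` s = the column mass
on the preferred set (default 0.9, the value used throughout the test
suites), remainder uniform: poly-Arg tryptase (R at P2, P1, P1′); asp-ase
(D at P1 and P3, aromatic P4, Glu-leaning P6 when the window includes
P6); F/Y-K tryptase (F/Y at P2, K at P1, R/K at P3′, with Asp/Glu pinned
to 1e-3 everywhere — the "no acidic neighbours" signature); F/Y chymase
(F/Y at P1, L at P2′). Each model's consensus pattern is derived from its
matrix at the default thresholds, so matrix and pattern are mutually
consistent by construction.

**Biopanning.** A library of 1e5 clones (a desk-scale stand-in for the
~5×10^7-clone experimental library; configurable) is drawn uniformly.
Per round, each clone releases with probability
p = p_bg + (p_max − p_bg)·logistic(slope·(score − midpoint)), where score
is its best-register PWM log2-odds under the planted model; the default
midpoint is the 99.9th percentile of the unselected library's scores, so
only the rare strongly cleavable clones start hot. The buffer control
releases every clone at p_bg (the spontaneous-release symmetry of a
PBS-only control). Released counts are binomial; the released pool is
re-amplified by unbiased multinomial resampling to the library size
(phage fitness effects are not modeled); after the last round the
sequenced sample (default 96 clones) is drawn multinomially from the
released pool. Defaults: 5 rounds, p_max 0.5, p_bg 0.001, slope 1.0.
Round summaries report release counts, the enrichment fold
(enzyme/control; NaN-flagged if the control released nothing), and the
top-clone fraction; extinction ends the simulation early with a flagged
round. The logistic link is the minimal monotone saturating assumption
consistent with cleavage-dependent release; the simulator reproduces the
order of magnitude of reported enrichment folds but cannot attribute
between-enzyme differences, which conflate activity, stringency and
titering.

**Other generators.** `sample_cleaved_clones` draws idealized
post-selection clones (window residues from the planted matrix at
registers keeping the window inside the insert, rest uniform) — the right
generator for parameter-recovery studies, since biopanning-selected
windows are *not* distributed like the planted matrix (selection
over-weights high-scoring windows). `simulate_proteome` plants consensus
or matrix-sampled windows at recorded coordinates in i.i.d.-composition
proteins, detects accidental background matches with the exhaustive
scanner, and flags them in the registry. `simulate_assays` gives each
panel substrate a planted initial rate of rate_max·2^(score deficit)
relative to the best substrate its scored positions allow (rate_max
0.002 AU/min), plus Gaussian read noise (sd 1e-4) in triplicate over the
bench time grid (0–360 min) with a no-enzyme blank; gel time courses use
a first-order rate scaled the same way (k_max 0.05 min⁻¹, fraction noise
sd 0.02, time points 0/15/45/150 min). `simulate_titration` produces
saturating titration-curve pairs with a planted equal-cleavage fold. All
generators are bit-reproducible for a fixed seed.

**What the generators do not emulate.** Real selections carry sequencing
errors, phage amplification bias, clone-dropout between rounds, and
non-independent residue preferences (the analysis is strictly
position-independent, as is the model it estimates); real proteomes are
not i.i.d.-composition. Passing recovery tests therefore demonstrates the
estimators' correctness under the stated model, not robustness to these
real-data features.

## Problem sizes in the test and acceptance suites

The suites run at desk scale by design: exhaustive alignment oracles at
n ≤ 6 peptides (9^6 assignments), scan-oracle equality on 50 proteins of
length 500, parameter recovery from 96 sequenced clones per planted model
(the bench sample size), biopanning at the 1e5-clone default over 5
rounds with ten replicate pannings for the selection statistic, and
100–200 replicate fits for the kinetics recovery bands.

## Known limitations

- Absolute register identification from phage inserts is impossible for
  motifs narrower than the window without an assay anchor (see above); the
  centring fallback is a convention, not an inference.
- Hard-count matrices from register-optimized alignments overfit on
  no-signal data: best-of-nine register selection alone concentrates
  columns to ≈ 0.7 bits/position at n = 96 (a fixed common register gives
  ≈ 0.14). Interpret information content relative to that null, not zero.
- The consensus grammar serializes residue *classes* only for the five
  named chemical classes; arbitrary residue sets at a position are stored
  as explicit sets and never coerced.
- Pattern-mode scanning reports mismatch counts that include failed
  required positions, but a failed required position always disqualifies
  the window regardless of the mismatch budget.
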