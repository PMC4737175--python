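# Methods

This note documents the models behind `nickplex`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Substrate panel model

A nick substrate is a three-strand assembly: an upstream probe donating
the junction 3′-OH, a 5′-phosphorylated downstream probe carrying a 3′
FAM label, and a splint complementary to both. The junction base of each
probe is encoded in its length: upstream A/C/G/T → 20/28/36/44 nt,
downstream pA/pC/pG/pT → 30/32/34/36 nt. The product of ligating U with
pD therefore has the unique length `len(U) + len(pD)`; across the 4×4
probe set the 16 sums run 50–80 nt, pairwise distinct with a minimum gap
of 2 nt. `design_length_code(n_up, n_down, sep, up0, down0)` generalizes
the scheme: downstream lengths step by `sep` and upstream lengths by
`n_down × sep`, which guarantees distinct sums with gaps ≥ `sep` for any
panel size (labels beyond the 4-base alphabet get synthetic names).

Each of the 16 pools holds one splint plus all eight probes, giving 16
substrates per pool — exactly 1 WC, 3 upstream-mismatch (UM), 3
downstream-mismatch (DM) and 9 double-mismatch combinations — and 256
distinct junction combinations across the panel. Pools are labeled by
the splint junction dinucleotide read 3′→5′ with the upstream-pairing
base first (pool 3′-GT-5′: WC product C/pA).

**Sequences.** Core sequences are drawn pseudo-randomly from
`context_seed` rather than fixed, since the structural properties — not
particular sequences — define the assay. Constraints honored: the
upstream probe ends 3′ in its junction base, so its length increments
are TC repeats prepended as 5′ tails outside the 20-nt splint-annealing
region; the downstream probe grows by TC repeats at its 3′ (FAM) end and
always terminates in TC, minimizing sequence effects on FAM fluorescence
yield; splints are 50 nt (20 upstream- + 30 downstream-complementary)
and identical across pools except at the two junction positions.

**Melting temperatures.** `tm_estimate` uses the unified
nearest-neighbor parameters (SantaLucia 1998, biopython's `DNA_NN3`)
with the Owczarzy 2008 magnesium-aware salt correction, at 250 nM per
strand. The default buffer is 25 mM monovalent cation + 10 mM Mg²⁺.
Candidate cores are redrawn (deterministically, from the seed) until all
four junction-base variants of the 20-nt upstream region melt within
±2.5 °C of 53 °C and the 30-nt downstream region within ±2.5 °C of
71 °C. Tm-matching the probe set is part of the assay design: reactions
are run near the upstream region's Tm so mismatched upstream termini can
exchange, while the downstream duplex stays annealed.

## Synthetic-data generator

`make_yield_profile` produces ground-truth reaction outcomes per pool.
Conservation is tracked per downstream probe (the only labeled strand):
products + adenylylated + unreacted = 1. Scenarios:

- `perfect_fidelity` — only the WC substrate ligates, to `intensity`.
- `tth_like` — a high-fidelity thermostable-ligase-like pattern:
  upstream tolerance restricted to the G:T (0.10) and T:G (0.25) wobble
  pairs; downstream tolerance concentrated on pT:T (0.50), pT:G (0.45),
  pA:C (0.40), pC:A (0.40) with a lesser tier pG:T/pA:A/pG:A/pC:C/pC:T
  (0.08–0.02); double mismatches do not ligate. Relative efficiencies
  multiply `intensity`; per-probe totals are capped by competition.
- `t4_like` — promiscuous: all single mismatches ligate (0.9 downstream,
  0.7 upstream; purine:purine pairs reduced), doubles still excluded.
- `uniform` / `custom` — equal shares, or a caller-supplied validated
  table.

These tables are qualitative emulations for exercising the analyzer;
they are not measured biochemistry. Default `intensity` 0.6 emulates a
30-min reaction where the WC product reaches ~60 % of its ceiling;
adenylylated fraction defaults to 0.05 per reacting downstream probe.

**Mobility.** Short FAM-labeled fragments run fast relative to the
(differently dyed) ladder. Apparent size = true length − shrinkage, with
shrinkage `A·exp(−L/λ) + c` (defaults A = 8 nt, λ = 25 nt, c = 1 nt):
non-negative, decreasing in length, and small enough that apparent size
is strictly increasing. AppN intermediates are placed at
`apparent_size(L + 4)`: a +4-nt effective adenylyl increment makes the
two documented coelutions exact (AppA with pG at 30+4 = 34 nt, AppC with
pT at 32+4 = 36 nt) while leaving AppG (38) and AppT (40) resolvable
from the probe peaks.

**Traces.** Each species contributes a Gaussian peak (constant width in
apparent nt, default SD 0.35 nt) at the scan position of its apparent
size under a mildly nonlinear scan axis; peak area is proportional to
amount (equal fluorescence per mole of FAM — terminal-TC probes minimize
context effects, residual variation is treated as noise). The ladder
(default 15–120 nt, 9 fragments) populates the standard channel with no
mobility offset. White Gaussian baseline noise (default SD 30) is added
from the seed; default amplitude puts a fully reacted product peak near
height 5000. Per-pool seeds derive from the master seed via
`SeedSequence`, so panels are bit-reproducible. Not modeled: injection
variability, dye spectral pull-up, peak tailing, annealing variability.
Passing round-trip tests therefore demonstrates correctness of the
analysis rules, not robustness to every instrument artifact.

## Trace analysis

**Calibration** fits a monotone piecewise-linear scan→size map through
the detected ladder apexes (exact on anchors, linearly extrapolated
beyond them); a ladder-count mismatch or non-monotone apexes raise a
calibration error. Piecewise-linear was chosen over Local Southern as
the simplest map that is exact on anchors and provably monotone.

**Peak calling** subtracts a rolling-minimum-then-smooth baseline
(window 300 samples, ≫ peak width), lightly smooths (Gaussian σ = 2
samples), and calls local maxima with height and prominence above the
150-unit floor. Peak boundaries are the flanking local minima or the
1 %-of-apex-height crossing, whichever is nearer; areas are trapezoidal
integrals of the baseline-corrected signal, apexes refined by parabolic
interpolation. The 1 % boundary truncates ≤ 0.2 % of a Gaussian peak's
area, within the stated ±0.5 % integration tolerance.

**Assignment** matches called peaks to expected species greedily by
absolute apparent-size deviation within a ±0.75-nt tolerance (half the
minimum 2-nt product spacing, after mobility compression); ties break
toward products over intermediates. Species whose expected positions
fall within twice the tolerance are declared a coelution group — under
the default code exactly {AppA, pG} and {AppC, pT} — and a peak there is
assigned to the group, not a member.

**Quantitation** divides each species' area by the total area of all
called reporter peaks (assigned or not; the standard channel never
enters the denominator). Product normalized yield = fraction / 0.25,
the ceiling for one product in an equimolar four-probe pool; values may
slightly exceed 1 and are reported unclipped. Coeluted area is reported
as the group total and excluded from product yields (no FAM product can
fall in an AppN group under the default code). Uncalled species get
fraction 0 with a `below_floor` flag. All yields carry an assumed ±10 %
relative error. Replicate runs of a pool are averaged with per-species
sample SD.

## Fidelity grids

Rows are splint junction dinucleotides ordered so each row's WC product
sits on the main diagonal when columns run in elution order A/pA…T/pT
(first row 3′-TT-5′, last 3′-AA-5′). Color bins partition normalized
yield into half-open intervals (0.80, ∞) green, (0.50, 0.80] yellow,
(0.10, 0.50] red, (0.02, 0.10] gray, [0, 0.02] open-if-called; "none"
(no called peak) is kept distinct from "open" (called but < 2 %), since
a rendering that conflates them loses the detection floor — both
renderings are recoverable from the stored called mask. Summaries
aggregate called cells by WC/UM/DM/DOUBLE class and list every non-WC
cell binned gray or better in probe:splint pair notation.

## Kinetics

`fit_initial_velocity` takes the leading run of time points at or below
`max_fraction` (default 0.20) conversion — the first disqualifying point
ends the run — and fits an ordinary least-squares line with an implicit
(0, 0) anchor, since the reaction starts with zero product; the anchor
choice is a documented package decision, and on noiseless linear data it
leaves the slope exact. V₀ = slope × substrate concentration (nM/s). At
least 3 qualifying points are required; fewer raises an error advising
denser early sampling. Replicates are summarized as mean ± sample SD
(SD undefined for a single replicate).

## Problem sizes and determinism

Default traces are 5600 samples, enough to span the 15–120-nt ladder at
~40 samples per apparent nucleotide; a full 16-pool simulate→analyze
round trip takes under a second. Every stochastic step (core-sequence
draws, trace noise, time-course noise) is driven by an explicit seed,
and child seeds derive deterministically, so all outputs are exactly
reproducible from their recorded configuration.

## Known limitations

- Scenario tables are qualitative; the package measures what an analyzer
  recovers from them, not real enzyme fidelity.
- Coeluted AppA/pG and AppC/pT area is not apportioned between members;
  assays needing unreacted-pG/pT quantitation should alter the length
  code so the coelutions vanish.
- No vendor binary (.fsa) parsing; traces enter as CSV or pre-called
  peak tables.
- Absolute molar quantitation is out of scope; all yields are fractions
  of total reporter fluorescence.
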