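# Methods

This note documents the models, conventions and numerical choices behind
`acidtol`, and what the synthetic-data generators do and do not emulate.

## Polyproline motif scanning

The scanner reports **maximal** runs of the residue P with length ≥
`min_len` (default 3).  Maximality is the only semantics under which the
standard dependence classes are coherent: "two separate PPP motifs" and
"one PPPP run" are distinct only if a longer stretch is not decomposed into
overlapping 3-mers.  Matching is case-insensitive; `X`, `*` and every
non-proline letter break runs — ambiguity codes are never allowed to extend
a run.  Coordinates are 0-based half-open internally and 1-based inclusive
in output tables (the biologist convention).

A protein's canonical **pattern label** counts runs per distinct length,
lengths ascending, joined by `+` (e.g. `2×3P+1×4P`), which makes census
tabulation deterministic.  The **high-dependence** rule — at least
`min_multi_runs` (2) separate runs, or one run of at least `min_long_run`
(4) — captures proteins expected to need the most eIF5A activity.  Exact
census bin edges for very long runs are report configuration, not scanner
logic: the census exposes raw labels.

## Gene-set funnel

Screens and databases mix standard and systematic yeast gene names, so all
set arithmetic happens after canonicalization through an alias map
(systematic/ORF names as the canonical namespace).  Unknown identifiers
are kept verbatim and logged rather than dropped: silently losing genes
corrupts funnel counts.  The deduplicating union across screens reports
per-source sizes and every pairwise overlap so the inclusion–exclusion
identity can be audited.  Functional categorization is a flat slim mapping:
a gene with k categories counts once in each of the k rows (member lists
are emitted so single-count views can be derived), and unannotated genes
fall under "unknown function".  No enrichment statistics are computed —
categorization only.

## Direct-target calling

A documented target becomes *direct* when the factor's binding consensus
matches its promoter at least once.  The URS1 consensus bound by Ume6p is
not uniquely standardized; the default here is the canonical core
`TCGGCGGCT`, explicitly a configurable choice (any IUPAC-degenerate
pattern is accepted).  Both strands are scanned by default since URS1
function is orientation-independent; promoter `N` matches nothing (an
unsequenced base is never evidence of a site); overlapping matches are all
reported.  The promoter window defaults to 1000 bp upstream, configurable.
Minus-strand matches are mapped back to promoter coordinates (1-based
position of the leftmost base).

## Expression arithmetic

Relative transcription uses the double-delta Cq model with amplification
efficiency E ∈ (1, 2], default 2.0 (perfect doubling; no standard curves
are modelled).  Replicate Cq values are averaged per (sample, gene)
*before* the ΔΔ arithmetic — one level per condition — and the calibrator
level is exactly 1 by construction.  Cq calling itself (e.g.
second-derivative-maximum) is instrument-side and out of scope: Cq values
are inputs.  Protein abundance is RFU = FI / OD600 with optional
untagged-strain background subtraction (off by default), normalized to a
calibrator.  Translation efficiency is the protein/mRNA ratio for the same
sample, gene and calibrator; re-expressing everything against a different
calibrator multiplies all levels by one constant and leaves every ratio
and percent difference unchanged (tested as an invariant).

Percent differences are reported to the nearest integer in tables.  The
bundled UME6 reference inputs use a baseline TE ratio of 1.67: the
stressed-strain comparison then computes TE 2.4/1.6 = 1.5 vs 1.67 × 4.1/2.7
≈ 2.54, a ~69% advantage.  Note the printed inputs are internally tense:
a "1.6-fold" protein increase at unchanged mRNA would give a 60% TE gain,
while the reported TE gain is 67%; this package treats the 67% figure
(ratio 1.67) as the authoritative baseline.

The two-group test is the two-sided unequal-variance (Welch) t-test —
a deliberate conservative default where the original test is unspecified —
with stars at P < 0.05 / P < 0.01.  Identical zero-variance groups return
P = 1.

## Growth variables

On ln(OD), least-squares lines are fit over every contiguous window of
`window_size` points (default 4); the **rate** is the maximum slope, with
ties resolved to the earliest window for determinism.  The **lag** is
where that tangent crosses ln(od_initial), the classic graphical lag;
od_initial is the mean of the first max(2, window_size // 2) readings
(robust to single-read noise), overridable via `n_initial` — note that for
a curve already growing at t = 0 this mean sits above the first reading,
so the default lag of a pure exponential is a fraction of one sampling
interval rather than exactly 0 (use `n_initial=1` for the textbook
tangent-through-origin behaviour).  **Efficiency** is max(OD) − od_initial
on the linear scale.  Negative lags are clipped to 0 and flagged; flat or
declining curves report rate 0 with lag undefined (NaN).  Whether the
exponential-phase slope should be taken on log or linear OD is genuinely
ambiguous in common usage; log scale is the standard reading of a specific
growth rate and is the default, with `log_scale=False` available.  No
smoothing is applied by default; a 3-point running median is available for
noisy plates.

The 4-point window is calibrated to roughly-hourly sampling (≈ 3 h of
exponential phase per window).  At much denser sampling the max over many
short noisy windows biases the rate upward; widen the window accordingly.

Survival is 100 × CFU(t)/CFU(0), exactly 100 at t = 0 and invariant to
dilution factors; the death rate is the negated slope of a log-linear CFU
fit over positive counts.

## Synthetic data: what it emulates, and what it does not

Each generator produces one input class with planted, exactly recorded
truth (`TruthBundle`, serialized as JSON beside the outputs), under an
explicit integer seed; identical seeds reproduce identical bytes.

- **Proteome** — random sequences whose background alphabet excludes
  proline, so the planted census is exact; a realistic mode admits
  background prolines and then the truth is recomputed from the finished
  sequences.  Lengths are uniform on 200–600 aa (150–450 in the
  coordinated bundle).  No attempt is made to mimic real amino-acid
  composition beyond what the scanner needs.
- **Screens** — three gene lists built from the seven Venn regions of a
  planted overlap specification.  The default plants sizes 216/650/409
  with union 1031 (regions 72/490/275/60/34/50/50 — one consistent
  solution; the real region sizes of the original screens are unknown).
- **Regulon** — direct targets carry one planted consensus realization
  (random strand when both strands are scanned); non-direct promoters are
  rejection-sampled to contain zero matches on either strand.  For the
  9-bp default pattern in a 1000-bp promoter a spontaneous match occurs in
  < 1% of draws, so rejection is cheap.
- **Growth** — three-phase curves: OD constant at od0 during the lag, then
  the logistic solution with the planted intrinsic rate toward capacity;
  multiplicative Gaussian noise mimics an OD reader.  Defaults: od0 0.05
  (a typical inoculum), capacity 4.0 (shake-flask stationary density in
  synthetic medium), hourly sampling over 48 h.  Because the logistic
  slope on ln OD is r(1 − OD/capacity), the best-window estimate carries a
  small (< 3%) downward bias relative to the planted intrinsic rate; the
  recovery tolerances account for this.
- **Expression / fluorescence** — Cq = base − log_E(fold) + noise around a
  reference baseline; FI = abundance × OD × gain × (1 + noise).  Planted
  qPCR noise of 0.1 cycles with 3 replicates propagates to ~6% median
  fold error; recovery is therefore asserted on the median across planted
  folds and replicate datasets, not on single draws (a single ΔΔCq value
  at that noise exceeds 10% error roughly one time in four by propagation
  alone).
- **Coordinated funnel bundle** — ties all of the above to one gene
  universe (default 6000 genes) so that the planted stage sizes
  (558 → 1031 → 85 → 17 and 1481/170/176/24) propagate consistently; a
  fraction of screen entries are written under alias names to exercise
  canonicalization.

What passing round-trip tests shows is that the *pipeline arithmetic* is
exact and the estimators recover planted parameters under the stated noise;
it does not validate biological conclusions on real proteomes, screens or
regulation databases, whose composition (proline frequency structure,
correlated screen noise, promoter base composition, shared regulatory
sites) the generators deliberately do not model.

## Problem sizes

Default test and acceptance workloads: 1000 random proteins × min-run
lengths 1–6 and 200 random promoters for the oracle comparisons; 500 noisy
growth curves and 50 simulated qPCR datasets (× 3 planted folds) for
recovery; one full-scale funnel bundle (6000 proteins, 1481 promoters).
These sizes give stable medians and exact set counts while keeping a full
run in the seconds range.
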