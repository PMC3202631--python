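# Methods

## Scope and model overview

`xtalselect` predicts, from sequence alone, the propensity of a protein
target to progress through a crystallography pipeline to
diffraction-quality crystals, and supports the selection steps built
around such predictors: admitting putative structural homologues into a
candidate pool, profiling a sequence for construct design, and ranking
candidates. Two predictors are implemented. Both are composition-level
models: they see the amino-acid makeup of a sequence, never its order.

### Feature layer

All predictions are functions of a fixed 8-dimensional feature vector
(plus length): isoelectric point (pI), GRAVY, and the frequencies of
S, C, G, F, Y, M.

* **GRAVY** is the mean Kyte–Doolittle hydropathy over scoreable
  residues, computed from residue counts so that a homopolymer returns
  its scale value exactly.
* **pI** is the root of the net-charge function under a fixed
  Henderson–Hasselbalch model with the EMBOSS pKa set (N-term 8.6,
  C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1),
  found by bisection on [0, 14] to 1e-3 pH units (≤100 iterations; the
  charge function is strictly decreasing so bisection always converges,
  and the termini alone guarantee a sign change on the interval). pKa
  tables differ between common tools; the set name is recorded in every
  model file, and models are only comparable within one set. The unit
  tests validate pI against a brute-force pH-grid scan of the same
  charge model, not against another tool's pI (which would conflate pKa
  table differences with implementation error).
* **Ambiguity codes** X/B/Z/U are accepted and masked: they count toward
  sequence length but are excluded from GRAVY, from the charge model and
  from frequency numerators and denominators. This avoids inventing
  hydropathy or charge values for unknown residues; a sequence that is
  entirely masked cannot be scored and raises an error.

### OB-Score

A 2-D histogram model over (pI, GRAVY). Defaults: pI bins of 0.5 pH over
[0, 14] (28 bins), GRAVY bins of 0.25 over [−4.5, 4.5] (36 bins), K =
1008 bins total. Both feature axes are bounded by construction, so
out-of-range values (numeric edge cases only) clamp into the edge bins
rather than being rejected. The per-bin Z-score uses the binomial
expectation under the smoothed background fraction
`b = (bg + c)/(N_bg + c·K)` with Laplace pseudocount c = 1 applied to the
background only (preventing division by zero in background-empty bins):
`Z = (pos − N_pos·b)/sqrt(N_pos·b·(1 − b))`. With pseudocount 0, a bin
empty in both sets has no evidence and its Z is defined as 0.

A consequence of spreading the pseudocount mass over all K bins is a
downward bias of `b` in densely occupied bins, so under the null
(positives and background from the same distribution) dense-bin Z values
are systematically positive; at n = 2000 per side on the default grid the
maximum |Z| over occupied bins reaches ≈ 8–11 across seeds. The test
suite checks against that measured envelope. Decision thresholds for the
OB-Score should therefore be calibrated on scores, not read off the
nominal N(0,1) scale.

### ParCrys

A positive-only Parzen-window estimator: the training set is crystallised
reference proteins only, which sidesteps defining a "non-crystallisable"
negative set. Each feature dimension is standardized by the reference
mean and standard deviation (population sd, ddof = 0); a zero-variance
dimension would make standardization undefined, so its sd is replaced by
1 with a warning (the dimension becomes uninformative rather than fatal).
The kernel is a Gaussian product kernel with the multivariate
Scott/Silverman bandwidth `h_d = (4/((d+2)·n))^(1/(d+4))` per (unit
variance) dimension, d = 8. Scores are natural-log densities accumulated
with log-sum-exp: raw 8-D densities underflow double precision for
distant queries, while the log score remains finite (and is additionally
floored at the smallest representable positive log).

Threshold semantics: `score >= threshold` predicts crystallisable.
Calibration maximises MCC over candidate cuts at midpoints between
adjacent distinct scores (plus ±∞), ties resolving to the lowest
qualifying cut — the same best-achievable-MCC statistic used to report
predictor performance, so the calibrated operating point and the reported
ceiling coincide.

### Evaluation statistics

* **AROC** ties are credited ½ (Mann–Whitney convention), which makes
  the threshold-sweep curve area and the rank statistic provably equal;
  the suite checks both routes against a brute-force pairwise count. The
  sweep itself is delegated to scikit-learn's `roc_curve`
  (`drop_intermediate=False`) with trapezoidal integration.
* **MCC** returns 0 when any denominator factor is 0 (degenerate
  confusion tables stay defined).
* **AROC comparison** uses a stratified paired bootstrap: instances are
  resampled with replacement within each class, both predictors are
  re-evaluated on the identical resample, and the two-tailed p-value is
  `2·min(P(diff≤0), P(diff≥0))` with the (count+1)/(n_boot+1)
  small-sample correction, capped at 1. Default 2000 resamples, seeded.
  This is a generic, assumption-light choice; it is slightly
  conservative (identical score vectors give p = 1), and across 200
  seeded null simulations it rejects at the 5% level in well under 10%
  of runs.
* **Percent presentation** rounds half away from zero to integer percent
  (61/295 → 20.68% → 21%).

### Rost-curve homologue admission

An aligned pair is admitted as structurally similar when its percent
identity reaches the length-dependent threshold
`n + 480·L^(−0.32·(1+e^(−L/1000)))`, where the offset `n` (default 5
identity points) is the calibration knob — the curve is known to be
search-algorithm dependent. The closed-form expression is a fit for
short-to-medium alignments: extrapolated, it bottoms out near L = 417
and then rises spuriously (to ≈ n+32 around L = 3200) before decaying
again. The implementation therefore holds the threshold constant for
L > 450, the conventional plateau of ≈ n + 19.5 identity points. The
curve consequently approaches that plateau, not the bare offset `n`, for
long alignments.

### Window profiles and ranking

For construct design, every length-`window` subsequence (default window
60, stride 1) is scored as an independent sequence — features are
recomputed on the fragment — and each residue receives the mean score of
all windows covering it (mean, not min/max, is recorded in the profile
metadata via the model name). Sequences shorter than the window get one
whole-sequence window; with stride > 1 a final window flush with the
C-terminus is added when the stride pattern would leave tail residues
uncovered, so coverage of every residue is an invariant. Windows below
10 residues are rejected: pI and composition features are meaningless on
shorter fragments. Because both scorers are composition-only, the profile
of a reversed sequence is the reversed profile — the suite uses this as
a regression property.

Ranking sorts descending by score with a stable order (input order breaks
ties) and optional secondary keys such as ascending length.

## Synthetic data: what it emulates and what it does not

The generator draws residues i.i.d. from a per-population composition and
lengths from a log-normal (mean 300, sd 150 residues, clipped to
[30, 2000] — a realistic single-chain length range). The background
composition is the Swiss-Prot average-proteome table (a documented
in-code constant). The positive ("crystallisable-like") population
multiplies G and F by 1.4 and S and C by 0.6 and renormalizes: the two
populations then differ in exactly the residues the ParCrys feature set
models, and — through the hydropathies of those residues — mildly in
GRAVY, which is what gives the OB-Score its (weaker, two-feature) signal.
Shift sizes were chosen so that separation is clear but not trivial at
desk-scale n (held-out ParCrys AROC ≈ 0.83 at 500+500).

I.i.d. sampling deliberately omits positional structure, domains,
disorder, transmembrane segments and real covariance between features.
Passing tests therefore demonstrate that the estimators recover
composition-level differences they model — not that real crystallisation
outcomes are predicted at any particular accuracy; the published
benchmark figures for these predictor families require external blind
datasets and are out of scope here.

## Problem sizes and numerical choices

Test-suite and acceptance-script simulations use desk-scale sizes chosen
as the package's own benchmark conditions: 500+500 sequences for
parameter recovery, 2000 per side for the null Z-matrix envelope,
200 bootstrap/shuffle replicates for null calibration, 2000 bootstrap
resamples for a single predictor comparison. Seeds are explicit
everywhere; refitting either model on identical input is bit-exact.
Model JSON files store the full standardized reference matrix (ParCrys)
or counts, edges and Z values (OB-Score) plus the pKa-set name, and
round-trip exactly.

## Known limitations

* Both predictors ignore residue order; motifs, disorder and
  transmembrane topology are invisible to them.
* The OB-Score Z values are not calibrated N(0,1) quantities (see the
  pseudocount bias above); use them as a ranking score.
* ParCrys scores are densities under the positive reference model only —
  they measure resemblance to crystallised proteins, not a calibrated
  probability of success.
* Numeric parity with the historical OB-Score/ParCrys web servers is not
  claimed: their training snapshots, bin granularity, kernel details and
  pKa tables are not fully published, so the constructions here are
  explicit, pinned stand-ins.
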