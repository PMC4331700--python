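# Methods

This note records the model, the defaults and why they were chosen, the
numerical decisions, and what the synthetic benchmark does and does not
establish.

## Windows, labels, and padding

A candidate site is any lysine. Its context is a window of `2n + 1`
residues; `n = 6` (13-mers) is the default because short-window
evaluations of lysine-modification predictors consistently favor this
length, and every contract in the package is stated in 1-based protein
coordinates. Lysines within `n` of a terminus are kept: the missing
cells are padded with `-`, and pad cells are excluded from identity,
composition, chi-square, and emission counting (each statistic tracks
its effective support). The alternative — discarding short windows —
throws away real sites near termini; padding keeps them at the cost of
lower support in the outer columns. Non-canonical residues (B, Z, U, O,
J and anything else) map to `X`, which likewise contributes to no
count-based statistic and scores as zero log-odds.

## Redundancy reduction

Near-identical training windows inflate cross-validated performance, so
fragment sets pass through a greedy single-pass identity clustering:
visit fragments in input order (all windows have equal length, so the
usual length-descending order is vacuous), join the first representative
whose identity strictly exceeds the threshold, otherwise found a new
cluster. Identity is exact-match fraction over mutually non-pad cells.
The default operating point is 0.40. Strict inequality is deliberate:
identity exactly at the threshold does not merge. CD-HIT's word-based
pre-filter heuristics are not reproduced — for fixed-length 13-mers the
exact pass is cheap, deterministic, and reproducible bit-for-bit, which
matters more here than heuristic fidelity. A second pass removes every
negative window exactly equal to a positive window so the classes never
share a fragment.

## Maximal dependence decomposition

Contingency categories: the 20 residues are mapped to five biochemical
groups — nonpolar {G,A,V,L,I,P,M}, aromatic {F,Y,W}, polar-uncharged
{S,T,C,N,Q}, acidic {D,E}, basic {K,R,H}. Isolating the aromatics as
their own group reflects the dominant aromatic-enrichment signal this
decomposition is meant to expose; the grouping is injectable for
sensitivity analysis.

For each pair of flank positions the Pearson chi-square is computed
over the group×group table, after dropping zero-margin rows/columns;
degrees of freedom are `(r−1)(c−1)` for the retained table, and
fragments with a pad or `X` at either position are skipped. The center
column (always K) is excluded — zero variance.

The recursion: stop and emit the current set as one cluster when no
pair exceeds the critical value, or when no split can produce two
children of at least `min_cluster_size`; otherwise split at the
position with the largest dependence sum `S(i)` (ties to the most
N-terminal position), peeling off the largest eligible residue group
there (ties to the lowest group id). Clusters are emitted in discovery
order and the terminal node of the pure-remainder path is flagged
*residual*. Defaults: `min_cluster_size = 80` (a subgroup needs enough
windows to train a stable profile), `chi2_critical = 34.27`, the upper
0.005 point of chi-square at df = 16 (the full 5×5 table).

A calibration caveat recorded here deliberately: 34.27 controls each
*pair* at 0.005, not the family of 66 pairs a 13-mer yields. On
dependence-free data any single chi-square exceeds the cutoff in well
under 1% of simulations, but *some* pair does in roughly a quarter of
runs, so MDD splits null data at about that rate. A familywise-
controlled cutoff (Šidák over 66 pairs ≈ 41.3) would bring the null
split rate under 5%; the per-pair default is kept because the split
decision is descriptive, the downstream models are validated by
cross-validation rather than by the split test, and the cutoff is a
plain argument for anyone who prefers stricter control.

## Profile HMMs over fixed-length windows

Training windows are gapless and equal-length, so each model is `L =
2n + 1` match states with smoothed insert/delete mass rather than a
general alignment-derived architecture. Match emissions are Laplace
estimates `(count + κ) / (support + 20κ)` with pseudocount `κ = 1`
(configurable); Dirichlet-mixture priors in the style of HMMER are
intentionally not reproduced. Transitions are shared across nodes:
M→M = 0.99, M→I = M→D = 0.005, and I/D states split their mass 0.5/0.5
between staying and returning — enough smoothing that every path has
positive probability while the match path dominates. Insert states emit
the background.

Scoring is the full forward algorithm. The null is the *same* state
machine with every emission replaced by the background distribution, so
the shared transition mass cancels and a model whose emissions equal
the background scores exactly 0 bits; equivalently, the null
probability is the product of background frequencies times the
transition mass of all length-`T` paths. The background defaults to the
Laplace-smoothed pooled flank composition of the positive training set
(uniform when no data is available). For padded windows the model is
restricted to the match states of the non-pad columns: a pad cell
contributes neither emission nor null mass. Probabilities stay within
float64 range at `L = 13` (worst paths ≈ 1e-18), so no log-space
rescaling is needed; scores are reported in bits.

Thresholds: candidate cutoffs are all midpoints between adjacent
distinct observed scores plus sentinels beyond both extremes; the
decision rule is strict (`score > threshold`). The scan maximizes
accuracy by default (MCC optionally), breaking ties toward higher MCC
and then toward the lower, more sensitive threshold. In end-to-end
training the threshold is selected on the same cluster-plus-sampled-
negatives scores the model was trained beside; honest performance
estimates come from the cross-validation machinery, which re-trains
and re-selects per fold, never touching the held-out fold.

## Evaluation protocol

Negatives for each subgroup are sampled uniformly without replacement
at `round(n_pos × ratio)` with ratio 2.08 (round-half-to-even),
reproducibly from a seed. Folds are label-stratified — within each
label, fold sizes differ by at most one — because several subgroups are
small and unstratified folds can starve a fold of one class; the seed
is recorded. Metrics are the standard confusion-matrix set: SEN =
TP/(TP+FN), SPE = TN/(TN+FP), ACC, and MCC with the zero-denominator
convention MCC = 0; AUC is the probability a random positive outscores
a random negative (ties half). Subgroup reports are combined by
unweighted macro-averaging; tables print percentages to two decimals
and MCC to 3–4, with internal values unrounded. The combined
predictor's decision rule is the union ("any model fires", rule id
`union-v1`) — the natural reading of per-model cutoffs; the rule id is
stored with the model so routing alternatives can be added.

## Synthetic benchmark

The generator draws windows from a mixture of subpopulations: flanks
from a background composition (uniform by default; a named
"ubiquitin-like" preset enriches A, Q, L, S, V), a forced central K,
and planted per-position group biases. Hidden subpopulation labels are
returned separately and never written into fragment files. Benchmark
conditions, fixed once:

- **Two-motif CV benchmark**: 400 positives, half with aromatic at +1
  and half with aromatic at −1 at bias probability 0.9 ("strong but
  noisy"), negatives pure background at the 1:2.08 ratio. Used for the
  clustered-vs-single comparison (50 seeded replicates in the
  acceptance script).
- **Recovery benchmark**: 400 positives from two subpopulations with
  paired, disjoint certain biases (aromatic@+1 + acidic@−1 vs the
  mirror image). With single overlapping biases, background aromatics
  (3/20 per cell) contaminate the split and adjusted-Rand recovery of
  0.95+ is unreachable in principle; the disjoint pairing is the regime
  "exact recovery" describes.

What passing these tests shows: the chi-square machinery detects
planted dependence, the recursion separates separable subpopulations,
and per-subgroup models beat a single pooled model when distinct
sub-motifs truly exist. What it does not show: performance on real
proteomes — real backgrounds are non-uniform and autocorrelated, real
motifs are weaker and overlapping, site density is far lower, and
homology structure is richer than anything the generator emulates.

## Problem sizes and other fixed choices

Simulation sizes (400-positive benchmarks, 100 null simulations, 50
replicates, five folds) were chosen as the smallest scales at which the
planted effects are comfortably detectable, and are stated alongside
every reported number. Logo statistics use IC = log₂20 − H in bits
with no small-sample correction, letter height = frequency × IC, and
IC = 0 for zero-support columns. Protein simulation places
non-overlapping planted windows by bounded rejection sampling and
reports an error when the requested sites cannot fit. Serialization of
models and predictors is versioned plain text using exact float `repr`,
so round-trips are bit-exact.

## Known limitations

- No E-values and no HMMER score parity; thresholds act on bit scores.
- No local/glocal alignment modes: queries are fixed-length windows.
- The per-pair chi-square cutoff splits null data more often than a
  familywise-controlled one (see above).
- Binary splits only; no one-child-per-group splitting or re-merging.
- The union decision rule is the only combination rule implemented.
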