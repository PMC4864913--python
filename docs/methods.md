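# Methods

## The problem

Gene-expression connectivity mapping matches a *query gene signature* — a
short ordered list of genes with up/down regulation status that summarizes a
biological state (typically a disease-versus-normal contrast) — against a
database of *reference profiles*, genome-wide signed rankings of probes by
differential expression under individual drug treatments. Compounds whose
profiles oppose the signature are candidate therapeutics (reversal
connections); compounds whose profiles agree share mechanism with the state.

The question `sigprog` addresses is how long the query signature should be.
Too short and it under-determines the biology; too long and genuine but minor
features drown the main theme in spurious connections. The package implements
a two-stage procedure: (1) stringent paired differential-expression analysis
producing a ranked list of n significant genes, and (2) *gene signature
progression* — querying the database with the top-k genes for k = 1, 2, …, n
and stopping at the smallest k whose returned connections meet a target
empirical false discovery rate.

## Stage 1: differential expression

Each probe is tested with a paired-sample t test on the per-subject log2
differences d_i = treatment_i − control_i:

    t = d̄ / (s_d / √n_pairs),   p two-sided from t with n_pairs − 1 df.

Multiple testing is controlled by bounding the expected number of false
positives: at threshold p < E_fp/N (N = number of probes), the expected
false-positive count under the global null is exactly E_fp. The default
E_fp = 1 is deliberately tight — every declared gene should be real.

Two biological filters follow (flags are conjunctive, order immaterial):

| parameter       | default | meaning                                            |
|-----------------|--------:|----------------------------------------------------|
| `e_fp`          | 1       | expected false positives tolerated over all probes |
| `min_mean_log2` | 6       | mean log2 expression required in ≥ 1 condition     |
| `min_abs_diff`  | 1       | minimum \|mean log2 difference\| (1 ⇔ fold change 2) |

Boundary values are retained (exclusion is strict "less than").
Zero-variance probes are degenerate for the t test: a zero mean difference
reports (t = 0, p = 1); a nonzero one reports the smallest positive double
with a `degenerate` flag. They are never silently dropped.

## Ranking and signed ranks

Selected genes are ordered by ascending p-value (M1, default), by descending
|mean log2 difference| (M2), or by the weighted combination
R = w_p·R_p + w_e·R_e of the two rank vectors with w_p + w_e = 1. The gene at
position j receives absolute rank j and signed rank ±j, the sign being its
direction of regulation. Ties are broken deterministically: M1 falls back to
effect size then probe id, M2 to p-value then probe id, weighted to p-value
then probe id; determinism matters because signature slices must be
reproducible.

A signature can also be *combined* from several reference profiles (to build
a drug-class signature from class members): per probe the signed ranks are
summed across profiles, probes with exact cancellation are excluded, the
rest are ordered by |sum| with sign(sum) as regulation status. Which probes
to keep is an open design point; the default keeps probes whose |sum| exceeds
the 0.99 quantile of a Monte-Carlo null (independent uniform signed ranks per
profile), with top-fraction and keep-all policies as alternatives.

## Connection scoring and the permutation test

With signature genes g_1…g_m (rank order) and a profile's signed ranks r(·)
over N_ref probes:

    raw = Σ_i w_i · r(g_i),  w_i = sign_i·(m − i + 1)   (ordered mode)
                             w_i = sign_i               (unordered mode)
    c   = raw / c_max,       c_max = Σ_{j=0}^{m−1} (m−j)(N_ref−j)  (ordered)
                             c_max = Σ_{j=0}^{m−1} (N_ref−j)       (unordered)

so c ∈ [−1, 1], attaining ±1 only for the extremal matching configuration.
Ordered mode is the default because query signatures carry signed ranks
constructed the same way as reference profiles. A compound's score is the
arithmetic mean of c over its replicate profiles.

Significance: n_perm random signatures of the same length (genes sampled
without replacement, signs fair coin flips) are scored against the compound's
whole replicate set, and

    p_left = (#{null < observed} + 0.5) / n_perm

(right-sided with >; two-sided twice the smaller, capped at 1). The +0.5
zero-avoiding correction makes the smallest reportable p at 10^5 permutations
5.0×10⁻⁶; ties between null and observed count as not-less-than
(conservative). The z-score is (observed − null mean)/null sd; a degenerate
null (sd = 0) reports z as missing.

A compound is marked significant (SM = 1) when p < N_fp/N_sets, the threshold
that tolerates N_fp false connections per query over N_sets compounds.
*Perturbation stability* (PS) of a significant connection is the fraction of
the m leave-one-out signatures (ranks closed up to 1..m−1) under which it
stays significant at the same threshold; PS is undefined at m = 1.

Numerical organization: the null for a given (m, compound) is computed once
per run and cached; its random stream is derived from the root seed, a CRC of
the compound name, and m, so results are independent of evaluation order and
exactly reproducible. Null generation is vectorized: each chunk draws iid
uniform keys over the universe, takes the m smallest per row (a uniform
m-subset in uniform order) and scores all replicates with one einsum.

## Stage 2: the progression loop

For k = k_start, k_start + k_step, … ≤ k_max the top-k signature is queried;
with N_p significant connections the empirical FDR is

    eFDR(k) = min(1, N_fp / N_p)        (eFDR = 1, flagged, when N_p = 0).

The loop stops at the first k with eFDR ≤ α (default α = 0.1) — that k is the
optimal signature length. If no k reaches α the earliest argmin of eFDR is
reported with `achieved = False`; the sentinel value for N_p = 0 keeps this
fallback total. With k_step > 1 a coarse hit is refined by rescanning the
skipped interval at step 1, so the reported optimum is exact; the defaults
(step 1) execute the plain procedure. Note eFDR ≤ α forces N_p ≥ ⌈N_fp/α⌉
(≥ 10 at the defaults), so the stop can only occur once the query returns a
healthy crop of connections. Each k is scored independently; compounds
significant at intermediate k need not persist to the optimum.

## Synthetic data: what it emulates and what it does not

`generate_paired_expression` draws per-probe baselines ~ N(8, 1) on the log2
scale, adds N(0, 0.3²) within-pair noise to both conditions, and shifts a
planted subset of probes by ±2 log2 units in the treatment arm (half up, half
down). Defaults — 2000 probes, 30 pairs, 100 planted DEGs — describe a
well-powered two-fold-change microarray study; at these settings the paired
t test has essentially full power at the E_fp = 1 threshold, so the filter
cascade recovers ≳ 95% of planted probes, and with the effect set to 0 the
significant count is ≈ E_fp per matrix.

`generate_reference_db` builds background compounds as independent uniform
signed-rank permutations and planted compounds by placing the planted gene
set, with chosen signs (flipped for anti-correlated compounds), at uniformly
random positions inside the top band of absolute ranks. The band size is
g + round((1−strength)·(N−g)): at strength 1 the planted genes are exactly
the top g ranks; as strength → 0 planting degrades to uniform. Planting acts
on ranks directly rather than via simulated expression, since the scoring
engine consumes ranks.

`hdaci_style_fixture` stages a drug-class recovery experiment: seven
compounds share one planted theme (60 genes, strength 0.95, universe 600
probes) — four "input" compounds with replicate counts (1, 7, 3, 2) from
which the class signature is combined, three held-out with (12, 18, 6) — on
top of 100 pure-noise background compounds. A successful end-to-end run
combines the four, progresses at α = 0.1, and returns all seven theme
compounds significant. Because eFDR ≤ 0.1 with N_fp = 1 requires at least 10
significant connections, the stop additionally needs ~3 background compounds
at the threshold — about one is expected per query by construction, so the
break-out k is partly driven by that fluctuation, mirroring how the real
experiment returned its class drugs alongside a few unrelated compounds.

What the generators do *not* model: probe-level effects and saturation,
correlated genes, batch effects, heteroskedastic noise, and any relationship
between expression level and variance. Passing tests therefore demonstrate
the statistical machinery is correct under its stated model, not that the
thresholds are optimal for any particular real platform.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run at desk scale: permutation
tests at n_perm = 10³–2×10⁴ for unit checks, 10⁵ only for the p-floor check
on a 5-probe universe; the class-recovery run uses the fixture defaults above
at n_perm = 10⁴; null calibration uses 200 simulated 1000-probe matrices.
These sizes were chosen so a complete run takes minutes on one core while
keeping every Monte-Carlo tolerance at ≥ 3 standard errors.

## Known limitations

- The reference-profile tie rule (stable sort, probe id as final key) and the
  zero-log-ratio sign (+1, logged) are local conventions; real sscMap-era
  databases may have used others.
- The leave-one-out definition of perturbation stability is one of several
  published perturbation schemes.
- Left-sided testing finds reversal connections only; use `--sided right`
  for mechanism-sharing queries and `two` for both.
- No moderated t statistics or shrinkage: the expected-false-positive bound
  is the designed control and assumes roughly valid per-probe p-values.
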