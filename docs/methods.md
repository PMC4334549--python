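# Methods

## The ERC statistic

The input is one phylogenetic tree per gene, with branch lengths in
substitutions per site, on a shared species topology (species subsets
allowed). Branches are identified by the bipartition they induce on the full
leaf set, canonicalised as the side not containing the lexicographically
smallest species, which makes branch identity independent of rooting and
file order. When a gene lacks some species, the reference topology is
restricted to the gene's species set; a restricted branch that corresponds
to a single reference branch keeps its length, while a branch formed by
merging a pruned path sums lengths of non-comparable pieces and is therefore
treated as **absent** for that gene. Zero-length branches are valid data and
kept. Genes observed in fewer than `min_species` species (default 17, the
usual cutoff for a 33-species mammalian panel) are dropped.

Branch lengths are dominated by the shared species divergence times. The
projection normalization removes that common component: with `a` the
per-branch mean length over all retained genes (computed once, not
leave-one-out — with hundreds to thousands of genes the self-contribution is
negligible), each gene's relative-rate vector is

    r_g = b_g − (⟨b_g, a⟩_P / ⟨a, a⟩_P) · a

with inner products restricted to the gene's present branches P. By
construction ⟨r_g, a⟩_P = 0 (asserted to 1e-9 in tests), the presence mask
is unchanged, and scaling a gene's lengths by c scales its residual by c
exactly. Raw lengths are the default; `sqrt` and `log1p` variance
stabilisers are available behind a switch.

The ERC value of a pair is the Pearson correlation of their relative rates
over the branches present in **both** genes (Spearman available as an
option). An entry is undefined — and propagates as missing, never as zero —
when the shared-branch count is below `min_shared` (default 10; a
correlation over fewer points is noise-dominated) or either restricted
vector is constant.

## Group statistics

The mean ERC of a gene group averages all defined unordered member pairs.
Significance is a one-sided permutation test: `n_perm` random gene sets
(default 100,000), size-matched to the group's matrix-present gene count,
drawn without replacement within a set from all genes in the matrix; the
p-value is the tally fraction `#{null mean ≥ observed}/n_perm`, with ties
counting for the null. A zero tally is reported censored as `<1/n_perm` and
imputed at `1/(2 n_perm)` for downstream FDR work. The null universe, the
≥-tie rule, and the censoring convention are deliberate, documented choices;
the minimum group size is 3 matrix-present genes (2 available as a
compatibility option). Because the observed group and the null sets are
drawn from the same universe, the test is exactly calibrated on
covariation-free data regardless of the branch-length distribution — the
acceptance suite verifies uniformity of 200 null p-values by KS test.

Disease-pair tests reuse this machinery between two groups: genes shared by
both diseases are removed from **both** groups (the strict reading that
guarantees no self-correlation inflation), the observed statistic is the
mean over defined cross pairs, and the null draws disjoint random set pairs
matching the post-drop sizes (default 10,000). The two set sizes enter the
sampler in sorted order so that testing (A, B) and (B, A) with one seed
gives bitwise-identical p-values. In the all-pairs scan the comparison
count `n(n+1)/2` includes self-pairings for bookkeeping, but self-pairs are
never tested and never become edges; edges are pairs with q ≤ the FDR
threshold (default 5%), and clusters are plain connected components.

## q-values and η₀

Across a scan, q-values follow the Storey recipe `q(i) = min_{j≥i} η₀ m
p(j)/j`. η₀ — the proportion of groups with no ERC signature — is estimated
from the flat tail of the p-value histogram: the tail estimates
`#{p > λ}/(m(1−λ))` on the grid λ = 0.00–0.90 (step 0.05) are clipped at 1
and averaged over λ ∈ [0.3, 0.75]. The classical alternative (smooth the
curve, extrapolate to the last grid point) is near-equivalent for thousands
of tests but has standard deviation ≈ 0.2 at the few-hundred-test scale this
package targets, which makes it unusable there; the mid-grid average has
≈ 0.08 at m = 100 with negligible bias on the scan scenarios and the
Beta-mixture oracle used in tests. Censored p-values enter as `1/(2N)`.
Benjamini–Hochberg (η₀ ≡ 1) is available via `method="bh"` and is delegated
to statsmodels.

## Prioritization

GROUP scoring (the default applied in all benchmarks) gives each candidate
the mean of its defined ERC entries with the training genes; BEST scoring
takes the maximum. Candidates are ranked by descending score with mean ranks
at ties; the reported percentile is the fraction of candidates scoring
strictly lower, so rank 1 of n gives (n−1)/n and undefined-score candidates
rank below every defined score (they cannot be prioritized and must not
inflate percentiles). Window candidate lists take all genes whose interval
overlaps a window of total width `window_bp` centred on the target's
midpoint (default 1,000,000 bp; the literature this mirrors states both
"1 Mb" and "10 MB" in different places — 1 Mb total width is used here and
the choice is configurable). The target itself is a member of its candidate
list. Scattered mode draws candidates uniformly without replacement from the
matrix, excluding training genes, with the count matched to typical window
sizes (default 90) for comparability. Empirical candidate p-values compare
the candidate's GROUP score against `n_rand` genes drawn uniformly **with**
replacement (a clean binomial, exhaustively checkable on toy universes),
censored at `<1/n_rand`. The leave-one-out benchmark drops each group member
in turn, trains on the rest, and records the target's rank/percentile plus
the training set's own permutation p-value, whose bands index the summary —
prioritization is only informative when the training set itself covaries.

## The synthetic generator

Branch lengths are generated as

    b[g, i] = t_i · μ_g · exp(σ · d[g, i]),
    d[g, i] = √ρ · s[P(g), i] + √(1−ρ) · e[g, i],

with branch times `t_i` log-normal (median 0.05 substitutions/site, sdlog
0.6 — mammal-scale trees span roughly an order of magnitude in branch
length), per-gene rate multipliers `μ_g` log-normal (sdlog 0.4), rate
dispersion σ = 0.3 (moderate), one standard-normal factor `s` per
(pathway, branch) — covariation lives on branches, the axis ERC correlates
over — and independent per-gene noise `e`. The within-pathway correlation of
the latent `d` rows is exactly ρ and 0 across pathways. Species are dropped
per gene with probability 0.2 (each gene keeps at least 4) to exercise the
presence masks; default tree size is 32 species (61 unrooted branches).
Written gene trees round-trip bit-exactly through the loader, including the
merged-branch masking rules.

What the generator does **not** emulate: real amino-acid substitution
processes, correlated missingness (real orthology loss is phylogenetically
clustered), rate heterogeneity along a single branch, and the broad positive
background correlation seen in real proteomes (the ~59% positive null
fraction reported for real mammalian data; the synthetic null sits at 50%).
Passing tests therefore certify the statistical machinery, not the
biological effect sizes of any real dataset — published mean-ERC values for
real diseases (e.g. 0.344 for a 17-gene complement-deficiency group) require
the original 33-species rate data and are treated as reference behaviour
only.

### Expected attenuation of recovered ρ

The mean within-pathway ERC recovered from the pipeline sits slightly below
the planted ρ, for three understood reasons: (i) the multiplicative form —
the correlation of `exp(σd)` pairs is `(e^{ρσ²}−1)/(e^{σ²}−1) < ρ`, about
−0.011 at ρ = 0.5, σ = 0.3; (ii) branch-time dispersion reweights the
Pearson sums (effective branch count ≈ B·e^{−4·sdlog²}), adding a
finite-sample correlation bias of order −ρ(1−ρ²)/(2n_eff); (iii) the
pathway's shared factor leaks into the genome-average vector in proportion
to the pathway's fraction f of the gene universe and is then projected out,
costing about −2fρ — at f = 0.2 the recovered value drops to ≈ 0.37, which
is a property of ERC itself (covariation shared by much of the genome is
indistinguishable from the time signal), not an implementation artifact.
Recovery experiments therefore embed a 20-gene pathway in a 500-gene
background (f = 0.04) at full branch coverage, where the combined
attenuation stays inside the ±0.05 acceptance band (≈ 0.46 recovered at
ρ = 0.5, ≈ 0.27 at ρ = 0.3). The same normalization leak gives
cross-pathway pairs a small anticorrelation of order −2fρ, verified to
vanish as the universe grows.

Relatedly, Fisher's `z = atanh(r) ~ N(0, 1/(n−3))` null law presumes
homogeneous per-branch scales; with sdlog 0.6 the common `t_i` weights
inflate Var(z). The distributional test of that law runs at low time
dispersion (sdlog 0.1), where it holds to KS precision; permutation
calibration is exact at the default dispersion by exchangeability.

## Numerical and engineering choices

- All randomness flows through `numpy.random.Generator`; scans and pair
  tables spawn one child stream per unit from a single `SeedSequence`, so
  results are reproducible and independent of iteration order. Null-set
  sampling is vectorised (argpartition over random keys for universes up to
  4096 genes) and chunked to bound memory.
- The all-pairs Pearson matrix is computed with masked matrix products and
  then symmetrised exactly; entries are clipped into [−1, 1] and the
  diagonal is undefined. Matrix TSVs are written at %.17g so round trips are
  bit-exact; the npz container stores the same arrays with a SHA-256
  checksum verified in strict-mode loads.
- Degenerate inputs fail loudly with typed exceptions: unparseable newick
  names the file, alien leaves name the species, topology conflicts name the
  offending split, empty filters / all-undefined scores / all-shared disease
  pairs raise rather than return silence. A permutation test refuses only
  when the universe admits no null set other than the group itself and warns
  below twice the group size.
- Problem sizes in the test and acceptance suites (32 species, 200–1000
  gene universes, 25–200 replicates, 1000–10,000 permutations) are the
  package's standard desk-scale study conditions: large enough that the
  statistical claims under test are in their validity regime, small enough
  to iterate on.

## Known limitations

- ERC values between pairs sharing a gene are correlated; the permutation
  tests account for this implicitly, but the z-based intuition does not.
- The Storey-type η₀ estimator has an information floor of ≈ 0.08 sd at 100
  tests; single-scan η₀ values at that scale carry that uncertainty.
- Spearman mode falls back to a per-pair loop (ranks must be recomputed on
  each shared-branch subset) and is markedly slower than Pearson.
- The disease-table parser groups by exact normalized name only; curation of
  disease nomenclature is the user's responsibility.
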