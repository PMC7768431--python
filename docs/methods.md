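# Methods

This note documents the models and procedures `fluencynet` implements, the
defaults it ships, the numerical choices that are not forced by the science,
and what its synthetic benchmark does and does not establish.

## Group semantic networks from fluency data

The unit of analysis is a group, not a participant. Responses are cleaned
(lemmatization via a user-supplied map, removal of within-participant
repetitions and of non-category intrusions), and words produced by fewer than
`min_producers` (default 2) participants in the whole sample are dropped as
idiosyncratic. The idiosyncrasy filter is applied sample-wide *before*
group splitting so that the unique-response (McNemar) analysis runs on a
well-defined common word universe; for network construction it is anyway
subsumed by equating. Cross-group equating then restricts both group
matrices to words produced by ≥ `min_per_group` (default 2) participants in
*each* group, so both networks are defined over the identical node set.

Similarity is the cosine between binary incidence columns — the
co-production count normalized by the geometric mean of production counts —
which is non-negative by construction, avoiding the interpretive burden of
negative associations. Zero similarities are admissible edge weights; no
epsilon thresholding is applied anywhere.

### TMFG

The Triangulated Maximally Filtered Graph is built greedily: seed with the
4-clique of maximum total pairwise similarity, then repeatedly insert the
(node, triangular face) pair with the largest summed similarity from the
node to the face's three vertices. The result is maximal planar: 3n − 6
edges, connected, minimum degree 3. Numerical choices:

* The seed clique is found by exhaustive (vectorized) enumeration of all
  4-subsets up to n = 25 and by a weighted-degree greedy heuristic above —
  exactness where it is cheap, scalability where it is not. Fluency networks
  in the intended regime (30–60 nodes) use the heuristic for full matrices
  and the exact search inside bootstrap subsets.
* All ties (seed clique and insertion gains) resolve to the first candidate
  in node order, making graphs bit-reproducible across runs and platforms.

### Measures

* **CC** — mean local clustering (Watts–Strogatz form); nodes of degree < 2
  contribute 0. The mean-local form is used rather than transitivity.
* **ASPL** — mean hop distance over unordered pairs. TMFG output is always
  connected; arbitrary user graphs that are disconnected are reduced to the
  largest component with a warning, never silently infinite.
* **Q** — Newman modularity of the best partition across 10 seeded Louvain
  restarts (igraph's implementation). Restarts tame the stochasticity of
  Louvain on 30–60-node graphs; the returned Q always equals the
  definitional modularity of the returned partition.
* **S** — Humphries–Gurney small-world-ness,
  S = (CC/CC_rand)/(ASPL/ASPL_rand), with the reference terms averaged over
  `n_ref` (default 100) Erdős–Rényi G(n, m) draws matched on node and edge
  count. S ≈ 1 for random graphs by construction. Where many graphs of
  identical size are measured (null ensembles, bootstrap), one reference
  ensemble is shared — exact, since the reference depends only on (n, m).

## Validation machinery

**Random-network nulls.** 1000 Erdős–Rényi G(n, m) draws matched to the
empirical network's size; all four measures per draw; one-sample Z-test of
the empirical value against the null mean and SD. At fluency-network
densities a few percent of draws are disconnected; their ASPL uses the
largest component and the count is reported.

**Graded partial-network bootstrap.** Per realization, one node subset of
size round(p·n) (p ∈ {0.5, …, 0.9}; round half away from zero) is drawn
without replacement and applied to *both* incidence matrices, and each
group's network is re-estimated from scratch on the restricted matrix —
re-estimation, not induced subgraphs, keeps every partial network a proper
3n′ − 6 planar filter. Sharing the subset (and the Louvain seed) across
groups pairs the comparison on content. Per proportion and measure, the two
n_boot-sized samples are compared by a pooled-variance two-sample t
(df = 2·n_boot − 2, oriented high − low) with Cohen's d. Realizations are
driven by per-counter substreams of the master seed, so increasing n_boot
extends rather than reshuffles the sequence. A caveat inherited from the
procedure as published: realizations overlap in nodes and are not
independent, so the nominal t degrees of freedom overstate the information
content; the t and d values are descriptive separation indices, not
calibrated tests.

**Unique-response McNemar.** With b = words produced only by the high group
and c = only by the low group over the N-word universe, the statistic is the
continuity-corrected χ² = (|b − c| − 1)²/(b + c) with 1 df and
φ = √(χ²/N). The continuity-corrected form is the one consistent with the
worked values this package reproduces in its tests.

**Behavioral scoring.** AUT: idea creativity is the two raters' mean;
creativity sum, its per-participant total; creativity mean, sum/fluency;
ODT = creativity mean + flexibility. Inter-rater agreement is the two-way
consistency ICC (single- and average-measure forms both returned, since
reports often leave the variant ambiguous). Correlations are Spearman, with
natural-log transforms for the skewed count-like indices; zeros fall back to
log(x+1) with a warning. Median splits stably sort by (score, participant
id) so ties at the median resolve deterministically; group contrasts use
Student's pooled-variance t and pooled-SD Cohen's d.

## The synthetic study generator

Fluency corpora from child studies are typically not shareable, so the
package ships a generator with known ground truth. The "true" semantic
network is a planted-partition (stochastic block) graph, regenerated until
connected. Each participant performs a censored random walk: start at a
uniform word; at each step teleport to a uniform word with probability ε,
otherwise move to a uniform neighbour; emit first visits until the drawn
response count (shifted Poisson, 3 + Poisson(mean − 3), mean 10) is reached.
ε operationalizes associative flexibility: frequent jumps cut across
community boundaries, so high-ε groups yield less modular, shorter-path,
more small-world estimated networks. The grouping score is drawn from
non-overlapping uniforms per group (so a median split exactly recovers the
generating groups); non-grouping covariates are drawn identically in both
groups, making their contrasts null by construction.

Defaults (fixed once, by scanning the generator against the study conditions
the package targets): 150-word vocabulary, 8 equal communities, within- and
between-community edge probabilities 0.7 and 0.01, 29 + 29 participants,
ε = 0.05 (low) vs 0.4 (high). At these settings a study produces ≈ 130
words with two or more producers, matching the scale of a real one-minute
animal-fluency study of 58 children, and the ε contrast reproduces the
flexibility signature (lower ASPL and Q, higher S in the high group) in
≈ 95% of seeds at the bootstrap's 50% retention level with n_boot = 200.

What the generator does *not* emulate:

* **Production-frequency skew.** Real category fluency is heavily Zipfian
  (everyone says "dog"; few say "tapir"), which makes the cross-group
  equated set much smaller than the unique universe (roughly a quarter). The
  walk model with equal-size communities and uniform starts is far flatter:
  at the defaults, equating retains ≈ 40–55 words rather than ~30. Passing
  tests therefore establish the pipeline's behaviour, not distributional
  realism of child lexicons.
* **Estimator sampling noise is real noise.** Two groups generated with the
  *same* ε still differ: 29 walkers are a small sample, and the re-estimated
  networks inherit that variability as stable structural differences, which
  the bootstrap faithfully reports as non-zero d (typically max |d| ≈ 0.2–0.6
  at 50% retention). A user comparing real groups should interpret modest
  effect sizes against this baseline rather than against zero.
* **Q versus ε is monotone only while community structure dominates.** For
  near-uniform walks (ε ≳ 0.5) the similarity matrix is nearly flat and the
  TMFG degenerates to an effectively arbitrary planar triangulation, whose
  modularity is intrinsically high (Q ≈ 0.59 at these sizes); estimated Q
  therefore falls from ε = 0 to ε ≈ 0.4 and floors thereafter.

## Problem sizes used by the shipped checks

The test suite and the acceptance script are sized to run on one CPU in a
few minutes as a deliberate design choice: null ensembles use 1000 draws
(the reference count) at the fluency-network sizes 31/87 and 33/93;
parameter-recovery checks use 20 master seeds with n_boot = 200 at 50%
retention; the structural TMFG suite spans n = 4…40. Larger runs only
change Monte-Carlo error, not behaviour.

## Known limitations

* The TMFG insertion gain is the plain similarity sum to a face's vertices;
  no corrections for already-placed neighbours are applied (the standard
  greedy construction).
* Exact modularity is only verified against exhaustive search at toy sizes
  (n ≤ 8); Louvain with restarts is a heuristic and can in principle miss
  the optimum on adversarial graphs.
* Weighted-network variants of the measures, Pearson-correlation similarity
  networks, and percolation-robustness analyses are out of scope.
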