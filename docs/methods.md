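# Methods

This note documents the models and numerical choices behind `moanet`, what
the synthetic-data generators do and do not emulate, and the design
decisions taken where the problem left room.

## Network construction

The generic interaction network is any undirected simple graph read from a
2-column TSV or SIF edge list; self-loops are dropped and duplicate edges
collapsed on ingest, since neither has meaning for diffusion. Expression
filtering keeps genes with FPKM > 0.1 (the conventional "expressed" floor)
in *either* the control or the treated condition — the filter exists to
remove silent genes, and a gene switched on or off by treatment is
biologically present in the experiment. Genes missing from the expression
table count as not expressed. Nodes isolated by the intersection are
removed so every transition-matrix column is well defined.

Fold changes are (treated FPKM + 0.1)/(control FPKM + 0.1); the pseudocount
matches the expression floor and keeps ratios finite. A precomputed
`fold_change` column, when present, overrides the FPKM ratio.

Edge weights express co-regulation: w = 1 + f(|log2 fC_A|, |log2 fC_B|)
with f = min by default. The min form satisfies the constraints the weight
must have — symmetry, baseline 1 when either endpoint is unregulated, and
growth only when *both* endpoints respond — while staying on an
interpretable scale (w − 1 is the weaker endpoint's absolute log2 response).
Absolute values are used because co-regulation in either direction marks a
functionally engaged interaction. A geometric-mean alternative
(1 + sqrt(|l_A|·|l_B|)) with the same properties is available via
`weight_function="geometric_abs_log2"`; conclusions on synthetic data are
insensitive to the choice, which is why it is a config switch rather than a
second code path.

## Random walk with restart

The transition operator column-normalizes the weighted adjacency matrix:
P(B|A) = w_AB / Σ_C w_AC. The walk solves p = (1 − α) T p + α p0 with
restart probability α = 0.3. Two independent solvers are provided:

- `rwr`: power iteration, L1 residual < 1e−10, at most 10,000 iterations.
  The iteration contracts by (1 − α) per step, so the default tolerance is
  reached in ~65 iterations regardless of network size.
- `rwr_direct`: the sparse/dense linear solve of (I − (1 − α)T) p = α p0.
  The system is non-singular for any α > 0. Networks up to 3,000 nodes are
  densified (LAPACK is faster there); larger ones use sparse LU. This
  solver is the oracle in the test suite, never the production path.

Seed strengths are sc_immobilized / (sc_competition + 1); the pseudocount
keeps ratios finite when the competition experiment records zero spectra.
Seeds absent from the filtered network are dropped with a warning and the
remaining mass renormalized — a drug target can fail the expression filter
in a given cell line without invalidating the run.

### Node significance

The null re-runs the walk from 100 uniformly drawn random target sets of
the same cardinality, carrying the true strength multiset in fixed order,
and pools all node probabilities (sample size 100 × |nodes|). Empirical
p-values use (1 + k)/(1 + n) so no node reaches p = 0; the top-5% flag
marks nodes at or above the null's 95th percentile (ties kept). The two
flags (`top5`, `sig005`) answer different questions — extremeness within
the landscape versus rarity under the null — and are reported separately
rather than merged. Random targets are drawn from all network nodes;
restricting the null to a compartment (e.g. kinases) would require
annotation the pipeline does not assume.

## Gene-set scoring

Node probabilities strictly below their 95th percentile are zeroed (ties at
the threshold survive) and each term scores the sum over its members;
genes outside the network contribute nothing. Null scores come from 1,000
uniform node sets matched for size, drawn from the network (scores live on
network nodes, so the network is the correct universe even when the
annotation covers more genes).

Term p-values use the plain permutation estimator p = k/n, where k counts
null scores ≥ observed. The conservative (1 + k)/(1 + n) variant is
deliberately *not* used here: with hundreds of terms and 1,000 affordable
resamples per term, its floor of 1/1001 puts the smallest possible BH
q-value at ~0.2, and no term could ever clear a 5% FDR — the estimator
would decide the analysis, not the data. A term beating all 1,000 resamples
is reported at p = 0 and its selection is what the procedure is for.
Benjamini–Hochberg adjustment is delegated to statsmodels.

### Leave-one-target-out impact

Each target is removed in turn, the remaining seed probabilities
renormalized, and the walk and term scores recomputed; the matrix entry is
log10((score₋t + ε)/(score_full + ε)) with ε = 1e−12 guarding empty terms
(entries where both scores are below ε are set to 0). Negative entries mark
targets the term's association depends on. By default the matrix covers
the FDR-selected terms. A zero-strength target leaves the seed vector
unchanged, so its row is exactly zero — a useful internal control.

## Screen triage

Wells are divided by the median of their plate's negative controls
(median, not mean, for robustness to the occasional failed well).
Compound replicates are averaged after normalization, and z-scores are
referenced to the pooled normalized negative controls; a compound is a hit
at z < −2.12. Positive controls never enter the z-score; they feed an
informational Z′-style separation statistic for plate QC. Note that with
r replicates averaged against a single-well control sd, a null compound's
z-statistic has standard deviation ≈ 1/√r, so the −2.12 threshold is more
stringent on duplicate data than the single-well normal tail suggests.

Hit clustering is average-linkage hierarchical clustering (scipy) on
Jaccard distance between binary fingerprints, cut at a user-chosen
distance; clusters of ≥ 2 compounds are flagged as candidate scaffold
families. Compounds are processed in sorted-id order, making the partition
independent of input order. Linkage is configurable; average linkage is the
default because it behaves sensibly for the moderately noisy, moderately
sized families the planted-cluster generator emulates.

## Bliss synergy

Dose–response matrices carry viability fractions with dose-0 row/column as
single agents; viability is renormalized to the untreated well, effects
E = 1 − v are clamped to [0, 1] (raw deviations are kept alongside), and
the synergy matrix is E_obs − (E_x + E_y − E_x·E_y) on the interior cells,
summarized by mean and max. Replicate matrices should be averaged before
the computation; per-replicate deviations can be obtained by calling the
function per replicate.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *statistical structure* the pipeline assumes,
not the biology it came from:

- **Network**: preferential attachment (Barabási–Albert with
  m ≈ mean_degree/2, largest component kept) gives the heavy-tailed degree
  distribution and connectivity diffusion relies on. Default 500 nodes,
  mean degree 10 — large enough for stable permutation nulls, small enough
  for sub-second walks.
- **Expression**: control FPKM is 0.1 + log-normal(μ=1, σ=1.2), so every
  gene passes the expression floor; a BFS neighborhood of 50 genes around
  3 randomly chosen anchors gets |log2 fold change| centered at 2.0
  (random sign per gene, noise sd 0.3); background log2 fold changes are
  N(0, 0.3). The exact fold change is stored in its own column; treated
  FPKM is derived from it.
- **Targets**: 11 targets with integer count pairs realizing binding
  ratios in (2, 20); the fixture gives the module anchors ratios from the
  top quartile so the planted module is genuinely seed-proximal, and draws
  the remaining 8 targets outside the module. This mirrors the real use
  case: several strong targets concentrated in one functional neighborhood
  plus weaker off-target binders elsewhere.
- **Gene sets**: 200 decoy terms of 10–200 uniformly drawn genes plus one
  term equal to the planted module.
- **Dose–response**: Hill single agents (EC50 1.0, slope 1.5, E_max 0.5 by
  default — low enough that a planted interaction of 0.2 never saturates
  the [0,1] clamp); interior cells are Bliss expectation + interaction +
  noise. Noise applies to combination wells only, so the interior deviation
  of a noise-free matrix equals the planted interaction exactly and the
  noisy deviation is exactly half-normal.
- **Screen**: duplicate plates; negative controls and inert compounds
  share N(μ, 0.05μ); positive controls sit near zero; planted hits are
  shifted down by hit_effect·σ. A replicate-count parameter exists because
  the z-statistic's null variance depends on it (see above).
- **Fingerprints**: cluster prototypes are Bernoulli(0.3) bit vectors;
  members flip each bit with probability 0.05; every fingerprint keeps at
  least one set bit so Jaccard similarity stays defined.

Passing recovery tests on these fixtures shows the statistical machinery is
sound — that planted signal of the stated size is found and planted null
structure is not. It does not show the method overcomes what the generators
leave out: annotation bias and overlapping real gene sets, correlated
expression noise, false edges and ascertainment bias in curated interaction
networks, or batch structure in real screens.

## Numerical choices and degenerate inputs

- Determinism: every stochastic routine takes an integer seed;
  `numpy.random.default_rng` throughout. The pipeline derives per-stage
  child seeds from the root seed by fixed offsets so cached stages can be
  re-run identically.
- Empty or degenerate inputs fail loudly: empty filtered network, all-zero
  seed strengths, missing dose-0 row/column, fewer than two negative
  controls, all-zero fingerprints, single-target leave-one-out.
- Ties: kept at the node-probability threshold and at the null's top-5%
  quantile (≥, not >).
- Tolerances: walk convergence 1e−10 (L1), conservation asserted at 1e−9,
  solver-equivalence tested at 1e−8 (L∞).

## Known limitations

- Gene sets are flat; no ontology DAG propagation.
- The walk is undirected and memoryless; continuous-time kernels and
  directed signaling edges are out of scope.
- The −2.12 hit threshold is an input with a conventional default, not a
  quantity the package derives from control distributions.
- Term p-values at p = 0 are resolution-limited statements ("beats 1,000
  resamples"), not exact zeros; raise n_random where finer resolution
  matters.
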