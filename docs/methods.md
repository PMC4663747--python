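# Methods

This note documents the models, conventions, parameters and numerical
choices behind `microrep`, and what the synthetic-community validation does
and does not demonstrate about real data.

## Metabolic models and growth simulation

A model is a stoichiometric matrix **S** (metabolites × reactions) with flux
bounds, exactly one biomass pseudo-reaction, and boundary (exchange)
pseudo-reactions that each move a single extracellular metabolite across the
system boundary. Two compartments (cytosol, extracellular) suffice for all
analyses here; multi-compartment models are rejected at validation rather
than silently collapsed. Exchange reactions are written `1 M_ext →` with
positive flux as secretion, so "maximal uptake u" is an exchange lower bound
of −u. Files omitting bounds default to [0, 1000] mmol/gDW/h for
irreversible and [−1000, 1000] for reversible reactions, the conventional
"effectively unbounded" caps.

Growth is the linear program maximise v_b subject to S·v = 0,
v_min ≤ v ≤ v_max, solved with HiGHS (`scipy.optimize.linprog`). Only the
objective value (the growth rate, h⁻¹) is contract-stable: flux vectors at
degenerate optima depend on the solver path and are reported as-is, never
asserted on. Feasibility/optimality tolerances are 1e−9; growth-rate
comparisons use an absolute tolerance of 1e−6 h⁻¹.

### Medium and essentiality screen

The rich medium opens every exchange at the uptake limit (default
10 mmol/gDW/h, an estimate of naturally occurring uptake rates). Removing a
metabolite from the medium forces both bounds of its exchange reaction(s) to
0. This literal closure also blocks secretion of that metabolite; a
`removal_mode="uptake"` switch restricts the closure to the uptake side for
sensitivity analyses, but the both-bounds behaviour is the default. The
screen iterates over exchanged metabolites (not exchange reactions), so a
metabolite with several transporters is removed as a unit.

A nutrient is essential when its removal leaves growth below 0.05 h⁻¹ — a
cutoff motivated by doubling-time estimates for gut microbes. Removal LPs
that become infeasible are recorded as growth 0. The screen refuses to run
when the organism does not reach the cutoff on rich medium, since
essentiality is undefined without a growing baseline.

## Distances

- **Metabolic / phenotypic / annotation distance**: 1 − Jaccard index of the
  binary presence vectors taken over the union of features across the
  collection. Two all-zero profiles get distance 0 (identical), avoiding the
  0/0 case; this matches scipy's convention, which implements the
  computation. Distances are written to TSV at 12 significant digits so
  outputs are diff-stable.
- **Phylogenetic distance**: the cophenetic distance between two leaves,
  computed as the patristic path length through their most recent common
  ancestor. On non-ultrametric (real) trees, merge-height definitions of the
  cophenetic distance are ill-posed; path length is the convention of
  standard phylogenetics toolchains and coincides with the height-based
  definition on ultrametric trees. Trees must be rooted with branch lengths
  on every non-root edge; explicitly unrooted Newick input is rejected.

## Ordination, embedding, clustering

PCoA is classical Torgerson scaling: double-centre −½D², eigendecompose,
scale eigenvectors by √eigenvalue. Axes with nonpositive eigenvalues are
dropped and their summed magnitude is reported as
`negative_eigenvalue_mass`; no Cailliez/Lingoes correction is applied, on
the view that reporting the non-Euclidean mass is more transparent than
smoothing it away. Explained fractions are relative to the sum of positive
eigenvalues. Coordinates are sign-indeterminate per axis; tests compare them
only up to orthogonal transforms.

Feature loadings are Pearson correlations of each 0/1 feature column with
the first two coordinates (equivalently point-biserial), ranked jointly by
the L2 norm of the two correlations — a per-axis ranking would be equally
defensible; the joint ranking is the documented choice, with ties broken by
feature id for determinism. Constant features get relevance 0. The default
selection size of 200 features follows common biplot practice of showing a
fixed top set.

t-SNE runs on the precomputed distance matrix with random (seeded)
initialisation; the default perplexity is min(30, (n−2)//3), the largest
conventional value strictly below the (n−1)/3 validity bound. t-SNE output
is only used for local-structure inspection, never as a quantitative
surface.

Hierarchical clustering uses complete linkage, cut to exactly k clusters;
k is a user choice (dendrogram inspection is the intended workflow, as with
picking sub-type counts per genus). Cluster ids are assigned by decreasing
size, then lexicographically smallest member, so labels are stable.
Sub-type contrasts list features present in ≥ 90 % of one cluster and
≤ 10 % of the other (both thresholds configurable), sorted by the presence
gap.

## Cross-distance regressions

The exponential model y = 10^(α+βx) is fitted as an OLS regression of
log₁₀ y on x (semi-log transform). R² and RMSE are reported on the log₁₀
scale, consistent with fitting on transformed data; a
`rmse-scale`-style recomputation on the original scale is possible from the
stored pair table if needed. Pairs with y = 0 (identical leaves) cannot
enter the log fit; they are excluded from fitting but kept in `n_pairs` and
reported via `n_used`. The association measure is the Spearman rank
correlation of (x, y) over all pairs — invariant to the monotone transform,
so the raw/transformed ambiguity is moot. The linear model z = α + βx is
plain OLS with the Pearson correlation and z-scale RMSE.

Per-taxon summary tables fit both models for the full pair set and for each
(rank, label) subset with ≥ 3 members; failed subsets carry an error marker
instead of aborting the table. Correlations above 0.5 are flagged as strong.
The moving-average curve is a diagnostic only: pairs sorted by x, window of
⌈5 % of pairs⌉ points, step 1, reporting within-window means of x and the
response.

## Synthetic community generator

The generator produces the study conditions under which the pipeline is
validated; its defaults are fixed and not tuned per run:
100 organisms, 300 repertoire features, 15 nutrients, gain rate λ = loss
rate μ = 1 per unit branch length, alternative-route probability 0.5,
5 class-like and 10 genus-like clades, seed 42.

- **Tree**: pure birth (Yule), exponential waiting times, all tips extant.
  The birth rate defaults to 5 per lineage per unit time, which puts the
  expected root-to-tip depth near 1 for n = 100 — about one gain/loss event
  per feature per lineage at unit rates. This keeps pairwise divergence off
  the saturation plateau of the two-state process; extinction is omitted
  because the analysis consumes the tree only through cophenetic distances.
- **Repertoire evolution**: each feature evolves independently under the
  two-state Markov chain with P(0→1) = (λ/(λ+μ))(1 − e^−(λ+μ)t) over a
  branch of length t (symmetrically for loss), root states stationary. This
  induces the saturating, exponential-shaped relation between phylogenetic
  and repertoire distance that the regression stage targets. Horizontal
  transfer is deliberately absent — a known limitation: real gut microbes
  exchange metabolic genes across clades, which weakens the
  phylogeny–repertoire coupling relative to this generator.
- **Models**: every organism imports each nutrient k through an exchange and
  a transporter, converts it to biomass precursor k, and a single biomass
  reaction consumes all precursors. Where the organism carries the evolved
  "alternative route" trait for nutrient k, the partner nutrient k+1 also
  feeds precursor k, making nutrient k dispensable. Essentiality is thus
  wired structurally and the ground truth is exact by construction, without
  running FBA. Alternative-route traits evolve on the same tree under the
  same kinetics but with stationary presence equal to
  `p_alternative_route`, so the phenotype is phylogenetically structured
  like the repertoire. Repertoire features additionally appear as
  flux-silent dead-end reactions, shaping the presence profiles without
  touching growth. No pathway uses oxygen, so all models pass the anaerobic
  growth check.
- **Taxonomy**: class-like and genus-like labels come from cutting the
  (ultrametric) tree at the depths where exactly n_class and n_genus
  lineages coexist; genera nest within classes by construction.

What passing on this generator shows: the pipeline's stages are correct
(against oracles) and mutually consistent, and the expected qualitative
pattern — positive, saturating repertoire–phylogeny association; linear
repertoire–phenotype association — emerges when the data-generating process
matches the assumed one. What it does not show: robustness to annotation
bias, gap-filling artifacts, horizontal transfer, non-ultrametric trees, or
incomplete genomes, all of which affect real model collections.

## Determinism and problem sizes

All randomness flows from explicit integer seeds (community generation and
t-SNE); pipeline reruns with an identical configuration are byte-identical,
which the test suite asserts at file level. The validation suite uses
deliberately small problem sizes — ≤ 8-reaction LPs for vertex enumeration
(the oracle is exponential in the reaction count), ≤ 12 organisms for the
naive clustering oracle, the 100-organism default community for screen and
trend checks, and n = 2000 pairs × 20 replicates for regression parameter
recovery — sizes at which the independent oracles are exact and fast while
still exercising every code path.

## Known limitations

- The FBA layer covers growth maximisation only: no flux variability
  analysis, gene deletions, or community FBA.
- SBML support is a read-only subset (species, reactions, bounds,
  objective) routed through cobra; the package JSON schema is the native
  format.
- The generator's biomass reaction is a uniform all-precursor sink; real
  collections contain heterogeneous biomass compositions, which the
  analysis treats as given model content.
- Identifier namespaces are opaque tokens; no cross-database reaction
  mapping is attempted.
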