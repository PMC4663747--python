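# microrep

Linking what a microbe *can do* metabolically to *what it is* phylogenetically
and to *what it needs* to grow.

`microrep` is a Python library and command-line tool for comparative analysis
of collections of genome-scale metabolic models, aimed at microbial ecologists
and systems biologists working with communities such as the human gut
microbiota. Given one small metabolic model per organism and a rooted
phylogeny over the same organisms, it computes:

- **growth phenotypes** by flux balance analysis (FBA): maximise the biomass
  flux v_b subject to steady state S·v = 0 and flux bounds v_min ≤ v ≤ v_max,
  where S is the stoichiometric matrix and the bounds of exchange reactions
  encode the growth medium;
- **essential nutrients** by iteratively removing each exchanged metabolite
  from a rich medium (all uptakes open at 10 mmol/gDW/h) and calling a
  nutrient essential when the re-optimised growth rate drops below 0.05 h⁻¹;
- **pairwise distances**: metabolic distance as 1 − |b_i ∩ b_j| / |b_i ∪ b_j|
  (Jaccard) over binary reaction-presence vectors b, phenotypic distance as
  the same statistic over essential-nutrient sets, and phylogenetic distance
  as the cophenetic (patristic) path length between leaves of the tree;
- **ordination and clustering**: principal coordinate analysis with
  per-reaction loadings (the reactions most correlated with the leading
  coordinates), t-SNE for local structure, complete-linkage hierarchical
  clustering, and presence-fraction contrasts that extract the reactions
  distinguishing sub-type clusters;
- **cross-distance regressions**: the exponential model
  y = 10^(α + βx) relating metabolic distance x to phylogenetic distance y
  (fitted as ordinary least squares of log₁₀ y on x, summarised with the
  Spearman rank correlation), and the linear model z = α + βx relating
  essential-nutrient distance z to x (summarised with the Pearson
  correlation), for the full collection and per-taxon subsets.

Because real model collections are large and externally sourced, the package
ships a **synthetic community generator** with exact ground truth: a Yule
tree, reaction repertoires evolved along it by a two-state gain/loss Markov
process, and FBA-ready models whose essential nutrients are determined by
pathway wiring rather than numerics. Every analysis stage is validated
against that ground truth and against independent brute-force oracles.

## Worked example

Run the full pipeline on the default synthetic community (100 organisms,
300 evolving repertoire features, 15 nutrients):

```sh
microrep run --config config.yaml
```

with `config.yaml`:

```yaml
mode: synthetic
outdir: report
```

The report bundle contains, among other tables, `fits.json`:

```json
{
  "exponential": {
    "alpha": -1.320833771183552,
    "beta": 2.6889787456727,
    "correlation": 0.7642505633772232,
    "r_squared": 0.8344915891938571,
    "n_pairs": 4950
  },
  "linear": {
    "alpha": 0.07867218217494809,
    "beta": 1.1097218344068507,
    "correlation": 0.4937831860359279,
    "r_squared": 0.24382183481179165
  }
}
```

Reading this: over all 4950 organism pairs, phylogenetic distance grows
roughly as 10^(−1.32 + 2.69·x) in the metabolic distance x — a strong,
saturating (exponential) association (Spearman ρ = 0.76) — while the
essential-nutrient distance increases linearly with slope 1.11 but with much
more scatter (Pearson r = 0.49). Closely related organisms can thus differ
substantially in their repertoires, and the repertoire tracks the predicted
nutrient phenotype. The run log confirms the screen recovered the generator's
ground-truth essential nutrients exactly
(`"essentiality_truth_discordance": 0`) and that every model grows without
oxygen (`"anaerobic_capable_fraction": 1.0`).

Individual stages are also available as subcommands operating on files:

```sh
microrep simulate --outdir community/          # models/, tree.newick, taxonomy.tsv, ...
microrep essential --model community/models/org_0001.json --uptake 10 --cutoff 0.05
microrep distances --models community/models --tree community/tree.newick --outdir d/
microrep ordinate pcoa --dist d/dist_metabolic.tsv --out coords.tsv
microrep cluster --dist d/dist_metabolic.tsv --k 3 --out clusters.tsv
microrep regress --pairs report/pair_table.tsv --model exponential
```

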