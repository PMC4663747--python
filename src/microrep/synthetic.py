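"""Synthetic microbial communities with known ground truth.

The generator emulates the statistical structure the repertoire analysis
assumes, with every stochastic step driven by one seed:

1. a pure-birth (Yule) phylogeny with exponential waiting times;
2. binary repertoire features evolved independently along the tree under a
   two-state gain/loss Markov process (gain rate lambda, loss rate mu), root
   states drawn from the stationary distribution;
3. small FBA-ready metabolic models assembled from pathway templates, in
   which nutrient essentiality is wired structurally: organism o needs
   nutrient k unless it carries the evolved "alternative route" trait that
   lets the partner nutrient substitute for it.  Ground-truth essential
   nutrients therefore follow from the wiring alone, without running FBA;
4. monophyletic taxonomy labels at two nested ranks (class-like and
   genus-like) obtained by cutting the tree at two depths.

All pathways are oxygen-free, so every generated model grows anaerobically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .model_io import (
    BinaryProfileMatrix,
    MetabolicModel,
    Metabolite,
    ModelCollection,
    Reaction,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCommunity",
    "simulate_tree",
    "evolve_profiles",
    "assemble_models",
    "label_taxa",
    "generate_community",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the community generator.

    ``birth_rate`` is in speciations per lineage per unit time; gain/loss
    rates are per unit branch length.  The default birth rate of 5 puts the
    expected root-to-tip depth near one for 100 organisms, i.e. on the order
    of one gain/loss event per feature per lineage at unit rates — deep
    enough for repertoire divergence without saturating every pair.
    """

    n_organisms: int = 100
    birth_rate: float = 5.0
    n_features: int = 300
    gain_rate: float = 1.0
    loss_rate: float = 1.0
    n_nutrients: int = 15
    p_alternative_route: float = 0.5
    n_classes: int = 5
    n_genera: int = 10
    noise_sd: float = 0.1  # log10 units, used by direct-regression fixtures
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_organisms < 2 or self.n_features < 2 or self.n_nutrients < 2:
            raise ValueError("all counts must be >= 2")
        if min(self.birth_rate, self.gain_rate, self.loss_rate) <= 0:
            raise ValueError("rates must be positive")
        if not 0 <= self.p_alternative_route <= 1:
            raise ValueError("p_alternative_route must be in [0, 1]")
        if not 1 <= self.n_classes <= self.n_genera <= self.n_organisms:
            raise ValueError("need 1 <= n_classes <= n_genera <= n_organisms")


@dataclass
class SyntheticCommunity:
    tree: dendropy.Tree
    models: ModelCollection
    truth_essential: dict[str, set[str]]
    taxonomy: dict[str, dict[str, str]]
    profiles: BinaryProfileMatrix  # the evolved repertoire traits
    config: SimulationConfig = field(default_factory=SimulationConfig)


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(config: SimulationConfig, rng: np.random.Generator | None = None) -> dendropy.Tree:
    """Pure-birth tree with ``n_organisms`` leaves, all extant at the same time.

    Starts from a single lineage; while k lineages are alive the next
    speciation arrives after an Exp(birth_rate * k) waiting time and splits a
    uniformly chosen lineage.  Leaves are named org_0001... in a deterministic
    traversal order, so the Newick string is a pure function of the seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n, b = config.n_organisms, config.birth_rate

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.is_rooted = True
    root = tree.seed_node
    root.birth_time = 0.0
    active = [root]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / (b * k))
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        parent.edge.length = (
            t - parent.birth_time if parent is not root else None
        )
        parent.split_time = t
        for _ in range(2):
            child = parent.new_child()
            child.birth_time = t
            active.append(child)
    # one more waiting time so terminal branches have positive length
    t += rng.exponential(1.0 / (b * n))
    width = max(4, len(str(n)))
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.edge.length = t - leaf.birth_time
        leaf.taxon = taxa.new_taxon(label=f"org_{i + 1:0{width}d}")
    # internal edges of nodes that never split again cannot occur (pure birth
    # runs until n leaves), but the root's own edge stays length-less
    root.edge.length = None
    return tree


def expected_yule_depth(config: SimulationConfig) -> float:
    """Analytic expected root-to-tip depth of the simulated tree.

    The root is created at the first split; depth accumulates the waiting
    times while 2..n-1 lineages are alive plus the terminal stretch at n.
    """
    n, b = config.n_organisms, config.birth_rate
    return sum(1.0 / (b * k) for k in range(2, n + 1))


# ---------------------------------------------------------------------------
# gain/loss evolution

def _transition_probs(t: float, lam: float, mu: float) -> tuple[float, float]:
    """(P(0->1), P(1->0)) over a branch of length t for gain rate lam, loss mu."""
    r = lam + mu
    decay = 1.0 - math.exp(-r * t)
    return (lam / r) * decay, (mu / r) * decay


def evolve_profiles(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_features: int | None = None,
    gain_rate: float | None = None,
    loss_rate: float | None = None,
    feature_prefix: str = "feat",
) -> BinaryProfileMatrix:
    """Evolve independent binary features along the tree.

    Each feature follows a two-state Markov chain: over a branch of length t,
    P(0->1) = (lam/(lam+mu))(1 - e^-(lam+mu)t) and
    P(1->0) = (mu/(lam+mu))(1 - e^-(lam+mu)t); the root state is stationary
    (present with probability lam/(lam+mu)).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    nf = n_features if n_features is not None else config.n_features
    lam = gain_rate if gain_rate is not None else config.gain_rate
    mu = loss_rate if loss_rate is not None else config.loss_rate
    pi1 = lam / (lam + mu)

    states: dict[int, np.ndarray] = {}
    tip_rows: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            state = (rng.random(nf) < pi1).astype(np.int8)
        else:
            parent = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            p01, p10 = _transition_probs(t, lam, mu)
            u = rng.random(nf)
            state = np.where(parent == 1, (u >= p10), (u < p01)).astype(np.int8)
        states[id(node)] = state
        if node.is_leaf():
            tip_rows[node.taxon.label] = state
    width = max(4, len(str(nf)))
    features = [f"{feature_prefix}_{j + 1:0{width}d}" for j in range(nf)]
    organisms = sorted(tip_rows)
    df = pd.DataFrame(
        np.vstack([tip_rows[o] for o in organisms]), index=organisms, columns=features
    )
    return BinaryProfileMatrix(df, feature_kind="reaction")


# ---------------------------------------------------------------------------
# model assembly

def _organism_model(
    organism_id: str,
    n_nutrients: int,
    alt_row: np.ndarray,
    feature_row: np.ndarray,
    feature_ids: list[str],
) -> tuple[MetabolicModel, set[str]]:
    mets: list[Metabolite] = []
    rxns: list[Reaction] = []
    kw = max(2, len(str(n_nutrients)))
    nut = lambda k: f"nut_{k + 1:0{kw}d}"

    for k in range(n_nutrients):
        mets += [
            Metabolite(id=f"{nut(k)}_e", compartment="extracellular", name=f"nutrient {k + 1}"),
            Metabolite(id=f"{nut(k)}_c", compartment="cytosol"),
            Metabolite(id=f"prec_{k + 1:0{kw}d}_c", compartment="cytosol",
                       name=f"biomass precursor {k + 1}"),
        ]
        rxns += [
            Reaction(
                id=f"EX_{nut(k)}",
                stoichiometry={f"{nut(k)}_e": -1.0},
                lower_bound=-1000.0,
                upper_bound=1000.0,
                is_exchange=True,
            ),
            Reaction(
                id=f"TR_{nut(k)}",
                stoichiometry={f"{nut(k)}_e": -1.0, f"{nut(k)}_c": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
            Reaction(
                id=f"PW_{nut(k)}",
                stoichiometry={f"{nut(k)}_c": -1.0, f"prec_{k + 1:0{kw}d}_c": 1.0},
                lower_bound=0.0,
                upper_bound=1000.0,
            ),
        ]
    essential: set[str] = set()
    for k in range(n_nutrients):
        partner = (k + 1) % n_nutrients
        if alt_row[k]:
            # the partner nutrient can substitute for nutrient k
            rxns.append(
                Reaction(
                    id=f"ALT_{nut(k)}",
                    stoichiometry={
                        f"{nut(partner)}_c": -1.0,
                        f"prec_{k + 1:0{kw}d}_c": 1.0,
                    },
                    lower_bound=0.0,
                    upper_bound=1000.0,
                )
            )
        else:
            essential.add(f"{nut(k)}_e")
    # repertoire features as flux-silent dead-end reactions: they shape the
    # reaction presence profile without touching growth
    for j, present in enumerate(feature_row):
        if present:
            fid = feature_ids[j]
            mets += [
                Metabolite(id=f"{fid}_a_c", compartment="cytosol"),
                Metabolite(id=f"{fid}_b_c", compartment="cytosol"),
            ]
            rxns.append(
                Reaction(
                    id=f"R_{fid}",
                    stoichiometry={f"{fid}_a_c": -1.0, f"{fid}_b_c": 1.0},
                    lower_bound=0.0,
                    upper_bound=1000.0,
                )
            )
    rxns.append(
        Reaction(
            id="BIOMASS",
            stoichiometry={f"prec_{k + 1:0{kw}d}_c": -1.0 for k in range(n_nutrients)},
            lower_bound=0.0,
            upper_bound=1000.0,
            is_biomass=True,
        )
    )
    model = MetabolicModel(
        organism_id=organism_id,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="BIOMASS",
    )
    return model, essential


def assemble_models(
    profiles: BinaryProfileMatrix,
    config: SimulationConfig,
    alt_profiles: BinaryProfileMatrix | None = None,
) -> tuple[ModelCollection, dict[str, set[str]]]:
    """Build one FBA-ready model per organism from pathway templates.

    Every organism imports ``n_nutrients`` external nutrients, each feeding
    one biomass precursor; where the organism carries the evolved
    alternative-route trait for nutrient k, the partner nutrient also feeds
    precursor k, making nutrient k dispensable.  ``alt_profiles`` supplies
    those traits (one column per nutrient); when omitted, the last
    ``n_nutrients`` repertoire features are used.  Returns the collection and
    the wiring-derived ground-truth essential nutrient sets.
    """
    nn = config.n_nutrients
    if alt_profiles is None:
        if nn > len(profiles.features):
            raise ValueError("n_nutrients exceeds the feature budget of the profiles")
        alt = profiles.data.iloc[:, -nn:].to_numpy()
    else:
        if list(alt_profiles.organisms) != list(profiles.organisms):
            raise ValueError("alt_profiles organisms differ from profiles organisms")
        if len(alt_profiles.features) != nn:
            raise ValueError(
                f"alt_profiles must have exactly {nn} columns, got {len(alt_profiles.features)}"
            )
        alt = alt_profiles.data.to_numpy()
    feature_ids = list(profiles.features)
    models, truth = [], {}
    for i, org in enumerate(profiles.organisms):
        model, essential = _organism_model(
            org, nn, alt[i], profiles.data.iloc[i].to_numpy(), feature_ids
        )
        models.append(model)
        truth[org] = essential
    return ModelCollection(models), truth


# ---------------------------------------------------------------------------
# taxonomy labels

def _clades_at_count(tree: dendropy.Tree, count: int) -> list[list[str]]:
    """Cut the (ultrametric) tree where exactly ``count`` lineages coexist."""
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if count == 1:
        return [sorted(leaves)]
    if count == len(leaves):
        return [[l] for l in sorted(leaves)]
    depth: dict[int, float] = {}
    split_depths = []
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else depth[id(node.parent_node)] + (node.edge.length or 0.0)
        depth[id(node)] = d
        if not node.is_leaf():
            split_depths.append(d)
    split_depths.sort()
    if count - 1 >= len(split_depths) + 1:
        raise ValueError(f"cannot cut tree into {count} clades: only {len(split_depths)} splits")
    # after the (count-1)-th split (root included) exactly `count` lineages exist
    lo = split_depths[count - 2] if count >= 2 else 0.0
    hi = split_depths[count - 1] if count - 1 < len(split_depths) else None
    if hi is not None and not hi > lo:
        raise ValueError(f"cannot cut tree into exactly {count} clades: tied split depths")
    cut = lo + (hi - lo) / 2.0 if hi is not None else lo + 1e-9
    clades = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        start = depth[id(node.parent_node)]
        end = depth[id(node)]
        if start <= cut < end:
            clades.append(sorted(l.taxon.label for l in node.leaf_iter()))
    covered = sorted(l for c in clades for l in c)
    if len(clades) != count or covered != sorted(leaves):
        raise ValueError(
            f"cut produced {len(clades)} clades instead of {count} "
            "(tree may not be ultrametric)"
        )
    return sorted(clades, key=lambda c: c[0])


def label_taxa(tree: dendropy.Tree, n_class: int, n_genus: int) -> dict[str, dict[str, str]]:
    """Two nested monophyletic label sets from depth cuts of the tree.

    Shallower cut -> ``n_class`` class-like clades, deeper cut -> ``n_genus``
    genus-like clades; genera nest within classes by construction.
    """
    n_leaves = sum(1 for _ in tree.leaf_node_iter())
    if not 1 <= n_class <= n_genus <= n_leaves:
        raise ValueError("need 1 <= n_class <= n_genus <= n_leaves")
    class_clades = _clades_at_count(tree, n_class)
    genus_clades = _clades_at_count(tree, n_genus)
    cw, gw = max(2, len(str(n_class))), max(2, len(str(n_genus)))
    taxonomy: dict[str, dict[str, str]] = {}
    for i, clade in enumerate(class_clades):
        for leaf in clade:
            taxonomy[leaf] = {"class": f"class_{i + 1:0{cw}d}"}
    for i, clade in enumerate(genus_clades):
        for leaf in clade:
            taxonomy[leaf]["genus"] = f"genus_{i + 1:0{gw}d}"
    return taxonomy


# ---------------------------------------------------------------------------
# orchestration

def generate_community(config: SimulationConfig | None = None) -> SyntheticCommunity:
    """Full synthetic community: tree, profiles, models, truth, taxonomy.

    The whole object is a pure function of the config (seed included).  The
    alternative-route traits evolve under the same gain/loss kinetics as the
    repertoire but with stationary presence ``p_alternative_route``, so the
    phenotype is phylogenetically structured too.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config, rng)
    profiles = evolve_profiles(tree, config, rng)
    p = min(max(config.p_alternative_route, 1e-6), 1 - 1e-6)
    total = config.gain_rate + config.loss_rate
    alt_profiles = evolve_profiles(
        tree,
        config,
        rng,
        n_features=config.n_nutrients,
        gain_rate=total * p,
        loss_rate=total * (1 - p),
        feature_prefix="altroute",
    )
    models, truth = assemble_models(profiles, config, alt_profiles)
    taxonomy = label_taxa(tree, config.n_classes, config.n_genera)
    for m in models:
        m.taxonomy = dict(taxonomy[m.organism_id])
    return SyntheticCommunity(
        tree=tree,
        models=models,
        truth_essential=truth,
        taxonomy=taxonomy,
        profiles=profiles,
        config=config,
    )
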