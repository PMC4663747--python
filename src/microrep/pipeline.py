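"""End-to-end orchestration: community -> FBA screen -> distances ->
ordination/clustering -> regressions, written as a diff-stable report bundle.

Every stage writes plain TSV/JSON through one float formatter (12 significant
digits) and carries the canonical sorted organism order, so re-running with
an identical config reproduces byte-identical files.  The run log records the
config hash, seeds, and library versions — never wall-clock time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import distances as dist_mod
from . import model_io, ordination, regression
from .fba import ScreenConfig, check_anaerobic_growth, essential_nutrients
from .model_io import BinaryProfileMatrix, ModelCollection, ValidationError
from .synthetic import SimulationConfig, generate_community

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.12g"


@dataclass
class PipelineConfig:
    mode: str = "synthetic"  # synthetic | provided
    outdir: str = "report"
    # provided-mode inputs
    models_dir: str | None = None
    tree_path: str | None = None
    taxonomy_path: str | None = None
    annotation_paths: list[str] = field(default_factory=list)
    # stage settings
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    n_axes: int = 2
    top_n_loadings: int = 200
    tsne_perplexity: float | None = None
    tsne_seed: int = 42
    cluster_k: int | None = None
    contrast: tuple[int, int] | None = (1, 2)
    contrast_hi: float = 0.9
    contrast_lo: float = 0.1
    window_fraction: float = 0.05
    oxygen_metabolite: str = "o2_e"

    def config_hash(self) -> str:
        doc = {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in vars(self).items()
            if k != "outdir"  # the output location is not part of the analysis
        }
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML (or JSON) pipeline config; unknown keys are rejected."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    sim = SimulationConfig(**doc.pop("simulation", {}))
    screen = ScreenConfig(**doc.pop("screen", {}))
    contrast = doc.pop("contrast", (1, 2))
    if contrast is not None:
        contrast = tuple(int(c) for c in contrast)
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValidationError([f"unknown config keys: {sorted(unknown)}"])
    return PipelineConfig(simulation=sim, screen=screen, contrast=contrast, **doc)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def _load_provided(cfg: PipelineConfig):
    for name, p in (("models_dir", cfg.models_dir), ("tree_path", cfg.tree_path)):
        if p is None or not Path(p).exists():
            raise ValidationError([f"provided mode: missing input {name} ({p})"])
    paths = sorted(Path(cfg.models_dir).glob("*.json"))
    if not paths:
        raise ValidationError([f"no model JSON files in {cfg.models_dir}"])
    collection = ModelCollection([model_io.read_model(p) for p in paths])
    tree = dist_mod.read_newick(cfg.tree_path)
    taxonomy: dict[str, dict[str, str]] = {}
    if cfg.taxonomy_path:
        tdf = pd.read_csv(cfg.taxonomy_path, sep="\t", dtype=str)
        for _, row in tdf.iterrows():
            taxonomy[row["organism_id"]] = {
                r: row[r] for r in tdf.columns if r != "organism_id" and pd.notna(row[r])
            }
    else:
        taxonomy = {m.organism_id: dict(m.taxonomy) for m in collection}
    return collection, tree, taxonomy, None


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle; returns a manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cfg.mode == "synthetic":
        community = generate_community(cfg.simulation)
        collection, tree, taxonomy = community.models, community.tree, community.taxonomy
        truth = community.truth_essential
    elif cfg.mode == "provided":
        collection, tree, taxonomy, truth = _load_provided(cfg)
    else:
        raise ValidationError([f"unknown pipeline mode {cfg.mode!r}"])

    # --- presence profiles -------------------------------------------------
    presence = model_io.build_presence_matrix(collection)
    model_io.write_presence_tsv(presence, outdir / "presence_reactions.tsv")

    # --- FBA essentiality screen ------------------------------------------
    growth_rows, nutrient_union = {}, set()
    screened: dict[str, set[str]] = {}
    anaerobic = {}
    for model in collection:
        ess, gmap = essential_nutrients(model, cfg.screen)
        screened[model.organism_id] = ess
        growth_rows[model.organism_id] = gmap
        nutrient_union |= set(gmap)
        ok, g = check_anaerobic_growth(model, cfg.oxygen_metabolite, cfg.screen)
        anaerobic[model.organism_id] = {"anaerobic_capable": ok, "growth_rate": g}
    nutrients = sorted(nutrient_union)
    ess_df = pd.DataFrame(
        [[1 if n in screened[o] else 0 for n in nutrients] for o in collection.organism_ids],
        index=collection.organism_ids,
        columns=nutrients,
        dtype="int8",
    )
    ess_df.index.name = "organism_id"
    _write_tsv(ess_df, outdir / "essential_nutrients.tsv")
    growth_df = pd.DataFrame(growth_rows).T.reindex(collection.organism_ids)[nutrients]
    growth_df.index.name = "organism_id"
    _write_tsv(growth_df, outdir / "growth_screen.tsv")
    ess_profiles = BinaryProfileMatrix(ess_df, feature_kind="essential_nutrient")

    truth_discordance = None
    if truth is not None:
        truth_discordance = sum(
            len(screened[o] ^ truth[o]) for o in collection.organism_ids
        )

    # --- distances ---------------------------------------------------------
    d_metabolic = dist_mod.jaccard_distance(presence)
    d_phenotypic = dist_mod.jaccard_distance(ess_profiles)
    d_phylo = dist_mod.cophenetic_distance(tree)
    (d_metabolic, d_phylo, d_phenotypic), (presence, ess_profiles) = (
        dist_mod.align_organisms([d_metabolic, d_phylo, d_phenotypic], [presence, ess_profiles])
    )
    dist_mod.write_distance_tsv(d_metabolic, outdir / "dist_metabolic.tsv")
    dist_mod.write_distance_tsv(d_phenotypic, outdir / "dist_phenotypic.tsv")
    dist_mod.write_distance_tsv(d_phylo, outdir / "dist_phylogenetic.tsv")
    annotation_dists = {}
    for p in cfg.annotation_paths:
        try:
            prof = model_io.read_presence_tsv(p, feature_kind="annotation")
            (dm,), _ = dist_mod.align_organisms(
                [dist_mod.jaccard_distance(prof)]
            )
            annotation_dists[Path(p).stem] = dm
            dist_mod.write_distance_tsv(dm, outdir / f"dist_annotation_{Path(p).stem}.tsv")
        except (ValidationError, FileNotFoundError) as exc:
            logger.warning("skipping annotation matrix %s: %s", p, exc)

    # --- ordination + clustering ------------------------------------------
    ordn = ordination.pcoa(d_metabolic, n_axes=cfg.n_axes)
    _write_tsv(ordn.to_frame().rename_axis("organism_id"), outdir / "pcoa_coordinates.tsv")
    eig = pd.DataFrame(
        {
            "eigenvalue": ordn.eigenvalues,
            "explained_fraction": ordn.explained_fraction,
        },
        index=[f"PCo{i + 1}" for i in range(len(ordn.eigenvalues))],
    ).rename_axis("axis")
    _write_tsv(eig, outdir / "pcoa_eigenvalues.tsv")
    top_n = min(cfg.top_n_loadings, len(presence.features))
    loadings = ordination.feature_loadings(presence, ordn, top_n=top_n)
    _write_tsv(loadings, outdir / "pcoa_loadings.tsv")

    emb = ordination.tsne_embed(d_metabolic, cfg.tsne_perplexity, seed=cfg.tsne_seed)
    _write_tsv(emb.to_frame().rename_axis("organism_id"), outdir / "tsne_coordinates.tsv")

    k = cfg.cluster_k or max(2, len({t.get("class") for t in taxonomy.values()} - {None}) or 2)
    clusters = ordination.hcluster(d_metabolic, k=k)
    cl_df = pd.DataFrame(
        {"cluster": [clusters.labels[o] for o in d_metabolic.organisms]},
        index=d_metabolic.organisms,
    ).rename_axis("organism_id")
    _write_tsv(cl_df, outdir / "clusters.tsv")
    if cfg.contrast is not None:
        a, b = cfg.contrast
        contrast = ordination.subtype_contrast(
            presence, clusters, a, b, hi=cfg.contrast_hi, lo=cfg.contrast_lo
        )
        _write_tsv(contrast, outdir / "subtype_contrast.tsv")

    # --- regressions -------------------------------------------------------
    pairs = regression.pair_table(d_metabolic, d_phylo, d_phenotypic)
    _write_tsv(pairs.table, outdir / "pair_table.tsv", index=False)
    subsets = []
    for rank in ("class", "genus"):
        labels = sorted({t[rank] for t in taxonomy.values() if rank in t})
        for label in labels:
            if sum(1 for t in taxonomy.values() if t.get(rank) == label) >= 3:
                subsets.append((rank, label))
    summary = regression.fit_summary_table(taxonomy, pairs, subsets)
    _write_tsv(summary, outdir / "fit_summary.tsv", index=False)
    fits = {}
    for kind, fit_fn in (("exponential", regression.fit_exponential), ("linear", regression.fit_linear)):
        try:
            fits[kind] = fit_fn(pairs).to_dict()
        except ValueError as exc:
            fits[kind] = {"error": str(exc)}
    (outdir / "fits.json").write_text(json.dumps(fits, indent=2, sort_keys=True) + "\n")
    for resp, fname in (("y", "moving_average_phylo.tsv"), ("z", "moving_average_nutrient.tsv")):
        curve = regression.moving_average(pairs, response=resp, window_fraction=cfg.window_fraction)
        _write_tsv(curve.points, outdir / fname, index=False)
    means = pd.concat(
        [regression.within_taxon_means(taxonomy, pairs, r) for r in ("class", "genus")],
        ignore_index=True,
    )
    _write_tsv(means, outdir / "within_taxon_means.tsv", index=False)

    # --- run log -----------------------------------------------------------
    import scipy
    import sklearn

    manifest = {
        "config_hash": cfg.config_hash(),
        "mode": cfg.mode,
        "n_organisms": len(collection),
        "n_reactions_union": len(presence.features),
        "n_pairs": pairs.n_pairs,
        "seeds": {"simulation": cfg.simulation.seed, "tsne": cfg.tsne_seed},
        "essentiality_truth_discordance": truth_discordance,
        "anaerobic_capable_fraction": float(
            np.mean([a["anaerobic_capable"] for a in anaerobic.values()])
        ),
        "versions": {
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    (outdir / "run_log.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def write_community(community, outdir: str | Path) -> None:
    """Materialise a synthetic community as files (models/, tree, tables)."""
    outdir = Path(outdir)
    (outdir / "models").mkdir(parents=True, exist_ok=True)
    for m in community.models:
        model_io.write_model(m, outdir / "models" / f"{m.organism_id}.json")
    (outdir / "tree.newick").write_text(
        community.tree.as_string(schema="newick", suppress_rooting=True)
    )
    tax_rows = [
        {"organism_id": o, **ranks} for o, ranks in sorted(community.taxonomy.items())
    ]
    pd.DataFrame(tax_rows).to_csv(outdir / "taxonomy.tsv", sep="\t", index=False)
    truth_rows = [
        {"organism_id": o, "essential_nutrients": ",".join(sorted(s))}
        for o, s in sorted(community.truth_essential.items())
    ]
    pd.DataFrame(truth_rows).to_csv(outdir / "truth_essential.tsv", sep="\t", index=False)
    model_io.write_presence_tsv(community.profiles, outdir / "profiles.tsv")
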