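"""Cross-distance regressions linking repertoire, phylogeny, and phenotype.

For every unordered organism pair the analysis collects the metabolic
distance x (Jaccard on reaction presence), the phylogenetic distance y
(cophenetic), and the phenotypic distance z (Jaccard on essential-nutrient
sets).  Two models are fitted:

* exponential, y = 10^(alpha + beta * x), estimated as an ordinary
  least-squares regression of log10(y) on x (semi-log transform), reported
  with the Spearman rank correlation of (x, y);
* linear, z = alpha + beta * x, reported with the Pearson correlation.

Fits can be restricted to taxon subsets (per class or genus), and a
moving-average curve of the response against x is provided as the standard
visual diagnostic of the trend.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceMatrix
from .model_io import ValidationError

__all__ = [
    "PairedDistanceSet",
    "RegressionFit",
    "MovingAverageCurve",
    "pair_table",
    "fit_exponential",
    "fit_linear",
    "taxon_subset",
    "fit_summary_table",
    "moving_average",
    "within_taxon_means",
]


@dataclass
class PairedDistanceSet:
    """One row per unordered organism pair with x/y/z distances."""

    table: pd.DataFrame  # columns: org_i, org_j, x_metabolic, y_phylo, z_nutrient

    @property
    def n_pairs(self) -> int:
        return len(self.table)

    @property
    def x(self) -> np.ndarray:
        return self.table["x_metabolic"].to_numpy()

    @property
    def y(self) -> np.ndarray:
        return self.table["y_phylo"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.table["z_nutrient"].to_numpy()


@dataclass
class RegressionFit:
    model_kind: str        # exponential | linear
    alpha: float
    beta: float
    correlation_kind: str  # spearman for exponential, pearson for linear
    correlation: float
    r_squared: float
    rmse: float
    n_used: int
    n_pairs: int
    subset_label: str = "All taxa"

    def to_dict(self) -> dict:
        return {
            "model_kind": self.model_kind,
            "alpha": self.alpha,
            "beta": self.beta,
            "correlation_kind": self.correlation_kind,
            "correlation": self.correlation,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n_used": self.n_used,
            "n_pairs": self.n_pairs,
            "subset_label": self.subset_label,
        }


@dataclass
class MovingAverageCurve:
    window_fraction: float
    points: pd.DataFrame  # columns: x_center, mean_response


def pair_table(
    metabolic: DistanceMatrix,
    phylogenetic: DistanceMatrix | None = None,
    phenotypic: DistanceMatrix | None = None,
) -> PairedDistanceSet:
    """All unordered pairs (i < j in canonical organism order) with distances.

    All supplied matrices must already be aligned on the same organism order
    (see :func:`microrep.distances.align_organisms`); missing matrices yield
    NaN columns.
    """
    orgs = list(metabolic.organisms)
    if len(orgs) < 2:
        raise ValidationError(["pair table requires >= 2 organisms"])
    for other, name in ((phylogenetic, "phylogenetic"), (phenotypic, "phenotypic")):
        if other is not None and list(other.organisms) != orgs:
            raise ValidationError([f"{name} matrix not aligned with metabolic matrix"])
    n = len(orgs)
    iu, ju = np.triu_indices(n, k=1)
    table = pd.DataFrame(
        {
            "org_i": [orgs[i] for i in iu],
            "org_j": [orgs[j] for j in ju],
            "x_metabolic": metabolic.values[iu, ju],
            "y_phylo": phylogenetic.values[iu, ju] if phylogenetic is not None else np.nan,
            "z_nutrient": phenotypic.values[iu, ju] if phenotypic is not None else np.nan,
        }
    )
    return PairedDistanceSet(table)


def fit_exponential(pairs: PairedDistanceSet, subset_label: str = "All taxa") -> RegressionFit:
    """Fit y = 10^(alpha + beta x) by OLS of log10(y) on x.

    Pairs with y <= 0 (identical leaves) cannot enter the semi-log fit and
    are excluded; they remain counted in ``n_pairs``.  R^2 and RMSE refer to
    the log10 scale; the association measure is the Spearman rank correlation
    of (x, y) over all pairs, which is invariant to the monotone transform.
    """
    x_all, y_all = pairs.x, pairs.y
    ok = y_all > 0
    x, y = x_all[ok], y_all[ok]
    if x.size < 3:
        raise ValueError("exponential fit needs >= 3 pairs with positive phylogenetic distance")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: zero variance in metabolic distance")
    logy = np.log10(y)
    res = stats.linregress(x, logy)
    pred = res.intercept + res.slope * x
    resid = logy - pred
    ss_tot = float(np.sum((logy - logy.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    if np.ptp(y_all) == 0:
        rho = 0.0  # constant response carries no rank association
    else:
        rho = float(stats.spearmanr(x_all, y_all).statistic)
    return RegressionFit(
        model_kind="exponential",
        alpha=float(res.intercept),
        beta=float(res.slope),
        correlation_kind="spearman",
        correlation=rho,
        r_squared=r2,
        rmse=rmse,
        n_used=int(x.size),
        n_pairs=pairs.n_pairs,
        subset_label=subset_label,
    )


def fit_linear(pairs: PairedDistanceSet, subset_label: str = "All taxa") -> RegressionFit:
    """Fit z = alpha + beta x by OLS, with Pearson correlation and z-scale RMSE."""
    x, z = pairs.x, pairs.z
    if x.size < 3:
        raise ValueError("linear fit needs >= 3 pairs")
    if np.ptp(x) == 0:
        raise ValueError("degenerate data: zero variance in metabolic distance")
    res = stats.linregress(x, z)
    pred = res.intercept + res.slope * x
    resid = z - pred
    ss_tot = float(np.sum((z - z.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    rmse = float(np.sqrt(np.mean(resid**2)))
    pearson = float(res.rvalue) if np.ptp(z) > 0 else 0.0
    return RegressionFit(
        model_kind="linear",
        alpha=float(res.intercept),
        beta=float(res.slope),
        correlation_kind="pearson",
        correlation=pearson,
        r_squared=r2,
        rmse=rmse,
        n_used=int(x.size),
        n_pairs=pairs.n_pairs,
        subset_label=subset_label,
    )


def taxon_subset(
    taxonomy: dict[str, dict[str, str]],
    pairs: PairedDistanceSet,
    rank: str,
    label: str,
) -> PairedDistanceSet:
    """Restrict the pair table to organisms carrying ``label`` at ``rank``."""
    members = {o for o, ranks in taxonomy.items() if ranks.get(rank) == label}
    if len(members) < 3:
        raise ValueError(
            f"subset {rank}:{label} has {len(members)} members; need >= 3 for regression"
        )
    t = pairs.table
    keep = t["org_i"].isin(members) & t["org_j"].isin(members)
    return PairedDistanceSet(t[keep].reset_index(drop=True))


def fit_summary_table(
    taxonomy: dict[str, dict[str, str]],
    pairs: PairedDistanceSet,
    subsets: list[tuple[str, str]] | None = None,
    strong_threshold: float = 0.5,
) -> pd.DataFrame:
    """Both fits for the full pair set and each (rank, label) subset.

    One row per subset with the Spearman correlation / R^2 / RMSE of the
    exponential fit and the Pearson correlation / R^2 / RMSE of the linear
    fit; associations above ``strong_threshold`` are flagged.  Subsets whose
    fit fails (too small, degenerate) get an ``error`` marker instead of a
    crash.
    """
    subsets = subsets or []
    rows = []
    for rank, label, subset_pairs in [("all", "All taxa", pairs)] + [
        (rank, label, None) for rank, label in subsets
    ]:
        row: dict = {"rank": rank, "label": label, "error": ""}
        try:
            sp = subset_pairs if subset_pairs is not None else taxon_subset(
                taxonomy, pairs, rank, label
            )
            row["n_organisms"] = len(
                set(sp.table["org_i"]).union(sp.table["org_j"])
            )
            row["n_pairs"] = sp.n_pairs
            ef = fit_exponential(sp, subset_label=f"{rank}:{label}")
            lf = fit_linear(sp, subset_label=f"{rank}:{label}")
            row.update(
                spearman=ef.correlation,
                exp_r2=ef.r_squared,
                exp_rmse=ef.rmse,
                exp_alpha=ef.alpha,
                exp_beta=ef.beta,
                pearson=lf.correlation,
                lin_r2=lf.r_squared,
                lin_rmse=lf.rmse,
                lin_alpha=lf.alpha,
                lin_beta=lf.beta,
                spearman_strong=ef.correlation > strong_threshold,
                pearson_strong=lf.correlation > strong_threshold,
            )
        except (ValueError, ValidationError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)


def moving_average(
    pairs: PairedDistanceSet,
    response: str = "y",
    window_fraction: float = 0.05,
) -> MovingAverageCurve:
    """Sliding mean of the response over pairs sorted by metabolic distance.

    Window size is ceil(window_fraction * n_pairs) points, advancing one point
    at a time; each output x is the mean x within the window.
    """
    if response not in ("y", "z"):
        raise ValueError("response must be 'y' or 'z'")
    if not 0 < window_fraction <= 1:
        raise ValueError("window_fraction must be in (0, 1]")
    x = pairs.x
    r = pairs.y if response == "y" else pairs.z
    if x.size == 0:
        raise ValueError("empty pair set")
    order = np.argsort(x, kind="mergesort")
    x, r = x[order], r[order]
    w = int(np.ceil(window_fraction * x.size))
    centers, means = [], []
    for i in range(x.size - w + 1):
        centers.append(float(x[i : i + w].mean()))
        means.append(float(r[i : i + w].mean()))
    return MovingAverageCurve(
        window_fraction=window_fraction,
        points=pd.DataFrame({"x_center": centers, "mean_response": means}),
    )


def within_taxon_means(
    taxonomy: dict[str, dict[str, str]],
    pairs: PairedDistanceSet,
    rank: str,
) -> pd.DataFrame:
    """Mean within-taxon x/y/z distance per label at the given rank."""
    t = pairs.table
    label_i = t["org_i"].map(lambda o: taxonomy.get(o, {}).get(rank))
    label_j = t["org_j"].map(lambda o: taxonomy.get(o, {}).get(rank))
    within = t[(label_i == label_j) & label_i.notna()].copy()
    within["label"] = label_i[within.index]
    out = (
        within.groupby("label")[["x_metabolic", "y_phylo", "z_nutrient"]]
        .mean()
        .reset_index()
    )
    out.insert(0, "rank", rank)
    return out
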