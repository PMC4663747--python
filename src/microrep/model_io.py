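"""Metabolic model schema, JSON (de)serialisation, validation, and presence matrices.

A :class:`MetabolicModel` is the minimal structure needed for flux balance
analysis and repertoire comparison: metabolites in two compartments
(cytosol / extracellular), reactions given by sparse stoichiometry with flux
bounds, a single biomass reaction, and exchange reactions that move one
extracellular metabolite across the system boundary.

Sign conventions
----------------
Stoichiometric coefficients are negative for consumed and positive for
produced metabolites.  An exchange reaction is written ``1 M_ext -> (nothing)``
so that positive flux is secretion and negative flux is uptake; the growth
medium therefore acts on exchange *lower* bounds.

Files are written in a canonical JSON layout (sorted keys, reactions and
metabolites sorted by id) so that semantically equal models serialise to
byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ModelCollection",
    "BinaryProfileMatrix",
    "ValidationError",
    "read_model",
    "write_model",
    "validate_model",
    "build_presence_matrix",
    "read_presence_tsv",
    "write_presence_tsv",
]

COMPARTMENTS = ("cytosol", "extracellular")

# caps used when a file omits bounds: irreversible [0, 1000], reversible +/-1000
DEFAULT_UPPER = 1000.0
DEFAULT_LOWER = -1000.0


class ValidationError(ValueError):
    """Raised when a model (or model file) violates schema invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


@dataclass(frozen=True)
class Metabolite:
    id: str
    compartment: str
    name: str = ""


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = DEFAULT_LOWER
    upper_bound: float = DEFAULT_UPPER
    is_exchange: bool = False
    is_biomass: bool = False


@dataclass
class MetabolicModel:
    organism_id: str
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    biomass_reaction_id: str
    taxonomy: dict[str, str] = field(default_factory=dict)

    def metabolite_ids(self) -> set[str]:
        return {m.id for m in self.metabolites}

    def reaction_ids(self) -> set[str]:
        return {r.id for r in self.reactions}

    def get_reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(f"no reaction {rid!r} in model {self.organism_id!r}")

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    def exchanges_for_metabolite(self, metabolite_id: str) -> list[Reaction]:
        return [
            r
            for r in self.exchange_reactions()
            if next(iter(r.stoichiometry)) == metabolite_id
        ]

    def exchanged_metabolite_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.exchange_reactions():
            seen.setdefault(next(iter(r.stoichiometry)))
        return sorted(seen)


@dataclass
class ModelCollection:
    models: list[MetabolicModel]

    def __post_init__(self) -> None:
        ids = [m.organism_id for m in self.models]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError([f"duplicate organism ids: {dupes}"])
        self.models = sorted(self.models, key=lambda m: m.organism_id)

    @property
    def organism_ids(self) -> list[str]:
        return [m.organism_id for m in self.models]

    def __iter__(self):
        return iter(self.models)

    def __len__(self) -> int:
        return len(self.models)

    def __getitem__(self, organism_id: str) -> MetabolicModel:
        for m in self.models:
            if m.organism_id == organism_id:
                return m
        raise KeyError(organism_id)


@dataclass
class BinaryProfileMatrix:
    """Organisms x features presence/absence matrix.

    ``feature_kind`` records what the columns are: metabolic reactions,
    essential nutrients, or external annotations (COG/Pfam-style).
    """

    data: pd.DataFrame  # index = organisms, columns = features, values 0/1
    feature_kind: str = "reaction"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError(["duplicate organism ids in profile matrix"])
        if self.data.columns.has_duplicates:
            raise ValidationError(["duplicate feature ids in profile matrix"])
        vals = set(pd.unique(self.data.values.ravel()))
        if not vals <= {0, 1}:
            raise ValidationError([f"profile values outside {{0,1}}: {sorted(vals - {0, 1})[:5]}"])
        self.data = self.data.astype("int8")

    @property
    def organisms(self) -> list[str]:
        return list(self.data.index)

    @property
    def features(self) -> list[str]:
        return list(self.data.columns)

    def values(self):
        return self.data.to_numpy()

    def restrict(self, organisms: Iterable[str]) -> "BinaryProfileMatrix":
        return BinaryProfileMatrix(self.data.loc[list(organisms)], self.feature_kind)


# ---------------------------------------------------------------------------
# validation

def validate_model(model: MetabolicModel) -> list[str]:
    """Return a list of invariant violations (empty list = valid model)."""
    v: list[str] = []
    met_ids = [m.id for m in model.metabolites]
    if len(met_ids) != len(set(met_ids)):
        v.append("duplicate metabolite ids")
    for m in model.metabolites:
        if not m.id or any(c.isspace() for c in m.id):
            v.append(f"metabolite {m.id!r}: id empty or contains whitespace")
        if m.compartment not in COMPARTMENTS:
            v.append(f"metabolite {m.id!r}: unknown compartment {m.compartment!r}")
    met_index = {m.id: m for m in model.metabolites}

    rxn_ids = [r.id for r in model.reactions]
    if len(rxn_ids) != len(set(rxn_ids)):
        v.append("duplicate reaction ids")
    biomass = [r for r in model.reactions if r.is_biomass]
    if len(biomass) != 1:
        v.append(f"expected exactly one biomass reaction, found {len(biomass)}")
    elif biomass[0].id != model.biomass_reaction_id:
        v.append(
            f"biomass_reaction_id {model.biomass_reaction_id!r} does not match "
            f"flagged biomass reaction {biomass[0].id!r}"
        )
    if not any(r.is_exchange for r in model.reactions):
        v.append("model has no exchange reaction")

    for r in model.reactions:
        if not r.id or any(c.isspace() for c in r.id):
            v.append(f"reaction {r.id!r}: id empty or contains whitespace")
        if not (math.isfinite(r.lower_bound) and math.isfinite(r.upper_bound)):
            v.append(f"reaction {r.id!r}: non-finite bound")
        elif r.lower_bound > r.upper_bound:
            v.append(
                f"reaction {r.id!r}: lower_bound {r.lower_bound} > upper_bound {r.upper_bound}"
            )
        if not r.stoichiometry:
            v.append(f"reaction {r.id!r}: empty stoichiometry")
        for mid, coef in r.stoichiometry.items():
            if mid not in met_index:
                v.append(f"reaction {r.id!r}: unknown metabolite {mid!r}")
            if not math.isfinite(coef) or coef == 0:
                v.append(f"reaction {r.id!r}: invalid coefficient {coef} for {mid!r}")
        if r.is_exchange:
            if len(r.stoichiometry) != 1:
                v.append(
                    f"exchange reaction {r.id!r}: must reference exactly one metabolite, "
                    f"found {len(r.stoichiometry)}"
                )
            else:
                mid = next(iter(r.stoichiometry))
                met = met_index.get(mid)
                if met is not None and met.compartment != "extracellular":
                    v.append(
                        f"exchange reaction {r.id!r}: metabolite {mid!r} is not extracellular"
                    )
            if r.is_biomass:
                v.append(f"reaction {r.id!r}: cannot be both biomass and exchange")
    return v


def _require_valid(model: MetabolicModel) -> None:
    violations = validate_model(model)
    if violations:
        raise ValidationError(violations)


# ---------------------------------------------------------------------------
# JSON schema
#
# {
#   "organism_id": str,
#   "taxonomy": {rank: label, ...},
#   "biomass_reaction_id": str,
#   "metabolites": [{"id", "name", "compartment"}, ...]        (sorted by id)
#   "reactions":   [{"id", "stoichiometry": {met: coef, ...},
#                    "lower_bound", "upper_bound",
#                    "is_exchange", "is_biomass"}, ...]        (sorted by id)
# }

def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "organism_id": model.organism_id,
        "taxonomy": dict(sorted(model.taxonomy.items())),
        "biomass_reaction_id": model.biomass_reaction_id,
        "metabolites": [
            {"id": m.id, "name": m.name, "compartment": m.compartment}
            for m in sorted(model.metabolites, key=lambda m: m.id)
        ],
        "reactions": [
            {
                "id": r.id,
                "stoichiometry": dict(sorted(r.stoichiometry.items())),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "is_exchange": r.is_exchange,
                "is_biomass": r.is_biomass,
            }
            for r in sorted(model.reactions, key=lambda r: r.id)
        ],
    }


def _model_from_dict(doc: dict, source: str = "<dict>") -> MetabolicModel:
    try:
        mets = [
            Metabolite(
                id=str(m["id"]),
                name=str(m.get("name", "")),
                compartment=str(m["compartment"]),
            )
            for m in doc["metabolites"]
        ]
        rxns = [
            Reaction(
                id=str(r["id"]),
                stoichiometry={str(k): float(c) for k, c in r["stoichiometry"].items()},
                lower_bound=float(r.get("lower_bound", DEFAULT_LOWER)),
                upper_bound=float(r.get("upper_bound", DEFAULT_UPPER)),
                is_exchange=bool(r.get("is_exchange", False)),
                is_biomass=bool(r.get("is_biomass", False)),
            )
            for r in doc["reactions"]
        ]
        model = MetabolicModel(
            organism_id=str(doc["organism_id"]),
            taxonomy={str(k): str(v) for k, v in doc.get("taxonomy", {}).items()},
            metabolites=mets,
            reactions=rxns,
            biomass_reaction_id=str(doc["biomass_reaction_id"]),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError([f"{source}: malformed model document ({exc!r})"]) from exc
    _require_valid(model)
    return model


def read_model(path: str | Path, format: str = "json") -> MetabolicModel:
    """Read and validate one metabolic model from ``path``.

    ``format`` is ``"json"`` (the package schema) or ``"sbml_subset"`` (a
    read-only SBML import via cobra, limited to species / reactions / bounds /
    objective; everything else in the file is ignored).
    """
    path = Path(path)
    if format == "json":
        try:
            doc = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ValidationError([f"{path}: invalid JSON at line {exc.lineno}: {exc.msg}"])
        return _model_from_dict(doc, source=str(path))
    if format == "sbml_subset":
        return _read_sbml_subset(path)
    raise ValueError(f"unknown model format {format!r}")


def _read_sbml_subset(path: Path) -> MetabolicModel:
    try:
        import cobra.io
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML import requires the optional 'cobra' dependency") from exc
    cm = cobra.io.read_sbml_model(str(path))
    # first (outermost) compartment is treated as extracellular by convention
    comps = sorted(cm.compartments)
    if len(comps) > 2:
        raise ValidationError([f"{path}: more than two compartments: {comps}"])
    ext = "e" if "e" in comps else (comps[0] if len(comps) == 2 else None)
    mets = [
        Metabolite(
            id=m.id,
            name=m.name or "",
            compartment="extracellular" if m.compartment == ext else "cytosol",
        )
        for m in cm.metabolites
    ]
    objective_ids = {r.id for r in cm.reactions if r.objective_coefficient}
    if len(objective_ids) != 1:
        raise ValidationError([f"{path}: expected one objective reaction, got {sorted(objective_ids)}"])
    biomass_id = next(iter(objective_ids))
    rxns = [
        Reaction(
            id=r.id,
            stoichiometry={m.id: coef for m, coef in r.metabolites.items()},
            lower_bound=float(r.lower_bound),
            upper_bound=float(r.upper_bound),
            is_exchange=r in cm.exchanges,
            is_biomass=r.id == biomass_id,
        )
        for r in cm.reactions
    ]
    model = MetabolicModel(
        organism_id=cm.id or path.stem,
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass_id,
    )
    _require_valid(model)
    return model


def write_model(model: MetabolicModel, path: str | Path) -> None:
    """Write ``model`` as canonical JSON (diff-stable: sorted keys and records)."""
    _require_valid(model)
    path = Path(path)
    text = json.dumps(_model_to_dict(model), indent=2, sort_keys=True)
    path.write_text(text + "\n")


# ---------------------------------------------------------------------------
# presence matrices

def build_presence_matrix(collection: ModelCollection) -> BinaryProfileMatrix:
    """Organism x reaction presence over the union of all reaction ids.

    Entry (o, r) is 1 iff organism o's model contains reaction r.  Columns are
    the sorted union of reaction ids, so every column has at least one 1.
    """
    if len(collection) < 2:
        raise ValidationError(["presence matrix requires at least 2 models"])
    union = sorted(set().union(*(m.reaction_ids() for m in collection)))
    rows = []
    for m in collection:
        have = m.reaction_ids()
        rows.append([1 if rid in have else 0 for rid in union])
    df = pd.DataFrame(rows, index=collection.organism_ids, columns=union, dtype="int8")
    return BinaryProfileMatrix(df, feature_kind="reaction")


def write_presence_tsv(profiles: BinaryProfileMatrix, path: str | Path) -> None:
    df = profiles.data.copy()
    df.index.name = "organism_id"
    df.to_csv(path, sep="\t")


def read_presence_tsv(path: str | Path, feature_kind: str = "reaction") -> BinaryProfileMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return BinaryProfileMatrix(df, feature_kind=feature_kind)
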