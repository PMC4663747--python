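"""Flux balance analysis and the single-nutrient-removal essentiality screen.

The growth model is the standard linear program

    maximize    v_b            (flux through the biomass reaction)
    subject to  S . v = 0      (steady-state mass balance)
                v_min <= v <= v_max

solved with HiGHS through :func:`scipy.optimize.linprog`.  The biomass flux is
read as the growth rate in 1/h.

A :class:`Medium` only touches exchange reactions.  "Maximal uptake of u" is
implemented as an exchange lower bound of -u (uptake is negative flux under
the secretion-positive exchange convention of :mod:`microrep.model_io`).
Removing a metabolite from the medium forces both bounds of its exchange
reaction(s) to 0, which blocks uptake *and* secretion; a ``removal_mode``
switch restricts the closure to uptake only for sensitivity checks.

A nutrient is called essential when its individual removal from rich medium
(all exchanges open at the uptake limit, 10 mmol/gDW/h by default) drops the
optimal growth rate below the cutoff of 0.05 1/h, an estimate of microbial
doubling ability in the mammalian gut.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .model_io import MetabolicModel, validate_model, ValidationError

__all__ = [
    "Medium",
    "FluxResult",
    "ScreenConfig",
    "FbaError",
    "solve_fba",
    "rich_medium",
    "remove_metabolite",
    "essential_nutrients",
    "check_anaerobic_growth",
]


class FbaError(RuntimeError):
    pass


@dataclass(frozen=True)
class ScreenConfig:
    """Parameters of the growth simulation and essentiality screen."""

    uptake_limit: float = 10.0        # mmol/gDW/h, rich-medium max uptake per exchange
    essentiality_cutoff: float = 0.05  # 1/h, growth below this marks a nutrient essential
    feasibility_tolerance: float = 1e-9
    growth_atol: float = 1e-6          # absolute tolerance on growth comparisons
    removal_mode: str = "both"         # "both" closes uptake+secretion; "uptake" only uptake

    def __post_init__(self) -> None:
        if self.uptake_limit <= 0 or self.essentiality_cutoff <= 0:
            raise ValueError("uptake_limit and essentiality_cutoff must be positive")
        if self.feasibility_tolerance <= 0 or self.growth_atol <= 0:
            raise ValueError("tolerances must be positive")
        if self.removal_mode not in ("both", "uptake"):
            raise ValueError("removal_mode must be 'both' or 'uptake'")


@dataclass(frozen=True)
class Medium:
    """Exchange-reaction constraints defining a growth condition.

    ``max_uptake`` maps exchange reaction ids to the maximal uptake rate
    (nonnegative, mmol/gDW/h).  ``closed`` exchanges get both bounds forced to
    0; ``uptake_blocked`` exchanges only lose their uptake capability.
    """

    max_uptake: Mapping[str, float] = field(default_factory=dict)
    closed: frozenset[str] = frozenset()
    uptake_blocked: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        bad = [k for k, v in self.max_uptake.items() if v < 0]
        if bad:
            raise ValueError(f"negative max_uptake for {bad}")
        overlap = set(self.max_uptake) & set(self.closed)
        overlap = {k for k in overlap if self.max_uptake[k] > 0}
        if overlap:
            raise ValueError(f"exchanges both open and closed: {sorted(overlap)}")

    def validate_against(self, model: MetabolicModel) -> None:
        exch = {r.id for r in model.exchange_reactions()}
        unknown = (set(self.max_uptake) | set(self.closed) | set(self.uptake_blocked)) - exch
        if unknown:
            raise ValidationError(
                [f"medium references non-exchange reactions: {sorted(unknown)}"]
            )


@dataclass(frozen=True)
class FluxResult:
    status: str  # optimal | infeasible | unbounded
    growth_rate: float
    fluxes: dict[str, float]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


_LINPROG_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _effective_bounds(model: MetabolicModel, medium: Medium) -> list[tuple[float, float]]:
    bounds = []
    for r in model.reactions:
        lo, hi = r.lower_bound, r.upper_bound
        if r.is_exchange:
            if r.id in medium.closed:
                lo, hi = 0.0, 0.0
            else:
                if r.id in medium.max_uptake:
                    lo = -float(medium.max_uptake[r.id])
                if r.id in medium.uptake_blocked:
                    lo = max(lo, 0.0)
        bounds.append((lo, hi))
    return bounds


def solve_fba(model: MetabolicModel, medium: Medium | None = None) -> FluxResult:
    """Maximise biomass flux at steady state under the given medium."""
    violations = validate_model(model)
    if violations:
        raise ValidationError(violations)
    medium = medium or Medium()
    medium.validate_against(model)

    met_ids = [m.id for m in model.metabolites]
    met_pos = {mid: i for i, mid in enumerate(met_ids)}
    n_m, n_r = len(met_ids), len(model.reactions)
    S = np.zeros((n_m, n_r))
    for j, r in enumerate(model.reactions):
        for mid, coef in r.stoichiometry.items():
            S[met_pos[mid], j] = coef

    c = np.zeros(n_r)
    bio_idx = next(i for i, r in enumerate(model.reactions) if r.is_biomass)
    c[bio_idx] = -1.0  # linprog minimises

    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(n_m),
        bounds=_effective_bounds(model, medium),
        method="highs",
    )
    status = _LINPROG_STATUS.get(res.status, "numerical")
    if status == "optimal":
        fluxes = {r.id: float(res.x[j]) for j, r in enumerate(model.reactions)}
        return FluxResult(status="optimal", growth_rate=float(-res.fun), fluxes=fluxes)
    if status in ("infeasible", "unbounded"):
        return FluxResult(status=status, growth_rate=float("nan"), fluxes={})
    raise FbaError(f"LP solver failure ({status}): {res.message}")


def rich_medium(model: MetabolicModel, config: ScreenConfig | None = None) -> Medium:
    """All exchange reactions open at the uptake limit (rich-medium condition)."""
    config = config or ScreenConfig()
    exch = model.exchange_reactions()
    if not exch:
        raise ValidationError([f"model {model.organism_id!r} has no exchange reactions"])
    return Medium(max_uptake={r.id: config.uptake_limit for r in exch})


def remove_metabolite(
    medium: Medium,
    model: MetabolicModel,
    metabolite_id: str,
    mode: str = "both",
) -> Medium:
    """New medium with the metabolite absent (its exchanges closed).

    With ``mode="both"`` (default) both exchange bounds are forced to 0, which
    also blocks secretion of that metabolite; ``mode="uptake"`` zeroes only
    the uptake side.
    """
    exchanges = model.exchanges_for_metabolite(metabolite_id)
    if not exchanges:
        raise KeyError(
            f"metabolite {metabolite_id!r} has no exchange reaction in model "
            f"{model.organism_id!r}"
        )
    ids = {r.id for r in exchanges}
    if mode == "both":
        return replace(
            medium,
            max_uptake={k: v for k, v in medium.max_uptake.items() if k not in ids},
            closed=medium.closed | ids,
        )
    if mode == "uptake":
        return replace(
            medium,
            max_uptake={k: v for k, v in medium.max_uptake.items() if k not in ids},
            uptake_blocked=medium.uptake_blocked | ids,
        )
    raise ValueError("mode must be 'both' or 'uptake'")


def _screened_growth(result: FluxResult) -> float:
    # infeasible removal LPs count as zero growth
    if not result.optimal:
        return 0.0
    return max(result.growth_rate, 0.0)


def essential_nutrients(
    model: MetabolicModel, config: ScreenConfig | None = None
) -> tuple[set[str], dict[str, float]]:
    """Single-removal essentiality screen over all exchanged metabolites.

    Each exchanged metabolite is individually removed from the rich medium and
    growth re-optimised; metabolites whose removal leaves growth below the
    essentiality cutoff are returned as essential, together with the full
    metabolite -> growth-rate map of the screen.
    """
    config = config or ScreenConfig()
    base = rich_medium(model, config)
    baseline = solve_fba(model, base)
    if not baseline.optimal or baseline.growth_rate < config.essentiality_cutoff - config.growth_atol:
        raise FbaError(
            f"model {model.organism_id!r} does not grow on rich medium "
            f"(growth {baseline.growth_rate!r}); essentiality screen is meaningless"
        )
    growth_map: dict[str, float] = {}
    essential: set[str] = set()
    for mid in model.exchanged_metabolite_ids():
        reduced = remove_metabolite(base, model, mid, mode=config.removal_mode)
        g = _screened_growth(solve_fba(model, reduced))
        if abs(g) <= config.growth_atol:
            g = 0.0
        growth_map[mid] = g
        if g < config.essentiality_cutoff:
            essential.add(mid)
    return essential, growth_map


def check_anaerobic_growth(
    model: MetabolicModel,
    oxygen_metabolite_id: str = "o2_e",
    config: ScreenConfig | None = None,
) -> tuple[bool, float]:
    """Does the model still reach the growth cutoff with oxygen removed?

    A model without any oxygen exchange reaction is counted anaerobic-capable
    and evaluated on plain rich medium.
    """
    config = config or ScreenConfig()
    medium = rich_medium(model, config)
    if model.exchanges_for_metabolite(oxygen_metabolite_id):
        medium = remove_metabolite(medium, model, oxygen_metabolite_id, mode=config.removal_mode)
    g = _screened_growth(solve_fba(model, medium))
    return g >= config.essentiality_cutoff - config.growth_atol, g
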