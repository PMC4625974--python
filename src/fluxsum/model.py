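"""Stoichiometric model containers for constraint-based flux analysis.

The central object is :class:`MetabolicModel`, a plain in-memory container
holding the stoichiometric matrix S (implicitly, as per-reaction coefficient
maps), flux bounds and objective coefficients.  It deliberately knows nothing
about solvers; the LP/MILP layers consume it read-only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional


class ModelError(Exception):
    """Base class for model construction/IO failures."""


class ModelFormatError(ModelError):
    """A model file could not be parsed in the requested dialect."""


class ModelIntegrityError(ModelError):
    """Parsed model violates referential integrity (e.g. unknown metabolite)."""


class UnknownReactionError(KeyError, ModelError):
    """A reaction id was looked up that does not exist in the model."""


class UnknownMetaboliteError(KeyError, ModelError):
    """A metabolite id was looked up that does not exist in the model."""


class BoundaryMetaboliteError(ModelError):
    """Flux-sum quantities are undefined for boundary (unbalanced) species."""


class DegenerateMetaboliteError(ModelError):
    """Metabolite participates in no reaction; turnover machinery is undefined."""


@dataclass(frozen=True)
class Metabolite:
    """One chemical species.

    ``is_boundary`` marks exchange-side pseudo-species (SBML
    ``boundaryCondition`` or "_b"-suffixed ids).  Boundary species are not
    mass-balanced and are never flux-sum scan candidates.
    """

    id: str
    name: str = ""
    compartment: str = ""
    is_boundary: bool = False


@dataclass
class Reaction:
    """One reaction column of S: stoichiometry, flux bounds and objective weight.

    Bounds are in mmol/gDCW-hr; negative stoichiometric coefficients denote
    consumption.
    """

    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    objective_coefficient: float = 0.0
    name: str = ""

    def validate(self) -> None:
        if not self.stoichiometry:
            raise ModelIntegrityError(f"reaction '{self.id}' has empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelIntegrityError(
                f"reaction '{self.id}' has lower_bound {self.lower_bound} "
                f"> upper_bound {self.upper_bound}"
            )
        for met_id, coef in self.stoichiometry.items():
            if coef == 0 or not math.isfinite(coef):
                raise ModelIntegrityError(
                    f"reaction '{self.id}' has invalid coefficient {coef!r} "
                    f"for metabolite '{met_id}'"
                )


@dataclass
class MetabolicModel:
    """An ordered stoichiometric model: metabolites, reactions, biomass pointer."""

    metabolites: List[Metabolite] = field(default_factory=list)
    reactions: List[Reaction] = field(default_factory=list)
    biomass_reaction_id: Optional[str] = None
    annotations: Dict[str, str] = field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index()[met_id]
        except KeyError:
            raise UnknownMetaboliteError(met_id) from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index()[rxn_id]
        except KeyError:
            raise UnknownReactionError(rxn_id) from None

    def _met_index(self) -> Dict[str, Metabolite]:
        return {m.id: m for m in self.metabolites}

    def _rxn_index(self) -> Dict[str, Reaction]:
        return {r.id: r for r in self.reactions}

    # -- derived views -----------------------------------------------------
    @property
    def internal_metabolites(self) -> List[Metabolite]:
        """Mass-balanced species, i.e. the rows of the steady-state constraint."""
        return [m for m in self.metabolites if not m.is_boundary]

    @property
    def exchange_reaction_ids(self) -> List[str]:
        """Reactions touching exactly one metabolite (uptake/secretion)."""
        return [r.id for r in self.reactions if len(r.stoichiometry) == 1]

    def incident_reactions(self, met_id: str) -> List[Reaction]:
        """Reactions with a non-zero coefficient for ``met_id``."""
        self.metabolite(met_id)
        return [r for r in self.reactions if met_id in r.stoichiometry]

    def max_finite_bound(self) -> float:
        best = 0.0
        for r in self.reactions:
            for b in (r.lower_bound, r.upper_bound):
                if math.isfinite(b):
                    best = max(best, abs(b))
        return best

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelIntegrityError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for r in self.reactions:
            r.validate()
            for met_id in r.stoichiometry:
                if met_id not in known:
                    raise ModelIntegrityError(
                        f"reaction '{r.id}' references unknown metabolite '{met_id}'"
                    )
        if self.biomass_reaction_id is not None and self.biomass_reaction_id not in set(rxn_ids):
            raise ModelIntegrityError(
                f"biomass_reaction_id '{self.biomass_reaction_id}' names no reaction"
            )

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[
                Reaction(
                    id=r.id,
                    stoichiometry=dict(r.stoichiometry),
                    lower_bound=r.lower_bound,
                    upper_bound=r.upper_bound,
                    objective_coefficient=r.objective_coefficient,
                    name=r.name,
                )
                for r in self.reactions
            ],
            biomass_reaction_id=self.biomass_reaction_id,
            annotations=dict(self.annotations),
        )


def guess_biomass_reaction(model: MetabolicModel) -> Optional[str]:
    """Pick the biomass reaction as the one carrying a positive objective weight."""
    candidates = [r.id for r in model.reactions if r.objective_coefficient > 0]
    if len(candidates) == 1:
        return candidates[0]
    return None
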