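"""Model readers/writers: community JSON dialect and SBML Level 3 FBC.

The heavy lifting is delegated to cobrapy (JSON and SBML parsing/writing)
and python-libsbml (format pre-checks, ``boundaryCondition`` detection);
this module converts between cobra's containers and the package's own
:class:`~fluxsum.model.MetabolicModel`.

Conventions:

* Boundary species (SBML ``boundaryCondition`` or "_b"-suffixed ids) are
  stripped from reaction stoichiometries and kept only as flagged
  placeholder metabolites — the steady-state balance covers internal
  species only.
* SBML files must be Level 3 with the flux-bounds (fbc) extension; models
  encoding bounds in kinetic laws are rejected with a format error rather
  than guessed at.
* Saves are deterministic (sorted keys, stable float formatting), so
  re-serializing an unchanged model is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Optional, Set

from .model import (MetabolicModel, Metabolite, ModelFormatError,
                    ModelIntegrityError, Reaction, guess_biomass_reaction)

JSON = "json"
SBML = "sbml"


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".json":
        return JSON
    if suffix in (".xml", ".sbml"):
        return SBML
    raise ModelFormatError(
        f"cannot infer model format from suffix {suffix!r}; pass format=")


def _validate_json_integrity(path: Path) -> None:
    """Fail early, naming the offending element, on dangling references."""
    try:
        with open(path) as handle:
            doc = json.load(handle)
    except json.JSONDecodeError as err:
        raise ModelFormatError(f"{path}: not valid JSON: {err}") from err
    if not isinstance(doc, dict) or "reactions" not in doc or "metabolites" not in doc:
        raise ModelFormatError(
            f"{path}: missing 'metabolites'/'reactions' arrays; not a "
            f"community-dialect model file")
    declared = {m.get("id") for m in doc["metabolites"]}
    for rxn in doc["reactions"]:
        for met_id in rxn.get("metabolites", {}):
            if met_id not in declared:
                raise ModelIntegrityError(
                    f"reaction '{rxn.get('id')}' references unknown "
                    f"metabolite '{met_id}'")


def _sbml_precheck(path: Path) -> Set[str]:
    """Validate SBML L3+fbc, return ids of boundaryCondition species."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        first = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise ModelFormatError(
            f"{path}: SBML parse error: {first.getMessage().strip()}")
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise ModelFormatError(f"{path}: file contains no SBML model")
    if doc.getLevel() < 3 or sbml_model.getPlugin("fbc") is None:
        kinetic = any(sbml_model.getReaction(i).isSetKineticLaw()
                      for i in range(sbml_model.getNumReactions()))
        detail = ("flux bounds encoded in kinetic laws are not supported"
                  if kinetic else "no fbc flux-bounds package found")
        raise ModelFormatError(
            f"{path}: requires SBML Level 3 with the fbc extension; {detail}")
    return {sbml_model.getSpecies(i).getId()
            for i in range(sbml_model.getNumSpecies())
            if sbml_model.getSpecies(i).getBoundaryCondition()}


def _from_cobra(cobra_model, boundary_ids: Set[str]) -> MetabolicModel:
    def is_boundary(met) -> bool:
        return met.id in boundary_ids or met.id.endswith("_b")

    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "",
                   is_boundary=is_boundary(m))
        for m in cobra_model.metabolites
    ]
    boundary = {m.id for m in metabolites if m.is_boundary}
    reactions = []
    for r in cobra_model.reactions:
        stoich = {m.id: float(c) for m, c in r.metabolites.items()
                  if m.id not in boundary}
        if not stoich:
            # reaction touched only boundary species; nothing to balance
            continue
        reactions.append(Reaction(
            id=r.id, stoichiometry=stoich,
            lower_bound=float(r.lower_bound), upper_bound=float(r.upper_bound),
            objective_coefficient=float(r.objective_coefficient),
            name=r.name or ""))
    model = MetabolicModel(metabolites=metabolites, reactions=reactions,
                           annotations={"source_id": cobra_model.id or ""})
    model.biomass_reaction_id = guess_biomass_reaction(model)
    model.validate()
    return model


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model(model.annotations.get("source_id") or "model")
    mets = {m.id: cobra.Metabolite(m.id, name=m.name,
                                   compartment=m.compartment or "c")
            for m in model.metabolites}
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[mid]: coef for mid, coef in r.stoichiometry.items()})
    objective = {cm.reactions.get_by_id(r.id): r.objective_coefficient
                 for r in model.reactions if r.objective_coefficient != 0.0}
    if objective:
        cm.objective = sum(c * rxn.flux_expression for rxn, c in objective.items())
    return cm


def load_model(path, format: Optional[str] = None) -> MetabolicModel:
    """Load a model from the community JSON dialect or SBML L3-FBC.

    Exchange reactions need no special handling on load: they are recognised
    structurally (single-metabolite stoichiometry) by
    :attr:`MetabolicModel.exchange_reaction_ids`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt == JSON:
            _validate_json_integrity(path)
            from cobra.io import load_json_model
            try:
                cm = load_json_model(str(path))
            except Exception as err:  # malformed beyond the integrity pre-check
                raise ModelFormatError(f"{path}: {err}") from err
            return _from_cobra(cm, boundary_ids=set())
        if fmt == SBML:
            boundary_ids = _sbml_precheck(path)
            from cobra.io import read_sbml_model
            try:
                cm = read_sbml_model(str(path))
            except Exception as err:
                raise ModelFormatError(f"{path}: {err}") from err
            return _from_cobra(cm, boundary_ids=boundary_ids)
    raise ModelFormatError(f"unknown format {fmt!r}; expected 'json' or 'sbml'")


def save_model(model: MetabolicModel, path, format: Optional[str] = None) -> None:
    """Serialize a model; JSON output is byte-stable for identical input."""
    path = Path(path)
    fmt = format or _infer_format(path)
    model.validate()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cm = _to_cobra(model)
        if fmt == JSON:
            from cobra.io import save_json_model
            save_json_model(cm, str(path), sort=True, pretty=True)
        elif fmt == SBML:
            from cobra.io import write_sbml_model
            write_sbml_model(cm, str(path))
        else:
            raise ModelFormatError(
                f"unknown format {fmt!r}; expected 'json' or 'sbml'")
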