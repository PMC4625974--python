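"""Programmatic toy metabolic networks.

These networks are small enough that every flux-sum quantity has a closed-form
value, yet they retain the structural features the scan workflow exercises on
genome-scale models: a fixed substrate uptake, competing parallel pathways, a
biomass drain and exchange reactions.

``make_mixed_acid_fixture`` is a reduced anaerobic mixed-acid fermentation
network of *E. coli* (PEP branch point, pyruvate fates, acetyl-CoA fates, and
the reducing-equivalent bookkeeping that couples them).  All stoichiometric
coefficients are unity so analytic oracles stay exact; carbon counts are
therefore not literal, but every internal species is strictly mass-balanced.
"""

from __future__ import annotations

import numpy as np

from .model import MetabolicModel, Metabolite, Reaction

#: Default cap on internal/secretion fluxes in the toy networks, mmol/gDCW-hr.
#: Kept an order of magnitude below the default big-M of 1000 mmol/gDCW-hr.
TOY_FLUX_CAP = 100.0

#: Substrate uptake rate of the toy networks, mmol/gDCW-hr.
TOY_UPTAKE = 10.0


def _rxn(rid: str, stoich: dict, lb: float = 0.0, ub: float = TOY_FLUX_CAP,
         obj: float = 0.0, name: str = "") -> Reaction:
    return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                    objective_coefficient=obj, name=name)


def make_two_branch_fixture() -> MetabolicModel:
    """Two competing linear pathways fed by a fixed uptake.

    ::

            UPTAKE (=10)            EX_E  ("product")
                |              R3    |
                A ---R1---> B ---> E
                |
                +---R2---> C ---R4---> F ---> EX_F
                                       |
                                       +---> BIOMASS

    Biomass consumes F only, so maximum growth (10) routes all uptake through
    C; the E branch is idle at the wild-type optimum.  Attenuating the
    turnover of C to a fraction k of its wild-type value caps growth at 10*k
    and forces the remaining 10*(1-k) units through B into E.
    """
    mets = [Metabolite(i, compartment="c") for i in ("A", "B", "C", "E", "F")]
    rxns = [
        _rxn("UPTAKE", {"A": 1.0}, lb=TOY_UPTAKE, ub=TOY_UPTAKE),
        _rxn("R1", {"A": -1.0, "B": 1.0}),
        _rxn("R2", {"A": -1.0, "C": 1.0}),
        _rxn("R3", {"B": -1.0, "E": 1.0}),
        _rxn("R4", {"C": -1.0, "F": 1.0}),
        _rxn("EX_E", {"E": -1.0}),
        _rxn("EX_F", {"F": -1.0}),
        _rxn("BIOMASS", {"F": -1.0}, obj=1.0),
    ]
    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           biomass_reaction_id="BIOMASS",
                           annotations={"fixture": "two_branch"})
    model.validate()
    return model


def make_mixed_acid_fixture(with_pdc: bool = False) -> MetabolicModel:
    """Reduced anaerobic mixed-acid fermentation network.

    Glucose enters via the PEP-consuming phosphotransferase system (PTS) or
    an ATP-dependent kinase, glycolysis is lumped into one PEP-forming step,
    and the PEP node branches toward succinate (PPC/MDH/FUM/FRD) or pyruvate
    (PYK).  Pyruvate is drained by LDH, PFL and PDH; acetyl-CoA by the
    acetate (PTA/ACK) and ethanol (ACALD/ALCD) routes.  NADH/NAD, ATP/ADP and
    CoA are balanced inside the network; growth is modelled as an ATP drain.

    When ``with_pdc`` is set, a single extra reaction (pyruvate
    decarboxylase, pyr -> acald + co2) is present and nothing else differs.
    """
    met_ids = [
        "glc", "g6p", "pep", "pyr", "oaa", "mal", "fum", "succ",
        "lac", "for", "accoa", "actp", "ac", "acald", "etoh", "co2",
        "coa", "nad", "nadh", "adp", "atp",
    ]
    mets = [Metabolite(i, compartment="c") for i in met_ids]
    rxns = [
        # uptake and lumped glycolysis
        _rxn("EX_glc", {"glc": -1.0}, lb=-TOY_UPTAKE, ub=0.0, name="glucose exchange"),
        _rxn("PTS", {"glc": -1.0, "pep": -1.0, "g6p": 1.0, "pyr": 1.0},
             name="glucose phosphotransferase"),
        _rxn("GLK", {"glc": -1.0, "atp": -1.0, "g6p": 1.0, "adp": 1.0},
             name="glucokinase"),
        _rxn("EMP", {"g6p": -1.0, "adp": -1.0, "nad": -1.0,
                     "pep": 1.0, "atp": 1.0, "nadh": 1.0},
             name="lumped glycolysis"),
        # PEP branch point
        _rxn("PYK", {"pep": -1.0, "adp": -1.0, "pyr": 1.0, "atp": 1.0},
             name="pyruvate kinase"),
        _rxn("PPC", {"pep": -1.0, "co2": -1.0, "oaa": 1.0},
             name="PEP carboxylase"),
        _rxn("MDH", {"oaa": -1.0, "nadh": -1.0, "mal": 1.0, "nad": 1.0},
             name="malate dehydrogenase"),
        _rxn("FUM", {"mal": -1.0, "fum": 1.0}, name="fumarase"),
        _rxn("FRD", {"fum": -1.0, "nadh": -1.0, "succ": 1.0, "nad": 1.0},
             name="fumarate reductase"),
        # pyruvate fates
        _rxn("LDH", {"pyr": -1.0, "nadh": -1.0, "lac": 1.0, "nad": 1.0},
             name="lactate dehydrogenase"),
        _rxn("PFL", {"pyr": -1.0, "coa": -1.0, "accoa": 1.0, "for": 1.0},
             name="pyruvate formate lyase"),
        _rxn("PDH", {"pyr": -1.0, "coa": -1.0, "nad": -1.0,
                     "accoa": 1.0, "co2": 1.0, "nadh": 1.0},
             name="pyruvate dehydrogenase"),
        # acetyl-CoA fates
        _rxn("PTA", {"accoa": -1.0, "actp": 1.0, "coa": 1.0},
             name="phosphotransacetylase"),
        _rxn("ACK", {"actp": -1.0, "adp": -1.0, "ac": 1.0, "atp": 1.0},
             name="acetate kinase"),
        _rxn("ACALD", {"accoa": -1.0, "nadh": -1.0,
                       "acald": 1.0, "coa": 1.0, "nad": 1.0},
             name="acetaldehyde dehydrogenase"),
        _rxn("ALCD", {"acald": -1.0, "nadh": -1.0, "etoh": 1.0, "nad": 1.0},
             name="alcohol dehydrogenase"),
        # secretion
        _rxn("EX_succ", {"succ": -1.0}),
        _rxn("EX_etoh", {"etoh": -1.0}),
        _rxn("EX_ac", {"ac": -1.0}),
        _rxn("EX_for", {"for": -1.0}),
        _rxn("EX_lac", {"lac": -1.0}),
        _rxn("EX_co2", {"co2": -1.0}, lb=-TOY_FLUX_CAP, ub=TOY_FLUX_CAP),
        # growth as ATP drain
        _rxn("BIOMASS", {"atp": -1.0, "adp": 1.0}, obj=1.0, name="ATP drain"),
    ]
    if with_pdc:
        rxns.append(_rxn("PDC", {"pyr": -1.0, "acald": 1.0, "co2": 1.0},
                         name="pyruvate decarboxylase"))
    model = MetabolicModel(
        metabolites=mets, reactions=rxns, biomass_reaction_id="BIOMASS",
        annotations={"fixture": "mixed_acid_pdc" if with_pdc else "mixed_acid"})
    model.validate()
    return model


def make_random_irreversible_network(
    seed: int,
    max_reactions: int = 15,
) -> MetabolicModel:
    """Random all-irreversible toy network with a fixed uptake.

    Construction: a fixed uptake feeds metabolite ``M0``; a random set of
    irreversible unit-coefficient conversions (occasionally branching into
    two products) links metabolites; every metabolite receives a secretion
    exchange so the fixed uptake is always feasible.  The exchange of the
    last metabolite doubles as the growth proxy.  Because every flux is
    non-negative, the generation/consumption split of any metabolite is
    sign-forced, which makes these networks exact LP-checkable.
    """
    rng = np.random.default_rng(seed)
    n_internal = int(rng.integers(3, 7))
    met_ids = ["M0"]
    reactions = [
        _rxn("UPTAKE", {"M0": 1.0},
             lb=float(rng.integers(2, 9)), ub=float(rng.integers(2, 9)))
    ]
    # normalise uptake bounds into a fixed rate
    u = min(reactions[0].lower_bound, reactions[0].upper_bound)
    reactions[0].lower_bound = reactions[0].upper_bound = u

    for j in range(n_internal):
        # next conversion adds 1 reaction and up to 2 metabolites (each
        # metabolite later costs one exchange reaction)
        if len(reactions) + len(met_ids) + 3 > max_reactions:
            break
        sub = str(rng.choice(met_ids))
        products = []
        n_prod = 2 if rng.random() < 0.3 else 1
        for _ in range(n_prod):
            if rng.random() < 0.6 or len(met_ids) < 2:
                new_id = f"M{len(met_ids)}"
                met_ids.append(new_id)
                products.append(new_id)
            else:
                cand = [m for m in met_ids if m != sub and m not in products]
                if cand:
                    products.append(str(rng.choice(cand)))
                else:
                    new_id = f"M{len(met_ids)}"
                    met_ids.append(new_id)
                    products.append(new_id)
        stoich = {sub: -1.0}
        for p in products:
            stoich[p] = 1.0
        reactions.append(_rxn(f"R{j}", stoich))

    for m in met_ids:
        reactions.append(_rxn(f"EX_{m}", {m: -1.0}))
    biomass_id = f"EX_{met_ids[-1]}"
    for r in reactions:
        if r.id == biomass_id:
            r.objective_coefficient = 1.0

    model = MetabolicModel(
        metabolites=[Metabolite(m, compartment="c") for m in met_ids],
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        annotations={"fixture": f"random_irreversible_{seed}"},
    )
    model.validate()
    assert len(model.reactions) <= max_reactions
    return model


FIXTURES = {
    "two_branch": make_two_branch_fixture,
    "mixed_acid": lambda: make_mixed_acid_fixture(with_pdc=False),
    "mixed_acid_pdc": lambda: make_mixed_acid_fixture(with_pdc=True),
}
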