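# fluxsum — metabolite-centric strain-design target identification

`fluxsum` implements **flux-sum analysis (FSA)** for constraint-based
metabolic models: given a stoichiometric model, a biomass reaction and a
target exchange reaction, it identifies metabolites whose turnover
("flux-sum") attenuation or intensification *forces* increased production of
a desired compound — or decreased production of an undesired one — while
guaranteeing a stated growth level.  It is aimed at metabolic engineers who
want intervention candidates expressed as metabolites (which may implicate
several reactions at once) rather than single gene/reaction knockouts.

## The method

Flux balance analysis (FBA) finds a steady-state flux vector `v` maximizing
a cellular objective (usually growth) subject to mass balance and capacity
bounds:

```
max  Z = Σ_j c_j v_j
s.t. Σ_j S_ij v_j = 0          for every internal metabolite i
     α_j ≤ v_j ≤ β_j
```

The **flux-sum** of metabolite *i* is its turnover rate — half the sum of
the absolute rates of all reactions producing or consuming it:

```
Φ_i = 0.5 Σ_j |S_ij v_j|
```

(at steady state total generation equals total consumption, hence the ½).
To place Φ in constraints the signed rate is split into non-negative
generation/consumption components with big-M binary switches:

```
S_ij v_j = g⁺_ij − g⁻_ij ,   g⁺ ≤ I⁺ M ,  g⁻ ≤ I⁻ M ,  I⁺ + I⁻ = 1
Φ_i = 0.5 Σ_j (g⁺_ij + g⁻_ij)
```

The scan then proceeds in four steps for each metabolite *i*:

1. **Reference.** Solve FBA for wild-type growth; with growth pinned,
   optimize the target exchange *adversely* (minimize it when the goal is
   to maximize production) to obtain the wild-type worst-case production
   and one well-defined vertex from which all Φ_i^WT are evaluated.
2. **Range.** Solve two MILPs for the feasible extremes Φ_i^min, Φ_i^max.
3. **Perturbed growth.** For each level k ∈ {0, 0.1, …, 1}, maximize
   biomass under one of

   ```
   (C1, attenuation)      Φ_i ≤ Φ_i^min + k·(Φ_i^WT − Φ_i^min)
   (C2, intensification)  Φ_i ≥ Φ_i^WT  + k·(Φ_i^max − Φ_i^WT)
   ```

   giving the attainable growth B_ik.
4. **Worst case.** With `v_biomass ≥ B_ik`, optimize the target adversely
   again.  If this *guaranteed* production beats the wild-type worst case,
   metabolite *i* is a target in that direction.

## Worked example

```
$ python examples/succinate_targets.py
wild-type growth:            15.000
wild-type worst-case succ:   0.000 mmol/gDCW-hr
targets (metabolite, direction, best k, guaranteed production):
    fum intensification  k=1.0 production=6.67 (growth 6.67)
    mal intensification  k=1.0 production=6.67 (growth 6.67)
    oaa intensification  k=1.0 production=6.67 (growth 6.67)
    pyr attenuation      k=0.5 production=5.00 (growth 10.00)
   succ intensification  k=1.0 production=6.67 (growth 6.67)

pyruvate attenuation profile (triangular):
   k   growth  guaranteed succinate
 0.0    -0.00                  0.00
 ...
 0.5    10.00                  5.00
 ...
 1.0    15.00                  0.00
```

On the bundled anaerobic mixed-acid fermentation toy, the wild type grows
at 15 (ATP-drain units) and guarantees **no** succinate.  Attenuating
pyruvate turnover to half its wild-type value redirects PEP through the
carboxylase branch and *forces* 5 mmol/gDCW-hr of succinate while retaining
two-thirds of wild-type growth; pushing the attenuation further starves ATP
regeneration and the guarantee collapses again — the characteristic
triangular profile.  Metabolites of the succinate branch itself (oaa, mal,
fum) appear as intensification targets, trading more growth for a larger
guarantee.

The same workflow is exposed as a CLI:

```
fluxsum fixtures write --name mixed_acid --out model.json
fluxsum scan --model model.json --target EX_succ --goal maximize --out run/
fluxsum fluxsum --model model.json --target EX_succ       # Φ_min/Φ_WT/Φ_max table
```

`scan` writes `points.tsv` (every solve), `report.json` (targets plus every
numeric convention used) and one profile TSV per target.  Genome-scale
models load from community-dialect JSON or SBML Level 3 FBC
(`--model iAF1260.json --glucose 1:g --glucose-exchange EX_glc__D_e
--medium EX_o2_e=0,0` reproduces anaerobic glucose-limited conditions; the
g→mmol conversion uses a glucose MW of 180.16 g/mol).

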