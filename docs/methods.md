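# Methods

## Model and scope

`fluxsum` operates on stoichiometric metabolic models at steady state: a
matrix S of coefficients S_ij, flux bounds α_j ≤ v_j ≤ β_j in mmol/gDCW-hr,
and a biomass reaction whose flux is the growth proxy.  Boundary
pseudo-species (SBML `boundaryCondition`, "_b"-suffixed ids) are flagged,
stripped from reaction stoichiometries and excluded from both the mass
balance and the scan candidate set; exchange reactions are recognised
structurally as reactions touching exactly one metabolite.  Gene–protein–
reaction rules, gene deletions and model curation are out of scope.

## Flux-sum and its linearization

The turnover (flux-sum) of an internal metabolite is
Φ_i = ½ Σ_j |S_ij v_j|.  Evaluated at a known flux vector this is a plain
sum.  Inside an optimization problem each signed rate is split as
S_ij v_j = g⁺_ij − g⁻_ij with g± ≥ 0, g± ≤ M·I±, I⁺ + I⁻ = 1, I ∈ {0,1},
making Φ_i = ½ Σ (g⁺ + g⁻) linear.  Two economies keep the MILPs small
without changing any optimum:

* split variables and indicators are instantiated **only for reactions
  incident to the instrumented metabolite** — non-incident terms contribute
  nothing to Φ_i;
* indicators are **omitted where the reaction's bounds already confine
  S_ij v_j to one sign** (the split is then forced by fixing the dead side
  to zero).  Most genome-scale reactions are irreversible, so this removes
  the large majority of binaries.  The reduction can be disabled
  (`SolveConfig.use_sign_presolve=False`), which the test suite uses to
  exercise the full binary formulation against a binary-free LP oracle.

Big-M defaults to 1000 mmol/gDCW-hr.  At machinery construction it is
validated against the largest finite flux bound and auto-raised (with a
warning) to 10× that bound if not strictly larger.  After every solve in
which Φ is constrained or minimized, any split variable sitting at its M
cap raises an error (M too small).  When Φ is being *maximized*, a split
variable at the cap means the true maximum exceeds any finite M; the
maximization is then reported as Φ_max = +∞, the same flag used when the
solver proves unboundedness outright.  Intensification of a metabolite with
Φ_max = +∞ is skipped with a reason code, since the C2 threshold is
undefined.

## The scan procedure

For a target exchange and a goal (maximize or minimize production):

1. **Reference state.**  Growth is maximized, then — with growth held at
   its optimum — the target exchange is optimized in the goal-adverse sense
   (lexicographic solve).  This stage-2 optimum is the wild-type worst-case
   production, and Φ_i^WT of every candidate is evaluated at the stage-2
   vertex.  FBA optima are degenerate, so Φ^WT is vertex-dependent; pinning
   the vertex with the same adverse objective that defines the wild-type
   production makes the two quantities mutually consistent and, in
   particular, makes the weakest-constraint scan endpoints reproduce the
   reference exactly.  The convention is recorded in report metadata.
2. **Turnover range.**  Φ_i^min and Φ_i^max by two MILPs under mass balance
   and bounds only (no growth constraint).
3. **Perturbed growth.**  B_ik = max biomass under C1 (attenuation,
   Φ ≤ Φ^min + k(Φ^WT − Φ^min)) or C2 (intensification,
   Φ ≥ Φ^WT + k(Φ^max − Φ^WT)) for k on the grid {0, 0.1, …, 1}.
   An infeasible solve is recorded as a status, never as growth 0 —
   conflating the two would corrupt the monotonicity of B_ik in k that the
   nested constraint sets guarantee.
4. **Worst-case production.**  The target exchange is optimized adversely
   under the same constraint set plus v_biomass ≥ B_ik.  A metabolite is
   classified a target when some point's guaranteed production improves on
   the wild-type worst case by more than a relative 10⁻³ (absolute floor
   10⁻⁶ mmol/gDCW-hr) — a threshold chosen to suppress solver noise, echoed
   in report metadata.

Directions whose interpolation range is empty (Φ^WT within 10⁻⁶ of the
relevant extremum) are skipped with a reason code rather than producing a
grid of identical points.  Currency-metabolite exclusion (protons, water,
cofactor pairs) is available but **off by default**: the method
deliberately scans every internal metabolite, and cofactor-adjacent species
can be genuine targets.  A non-growing wild type (growth 0) is scanned
normally and flagged in metadata.

## Numerical conventions

* All LPs and MILPs are solved by HiGHS via `scipy.optimize.milp` with
  `mip_rel_gap = 0`; the solver is single-threaded and deterministic, which
  makes scans (and the CLI's artifacts) reproducible byte-for-byte.
* Stage optima re-imposed as bounds (lexicographic stage 1, the B_ik growth
  floor) use an inequality with slack `max(10⁻⁹, 10⁻⁹·|optimum|)` rather
  than an equality: an exact equality is numerically infeasible under MILP
  tolerances.  The slack propagates into worst-case production at
  sensitivity ≤ 1, i.e. well below the 10⁻⁶ comparison tolerances used
  throughout.
* Integer feasibility tolerance 10⁻⁶; Φ comparisons use absolute tolerance
  10⁻⁶.
* Unbounded LPs are reported as a status, never clamped; big-M capping
  exists only inside the turnover machinery.

## Toy networks and what they do (and do not) show

`make_two_branch_fixture` is the minimal competing-pathway network: fixed
uptake 10 mmol/gDCW-hr, biomass at the end of one branch, the product
exchange at the end of the other.  Every scan quantity has a closed form
(growth 10k and guaranteed production 10(1−k) under branch-point
attenuation), which the test suite asserts exactly.

`make_mixed_acid_fixture` is a reduced anaerobic mixed-acid fermentation
network of *E. coli*: PTS- and kinase-mediated glucose entry, lumped
glycolysis, the PEP branch point (carboxylase toward
oxaloacetate→malate→fumarate→succinate versus pyruvate kinase), the three
pyruvate fates (lactate, formate+acetyl-CoA, CO₂+acetyl-CoA), the two
acetyl-CoA fates (acetate, ethanol), and internally balanced NADH/NAD,
ATP/ADP and CoA pools, with growth as an ATP drain.  All stoichiometric
coefficients are 1 so oracles stay exact; carbon and phosphate bookkeeping
is therefore schematic, uptake is 10 mmol/gDCW-hr and internal caps are
100 mmol/gDCW-hr (kept below big-M).  The fixture reproduces the
qualitative genome-scale phenomena the method is built around — the
triangular succinate-vs-k profile under pyruvate attenuation (redox
rerouting versus ATP starvation) and the weak dominance of the
PDC-inserted ethanol profile under acetaldehyde intensification — but its
absolute values are toy-scale: passing tests demonstrate the correctness
of the optimization machinery and the direction of the biological effects,
not quantitative predictions for *E. coli*.  In the toy the PDC profile
equals the wild-type profile (the unit-coefficient redox bookkeeping makes
the shortcut cost-neutral), so the dominance holds with equality.

`make_random_irreversible_network` generates all-irreversible unit-
coefficient networks (≤ 15 reactions) in which every metabolite has a
secretion outlet, so a fixed uptake is always feasible.  Because every flux
is sign-fixed, Φ is linear in v and the entire scan can be reformulated
binary-free; the tests and the acceptance script solve both routes with
independently constructed problems (the oracle builds dense matrices
straight into `scipy.optimize.linprog`) and compare every quantity to
10⁻⁶.

## Known limitations

* Φ^WT remains convention-dependent: a different tie-breaking objective
  would yield different wild-type flux-sums (and hence different C1/C2
  thresholds) on degenerate models.  The lexicographic convention used here
  is reported in every output.
* One metabolite is perturbed at a time; combined multi-metabolite
  constraints are not explored.
* The scan cost is one MILP per (metabolite, direction, k) plus two per
  metabolite; on genome-scale models with many reversible incident
  reactions individual MILPs can become hard, and no warm-starting is
  attempted.
* No mapping from metabolite targets to concrete genetic interventions is
  provided.
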