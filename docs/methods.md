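# Methods

## Scope and model

`ecgem` implements the construction and analysis of enzyme-constrained
genome-scale metabolic models.  The state is a stoichiometric model —
metabolites, reactions with bounds (mmol/gDW/h), boolean
gene–protein–reaction (GPR) rules, a biomass objective — and all analyses
are linear programs over `S v = 0` with the HiGHS solver
(`scipy.optimize.linprog`; feasibility/optimality tolerances 1e-9).

The enzyme constraint `v_j ≤ kcat_j · [E_j]` is encoded stoichiometrically:
after the model is made irreversible, every kinetically characterised
reaction consumes its enzyme species at `1/kcat` per unit flux, and each
enzyme species is produced by exactly one usage exchange whose upper bound
is the measured abundance (mmol/gDW).  Mass balance of the enzyme species
then enforces the cap, and a multifunctional enzyme's reactions are coupled
through the shared usage bound automatically.  Isozymes (OR branches) are
routed through an arm pseudo-metabolite with one branch reaction per
isozyme; complexes (AND branches) place every subunit on the same reaction
with subunit stoichiometry 1 (no subunit composition data is assumed).
Nested rules (OR of ANDs, AND of ORs) are flattened to disjunctive normal
form; each distinct protein set is one branch.

Design choices made where the construction was genuinely open:

* **Partial kinetic evidence.** A reaction is expanded only when *every*
  distinct GPR branch has a complete kcat assignment.  If any branch is
  uncharacterised the whole reaction is left unconstrained (recorded in the
  build report): capping only the characterised branches while an
  uncharacterised branch exists would impose no net constraint anyway, and
  imputing a default kcat would manufacture constraints from no evidence.
  This is also why the arm-reaction count can fall below the isozyme count.
* **Arm creation.** Arm metabolites are created only when ≥ 2 distinct
  branches survive; a single surviving branch adds its enzymes directly to
  the reaction.
* **Reversible enzymes.** The `_fwd`/`_rev` copies carry independent kcats
  (looked up per split id, falling back to the pre-split id) but share one
  enzyme species and usage bound.
* **Protein pool.** An optional global cap `Σ MW_p·u_p ≤ σ·P_tot`
  (g protein/gDW) is available via a pool pseudo-metabolite drawn at
  MW/1000 g per mmol of usage; it is off by default — per-protein abundance
  bounds are the primary constraint, and enzymes without abundance evidence
  are deliberately left unconstrained rather than pooled.

## Evidence tables

kcat evidence (1/h) may be a direct measurement or a specific activity
(µmol·mg⁻¹·min⁻¹) plus molecular weight, converted as
`kcat = SA·MW·60·10³·10⁻⁶ = 0.06·SA·MW`.  Among competing records for one
protein/reaction the maximum *direct* kcat wins; SA-derived values are used
only when no direct value exists; reaction-specific records beat wildcard
(protein-wide) records.  Selection is permutation-invariant with
deterministic tie-breaks.

Abundance evidence may come from a related organism.  Matching walks the
taxonomy outwards — species, genus, family, order, class — and takes the
maximum abundance at the *first* rank with any record.  (The alternative
reading, a maximum across all ranks at once, would let a distant homolog
override a near one; proximity-first is the conservative choice.)  Proteins
with no match at any rank get an unbounded usage reaction.  When inputs are
ppm of total protein mass, conversion to mmol/gDW uses
`ppm·10⁻⁶·P_tot/MW·10³` with a configurable total protein content
(default 0.5 g protein/gDW, a typical fungal value).

## kapp correction

Database kcats loaded directly can choke growth entirely.
`detect_overconstraint` flags a model whose growth optimum stays below a
threshold (default 1e-6 1/h) over a whole condition grid, and lists the
proteins whose capacity `kcat·E` falls short of the demand of the relaxed
model's flux distribution.  `estimate_kapp` sweeps a substrate × oxygen
uptake grid (default 20 × 20 = 400 conditions over 0.25–5.0 mmol/gDW/h
each; spacing is configuration, not a constant) and computes
`kapp_j(C) = v_j(C)/E_j` with the *fixed* measured abundance — abundances
are not condition-specific.  Fluxes default to the **relaxed** model (kcat
coefficients kept, usage bounds lifted): under the constrained model
`kapp ≤ kcat` by construction, so constrained fluxes could never reveal an
underestimated kcat; the `constrained` source is kept as a consistency
check and for saturation-based recovery of a known kcat.
`correct_kcats` replaces each kcat with `max_C kapp` under the
`replace_if_larger` policy (default), which is idempotent and can only
relax the model, so the growth optimum never decreases; `always_replace` is
available for the unconditional reading.

## Simulation suite

* **FBA** maximises (or minimises) an objective flux; fixed-growth mode
  supports chemostat-style questions (pin biomass, minimise uptake or
  maximise secretion).  Objective values are the primary surface; where an
  analysis consumes flux *vectors* (kapp sweeps, differential usage) they
  are stabilised with parsimonious FBA — objective pinned at its optimum
  (relative slack 1e-9), total |v| minimised via variable splitting —
  because FBA optima are degenerate.
* **Robustness** evaluates the growth optimum on a 2-D uptake grid and
  reports whether growth saturates at full supply (enzyme-limited) or keeps
  rising (missing constraint).
* **FVA** holds the objective at a fraction of its optimum (default 0.999,
  the "99.9 % confidence" reading of fraction-of-optimum; no statistical
  interval is involved) and solves min/max per reaction.  An explicit
  absolute `floor` lets two models be compared under an identical growth
  requirement, which is the regime in which the enzyme-constrained
  polytope is provably nested in the base polytope.
* **FV reduction** pairs each base reaction with the expanded reaction
  carrying the same total flux (same id, or the arm reaction of an isozyme
  split; branch and usage reactions are excluded) and reports
  `(1 − fv_ec/fv_base)·100 %` per reaction, defined as 0 where the base FV
  is 0, plus the mean over reactions *and* the reduction of summed FV —
  both are reported because a single headline percentage admits either
  reading.  Pairs with infinite FV are excluded and counted.
* **Knockouts** evaluate each gene's deletion: reactions whose GPR goes
  false are closed, and in an ecGSMM the usage bounds of the gene's
  proteins are zeroed (columns are kept, so isozyme branches reroute).
  `grRatio = μ_ko/μ_wt` with classification tolerance 1e-6 (lethal ≤ ε,
  neutral |grRatio−1| ≤ ε, else limiting).
* **Differential usage** runs parsimonious max-growth FBA per carbon
  source (all sources in the comparison closed except the named one,
  oxygen unbounded) and reports usage-reaction fluxes and fold changes
  against the reference with a 1e-8 denominator floor; enzymes active only
  under the alternate source are flagged "induced from zero" (fold change
  ∞) rather than divided by the floor.  Carbon-mole influx per condition is
  recorded so iso-carbon designs (e.g. glucose 1.0 × 6 = xylose 1.2 × 5 =
  maltose 0.5 × 12 C-mmol/gDW/h) can be verified.

## Network indices

The metabolite graph joins two metabolites whenever they co-occur in a
reaction; enzyme and arm species of an ecGSMM are nodes like any other,
tagged by role and compartment (compartmentalised duplicates stay
distinct).  A configurable currency list (ATP/ADP/AMP, NAD(P)(H), H2O, H⁺,
Pi/PPi, CO2, O2, CoA; all compartments) can be dropped before edge
formation.  Indices: node/edge counts, mean degree, diameter/radius/
characteristic path length on the largest connected component (the full
graph may be disconnected), mean local clustering with degree-<2 nodes
counted as 0, density `mean(k)/(n−1)`, heterogeneity `std(k)/mean(k)`
(population variance), and centralization `max(k)/n` — the latter kept in
this simple degree form (not the Freeman index) for comparability with the
convention used in ecGSMM network reports.

## Synthetic data

The generator emulates, at desk scale, the situations the pipeline must
handle: a substrate-exchange → linear-chain → biomass topology decorated
with isozyme steps, complex steps, reversible steps and a multifunctional
enzyme shared by two steps, with matching kcat/abundance tables.  Topology
is deterministic from the requested counts; seeded randomness covers only
kcat draws (uniform 50–200 1/h), abundance draws (uniform 0.005–0.05
mmol/gDW — capacities 0.25–10 mmol/gDW/h against a default uptake of 10,
so enzyme caps usually bind) and which steps are reversible.  The
max-growth optimum therefore stays closed-form:
`min(uptake, step capacities, E/(1/kcat_a + 1/kcat_b))` with isozyme steps
summing branch capacities and complex steps taking the scarcest subunit.
Variants: `make_overconstrained` scales one essential step's kcat down to
reproduce the choked-model phenotype; `make_carbon_switch_toy` builds
dedicated glucose/xylose/maltose entry pathways with iso-carbon uptakes.

What the toys do **not** emulate: genome-scale topology (loops, cofactor
coupling, compartments beyond tags), realistic kcat/abundance
distributions spanning many orders of magnitude, measurement noise, or
thermodynamic constraints.  Passing tests therefore demonstrate the
correctness of the construction and the LP analyses, not predictive
accuracy on real organisms.

## Verification sizes and numerics

The test suite and `scripts/acceptance.py` use 200 seeded toys for
expansion neutrality and closed-form agreement (tolerance 1e-8 relative),
30 linear toys for the capacity law, 1000 random draws for the SA
conversion (1e-12), 8 toys for FVA nesting, 4-condition grids for the
over-constraint repair loop, and, for the network indices, an exhaustive
enumeration of all labelled graphs on 4 nodes plus seeded random graphs up
to 12 nodes against an independent igraph implementation (1e-9).  These
sizes keep the default run in seconds while exercising every code path.
Degenerate inputs are defined explicitly: empty models and empty evidence
sets raise; infeasible conditions are skipped with warnings in sweeps and
reported as status in FBA; reductions with zero base variability are 0;
fold changes from a zero baseline are sentinels, not ratios.

## Known limitations

No subunit stoichiometry in complexes; no condition-specific proteomes in
kapp estimation (by design — abundances are fixed); no compartment-specific
protein pools; gene→protein mapping is taken from the model's
`protein_map` (a gene absent from the map is treated as its own protein
id); SBML export stores role tags in annotations, so third-party tools will
read an ecGSMM as a plain stoichiometric model.
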