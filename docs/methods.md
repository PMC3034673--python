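# Methods

## Model representation

A model is a list of metabolites, reactions and gene locus tags with a
designated biomass objective. Metabolites live in one of two compartments —
`c` (intracellular) and `e` (extracellular) — reflecting the
single-membrane abstraction typical of prokaryotic reconstructions that
resolve only intra- and extracellular pools. Each metabolite optionally
carries an elemental formula in Hill notation and a net charge; each
reaction carries a stoichiometry map (negative = consumed), a
reversibility flag, flux bounds α/β in mmol/gDW/h, EC numbers, a
gene-association boolean expression, a subsystem label and a kind
(`enzymatic`, `transport`, `exchange`, `biomass`). When a file omits
bounds, the standard constraint-based defaults apply: 0…1000 for
irreversible and −1000…1000 for reversible reactions. Stoichiometric
coefficients are stored as floats; equality anywhere in the package means
agreement within 1e-9.

Gene associations are parsed as AND/OR expressions with the usual
precedence (`and` binds tighter); a bare whitespace- or comma-separated
list of locus tags is read as an OR of isoenzymes, the permissive choice
when a source file does not spell out its GPR logic.

The stoichiometric matrix S (m×n, scipy CSR) is assembled directly from
the stoichiometry maps together with metabolite→row and reaction→column
index maps; the matrix→stoichiometry round trip is exact and is property-
tested on random networks.

## Serialization

The native dialect is a `reactions.tsv`/`metabolites.tsv` pair plus a
mirror JSON document with a mandatory `schema_version`. Reaction equations
are human-readable strings (`"atp[c] + glc[c] -> adp[c] + g6p[c] + h[c]"`,
`<=>` for reversible) with a strict grammar: every species carries exactly
one compartment tag, duplicate species on one side are an error, and parse
errors report the column offset. Table loading is collect-all: every
offending row is listed in one error rather than failing fast. Column-name
matching is case-insensitive over a documented synonym set, so a
supplementary spreadsheet workbook can be converted with
`convert_workbook`, which picks the reaction and metabolite sheets by
header match and writes a `column_mapping.json` log for manual
confirmation (the layout of third-party supplementary files is never
guaranteed). Unknown extra columns are carried through as annotations,
never dropped. Files are UTF-8 with `.` as the decimal separator.

## Quality control (curation)

*Dead ends.* A metabolite is a dead end if it lacks a producing or a
consuming reaction, counting a reversible reaction as both and counting
exchange and biomass reactions as legitimate producers/consumers (boundary
reactions are added during reconstruction precisely to resolve such gaps).
A species missing both roles is reported once per missing role. The
implementation is cross-checked against a brute-force double loop on
random networks.

*Mass/charge balance.* The deficit of a reaction is Σ(products) −
Σ(substrates) per element and for charge; balanced means all zeros within
1e-6. A participant without a formula makes the verdict `unknown` rather
than unbalanced — reconstructions rarely have full formula coverage, and
conflating "cannot check" with "wrong" would flood the report. Only
enzymatic and transport reactions are audited: exchange and biomass
reactions are boundary/lumped pseudo-reactions and are unbalanced by
construction. The canonical worked example is glucokinase with a missing
proton: glc (C6H12O6) + atp (C10H12N5O13P3, −4) → g6p (C6H11O9P, −2) +
adp (C10H12N5O10P2, −3) reports exactly {H: −1} and charge −1, and adding
`h[c]` zeroes the deficit.

*Topology and statistics.* Metabolite/reaction adjacency matrices are the
binarized Gram matrices of |S| (symmetric, zero diagonal); connected
components come from networkx. Network statistics mirror the usual
reconstruction summary: counts by compartment and reaction kind, reactions
with gene assignments, the subsystem distribution (over labeled
reactions), reactions-per-gene ratios per top-level EC class, and the
monofunctional fraction — the share of distinct EC numbers mapped to
exactly one reaction.

*Cross-model comparison.* Reaction ids are not comparable across
publications, so reactions are matched by a canonical signature: sorted
(species-key, coefficient) pairs, where the species key is the elemental
formula when available (else the compartment-stripped id), with reversible
reactions oriented to the lexicographically smaller direction. Only
enzymatic reactions are compared by default; an interconversion of species
with identical formulas collapses to an empty signature and is listed as
unmatchable rather than spuriously shared. A curated id-mapping can always
override signature matching by renaming species before the comparison.

## FBA/FVA engine

LPs are solved with scipy's HiGHS dual simplex, single-threaded and
deterministic, at 1e-9 primal/dual feasibility tolerances. Infeasible and
unbounded outcomes are reported distinctly on the solution status, never
as zero growth. Steady-state residuals at reported optima are far below
the 1e-8 invariant the tests enforce.

FVA pins the objective at `fraction` × optimum and minimizes/maximizes
each requested reaction. The pin uses a relative slack of 1e-7: with the
solver's own feasibility tolerance at 1e-9, a 2e-9-wide pinned interval is
(correctly) rejected by HiGHS presolve as numerically infeasible, so the
slack must sit comfortably above the tolerance; 1e-7 on fluxes of order
0.1–10 mmol/gDW/h changes no reported variability at the precision used.
The variability percentage is 100·(v_max − v_min)/max(|v_FBA|, ε) with
ε = 1e-6, which keeps the metric defined at zero-flux reactions.

Exchange reactions are stored bidirectionally in the COBRA convention
(`x[e] <=>`, negative flux = uptake) while every user-facing rate is a
positive uptake in mmol/gDW/h. `set_medium` fixes each named substrate's
uptake at its rate (α = β = rate; published simulations report single
fixed rates), closes the uptake of every other organic-carbon species
(secretion stays open), and leaves carbon-free species — water, protons,
phosphate, ammonium, salts — plus inorganic carbon (CO2/bicarbonate) open;
O2 is open when aerobic and closable by name (`{"oxygen": 0}`). Organic
means "formula contains carbon"; a species without a formula is
conservatively treated as a potential carbon source. A `mode="max"` uses
α = 0, β = rate for sensitivity work.

## Phenotype screens

A substrate screen offers each substrate as the sole carbon source at a
fixed uptake rate on the minimal medium; for nitrogenous substrates
(formula contains N) ammonium is additionally closed, so amino acids are
tested as sole carbon *and* nitrogen source. In-silico growth is "+" when
the biomass optimum exceeds 1e-6 h⁻¹ (published screens never define
"positive growth" numerically; any threshold below real growth rates and
above solver noise gives identical verdicts). Active transport and
utilization reactions are those touching the substrate species with
|flux| > 1e-9 mmol/gDW/h. A substrate without an uptake route yields "−"
with a reason rather than an error, matching how such tables treat absent
transporters. Activity tests maximize |flux| through a named reaction
under a medium. A transcription of the published 60-row in-vivo
substrate/activity verdict table ships as packaged data
(`halofba/data/table2_invivo.tsv`) so concordance against a loaded
genome-scale model is computable offline.

## Osmoadaptation case studies

The choline→betaine sweep fixes glucose and sweeps fixed choline uptakes,
maximizing biomass; the ectoine sweep emulates the osmoprotectant-free
condition by closing choline and betaine uptake and knocking out both
step-one choline-oxidizing enzymes (EC 1.1.99.1, EC 1.14.15.7), then
sweeps glucose. Pathway presence is audited before any LP; for the
transaminase and choline-oxidation steps either isoenzyme satisfies the
step.

"Production flux" of an osmolyte is its net synthesis rate by enzymatic
reactions at the optimum. In a model whose biomass drains the osmolyte (a
halophile's biomass plausibly does: reported ectoine fluxes rise in
proportion to growth at roughly half-molar yield on glucose), the
excretion flux at the biomass optimum is zero, so the synthesis rate — 
which equals excretion plus biomass incorporation at steady state, and
reduces to excretion when biomass does not contain the osmolyte — is the
quantity that generalizes. `objective="ectoine"` maximizes the excretion
flux directly and provides the stoichiometric yield bound the sweeps are
checked against. Percent changes in the alanine scenario are computed on
4-decimal rounded fluxes, matching the precision such studies report.

## Synthetic networks

*Toy chain / branched toy.* Analytic LP fixtures: the chain's optimum is
its uptake bound; the branched toy has alternate optima by construction
(two capacity-5 branches into a capacity-5 sink → each branch's FVA range
spans 5).

*Random QC networks.* A polymerization core: metabolites M1…Mm with
formulas (CH2O)^i, so any condensation Mi + Mj → M(i+j) is elementally
balanced; coefficients stay in {1, 2} to keep oracles exact. Injected
dead ends are extra species touching a single irreversible reaction (mode
recorded); injected imbalances add one water to a product side (deficit
{H: 2, O: 1} recorded). The same seed reproduces the model and ground
truth bit for bit.

*Mini-halophile.* A deterministic 50-metabolite / 58-reaction cartoon of a
halophile: glucose/choline/alanine/nitrate/O2/NaCl uptakes, lumped
glycolysis–TCA–oxidative phosphorylation (P/O = 2) with real cofactor
formulas, aspartate and glutamate nodes, the four-step ectoine branch with
both diaminobutyrate transaminases, the two-step choline→betaine pathway
with both step-one enzymes, a peroxide source + catalase pair, lactate
fermentation, respiratory nitrate reduction, and a biomass drain of
precursors, ATP and ectoine-as-osmolyte. Every enzymatic and transport
reaction is elementally and charge balanced (the audit must come back
clean), and the coefficients are chosen for clean rational optima, not
biological accuracy — e.g. the theoretical ectoine yield is exactly
1 mol/mol glucose because the pathway's ATP and NADH costs exactly cancel
glycolysis' output. The biomass ATP coefficient (40 mmol/gDW per unit
growth) keeps the fixture energy-limited across the case-study uptake
ranges so that osmolyte-pathway redox credit translates into growth, the
qualitative behavior the choline sweep probes. Glutamate dehydrogenase and
the ammonium transporter are reversible so amino acids can serve as sole
carbon and nitrogen source with surplus nitrogen excreted as ammonium
(ammonia is a secreted by-product in these organisms).

What the fixture does *not* emulate: genome-scale redundancy (thousands of
reactions, parallel isozymes and futile cycles), realistic biomass
composition, salinity-dependent maintenance, regulation (e.g. betaine's
inhibition of choline oxidation is a regulatory effect FBA cannot produce
and is not simulated). Tests passing on the fixture therefore certify the
*machinery* — LP correctness, medium construction, sweep logic, QC
oracles — not organism-specific flux values; genome-scale numbers require
loading the organism's reconstruction through `halofba.io`.

## Verification strategy and problem sizes

The LP path is cross-checked three ways: against an exhaustive
vertex-enumeration oracle (`halofba.bruteforce`, O(3^n), shares no code
with the simplex path) on 200 random toys of ≤ 8 reactions; against
cobrapy building the same fixture independently; and against analytic
optima of the toy generators. Curation oracles are exercised on 30 random
networks (~1,500 audited reactions) with 100 % recovery of injected
defects required. These sizes make the whole suite and the acceptance
script run in well under a minute each while exercising every code path;
they are the package's chosen desk-scale verification conditions, not
statistical estimates.

## Known limitations

* No SBML import/export; the TSV/JSON dialect and workbook converter are
  the interfaces.
* No thermodynamic directionality assignment, parsimonious FBA,
  MOMA/ROOM, dynamic FBA or gene-deletion scans.
* Compartments fixed to {c, e}.
* Cross-model comparison is formula-driven; models without formulas fall
  back to id matching, which is unreliable across publications.
* The empty-signature rule makes same-formula isomerizations unmatchable
  in comparisons (they are listed as unique).
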