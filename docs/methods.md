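# Methods

## Scope and modelling assumptions

The package simulates a *cell-scale* system over 12 days: molecule counts are
deliberately small (tens to hundreds) and the aggregation kinetics are
accelerated so that plaque formation, which takes decades in a human brain,
plays out on the timescale of a cell-culture experiment (aggregates within a
day or two, maximal plaque load within about ten days). All species share one
well-mixed compartment; spatial structure, transport and cell-to-cell
heterogeneity are outside the model. Time is kept in seconds internally
(all rate constants are per second); one day is 86,400 s and the standard
horizon is 12 days = 1,036,800 s.

The network couples:

1. **DNA damage / p53 / Mdm2.** p53 is translated from its mRNA and removed
   only via binding to Mdm2 (the complex degrades p53 and recycles Mdm2).
   Mdm2 transcription is p53-dependent (negative feedback) with an extra
   contribution from the GSK3β·p53 complex. ROS damages DNA; damage activates
   ATM; active ATM phosphorylates Mdm2; phosphorylated Mdm2 is degraded via
   ubiquitination. Damage therefore depletes Mdm2 and stabilises p53. Soluble
   Aβ additionally stimulates p53 mRNA synthesis.
2. **GSK3β.** No synthesis or turnover (there is no evidence for regulation
   at that level); the kinase shuttles between a free pool and the GSK3β·p53
   complex, which is the *active* pool: it phosphorylates tau and drives
   additional Aβ production. Reported "active GSK3β" is this complex.
3. **Aβ.** Zeroth-order production (1.86e-5 molecules/s, a measured value,
   identical in disease and control) plus production proportional to active
   GSK3β; first-order clearance (1.5e-5 s⁻¹ disease, 2.1e-5 s⁻¹ control;
   1e-4 and 2e-4 s⁻¹ as high-clearance variants). Two monomers form a dimer
   (reversible); a dimer may nucleate a plaque (both molecules enter the
   plaque pool) or deposit onto existing plaques. Plaques are counted in
   constituent molecules, not particles.
4. **Tau.** Constant slow synthesis; exchange between free and
   microtubule-bound pools (bound tau is protected); two-step
   phosphorylation by active GSK3β and first-order dephosphorylation;
   aggregation into tangles second-order in the aggregating pool, with
   doubly-phosphorylated tau aggregating 10× faster than free tau.
5. **Microglia and antibody.** 100 glia conserved across five states:
   inactive → (plaque-dependent, two stages) partially active → (antibody-
   dependent) fully active ⇄ plaque-bound. Two partial stages give a
   realistic 1–2 day lag between plaque appearance and full activation.
   Fully active glia bind plaques and degrade them by phagocytosis; while
   plaque-bound they generate ROS, as do plaques themselves. The antibody
   binds monomers and dimers (enhancing their degradation ~10-fold, antibody
   recycled), disaggregates plaques at a lower rate than spontaneous
   disaggregation, and is cleared with a ~3-day half-life (mimicking
   diffusion away from the cell).

The reported quantity "soluble Aβ" is monomers + dimers; antibody-bound
complexes are excluded. Total glia is conserved by construction and checked
by the validator, both engines, and the test suite.

## Rate-law conventions

Rates are evaluated on raw molecule counts. Second-order mass action is
k·X·Y (and k·X² for homodimerisation) with no combinatorial X(X−1) correction
and no volume scaling, matching the printed form of the reaction tables this
model family uses. The plaque growth law is a Hill function of plaque size
with coefficient 1,

    v = k_pg · AbDim · AbP / (AbP + k_pghalf),

bounded and monotone in AbP: growth rises linearly with plaque size when
plaques are small and saturates at k_pg per dimer for large plaques. Growth
therefore requires both dimers and at least one nucleated plaque.

Stoichiometry conventions (molecule bookkeeping): dimerisation consumes two
monomers; dedimerisation returns two; nucleation and growth each move one
dimer = two molecules into the plaque pool; disaggregation (spontaneous or
antibody-mediated) releases one monomer per plaque molecule; glial
phagocytosis destroys the bound plaque unit.

## Parameters and provenance

Every rate constant carries a provenance tag:

* `published` — the fifteen immunotherapy constants and the measured Aβ
  production/clearance rates, used verbatim.
* `calibrated` — the remaining base-network constants. The reconstruction of
  the base network was calibrated **once**, against the documented behaviour
  of this model family, and then frozen: plaque onset around day 2 under the
  disease clearance rate; a mean maximum plaque of ~75 molecules reached over
  the 12-day run; plaques still forming at the control clearance rate but not
  at 2e-4 s⁻¹; dimer counts always near zero; soluble Aβ in the tens;
  phospho-tau and tangles rising over days and continuing to rise (more
  slowly) after immunisation; glial activation within 1–2 days of dosing;
  plaque clearance within ~2 days of a day-4 or day-8 dose with a slow
  late rebound. Calibration used the deterministic engine plus a randomised
  search over the unconstrained constants against those targets; the final
  values are in `abtau.model.build_base_model` and are not adjusted anywhere
  else.
* `scan-default` — all sensitivity scans run with three ROS-generation rates
  set to alternative defaults (k_genROSAbeta = 2e-5, k_genROSGlia = 1e-5,
  k_genROSPlaque = 1e-5), which give slightly lower levels of every output;
  percentages and rankings are always relative to baselines computed under
  the same defaults.
* `override` — set by a scenario or by the user.

Five extension constants have two historical spellings; the parameter-table
spellings (k_binAbPGlia, k_relAbPGlia, k_degAbPGlia, k_disaggAbP1/2,
k_dedimerAbeta) are canonical and an alias map normalises the others on SBML
import, together with the legacy species names AggAbeta → AbDim and
AbetaPlaque → AbP.

The active-immunisation production constant k_synAntiAb = 1.375e-4
molecules/s is chosen so that production balances clearance at the standard
passive dose (50 molecules): antibody rises smoothly toward, and stays near,
the level a bolus provides.

## Interventions

"Day T" means the event triggers at exactly T·86,400 s. Passive dosing is a
timed event `antiAb := dose` (several times give repeated immunisation);
prevention sets the initial antibody amount instead and adds no event; active
immunisation adds the production reaction and no events. Scenario realisation
never mutates the base network. In the stochastic engine event assignments
must be integers; the deterministic engine accepts any non-negative value.

## Engines

**Stochastic.** Exact Gillespie direct method on int64 counts with a
numba-compiled inner loop. Propensities are guarded: a reaction with fewer
molecules of a consumed reactant than its stoichiometry has propensity zero,
so no update can drive a count negative. A timed event truncates the current
exponential waiting time at the trigger; by memorylessness this is exact; the
assignments are applied atomically and simulation resumes with recomputed
propensities. If all propensities vanish and no events are pending, the
simulation fast-forwards to the horizon (a valid absorbing state). Recording
uses a fixed grid (default step 0.05 day — output resolution only, the jump
process itself is exact); samples are right-continuous, so an event is
visible at the first grid point ≥ its trigger. Replicate k of an ensemble
uses seed (base_seed + k) mod 2³¹, making any replicate reproducible in
isolation; ensembles report per-grid-point means and sample SDs (ddof 1; a
single replicate reports SD 0).

**Deterministic.** The same rate expressions (count units, no concentration
conversion) integrated with LSODA at rtol 1e-8 / atol 1e-10 — tight because
scan percentages are differences of trajectory maxima. Events are localised
by stopping the integrator exactly at the trigger, applying assignments, and
restarting; never by interpolating across the discontinuity. Negative
undershoots below ~1e-7 molecules are clamped to zero; larger ones, and
states beyond 1e12 molecules (runaway kinetics on a perturbed model), abort
with the last good time. Halving the tolerances changes reported maxima by
well under 0.1%.

Because dimerisation, plaque nucleation/growth and tangle aggregation are
nonlinear at low copy number, the deterministic trajectory is not the
ensemble mean; `compare_engines` quantifies the gap per species and flags
where the deterministic curve leaves the mean ± 2·SE band. Agreement is exact
for linear fixtures and improves with copy-number scaling on the nonlinear
ones (tested).

Kinetic laws imported from SBML that match neither the mass-action nor the
saturating pattern are retained as interpreted expression trees; both engines
fall back to a slower interpreted path for such networks rather than refusing
them.

## Parameter scans

Each rate constant referenced by a rate law is set in turn to 0.5× and 2×
its default (all others at default) on the deterministic day-4
passive-immunisation model — the scenario where the two engines agree best —
and the maximum of each of six outputs (soluble Aβ, plaques, phospho-tau,
tangles, activated glia, ROS) over the *whole* 12-day horizon is compared
with the unperturbed maximum. Maxima are whole-horizon, so a post-dose
rebound counts; the practical consequence is that antibody-binding constants
affect the tau outputs (whose maxima occur late) but not the plaque maximum
(which occurs before dosing). Outputs whose relative change is below 0.5% are
classed "no effect" (the threshold is exposed in the scan settings). An
integrator failure on a perturbed model is recorded as a failed cell and the
scan continues.

Ranking: for each parameter the direction (halving or doubling) achieving the
larger percentage reduction of the primary output is kept, parameters are
sorted by that reduction, and the secondary output is ranked over the same
parameter set in the same per-parameter direction, with no-effect parameters
sharing the lowest rank. Rank agreement between the primary and secondary
rankings is summarised by the Pearson product–moment correlation of the
paired ranks with a two-sided t-test p-value. Reported percentages are
conventionally rounded to 2 decimals and correlations to 3.

## Reconstruction of the base network, and what tests do and do not show

The immunotherapy extension (species, 19 reactions, all rate constants) is
built verbatim from its published description. The GSK3β/p53/Aβ/tau base
network, by contrast, is a *reconstruction*: its mechanism follows the
published description of the predecessor model, but most of its rate
constants are calibrated (as above) rather than copied, because the original
machine-readable model is not redistributed with this package. The bundled
reference SBML file (`data/reference_model_synthetic.xml`, marked synthetic)
is this package's own export of the day-4 passive model; it pins the
serialisation and exercises import against an on-disk file, but it is not the
original supplementary model file.

Consequently: qualitative results are expected to transfer — the direction of
effect of doubling each parameter agrees with the published direction table
in ~91% of cells (the agreement fraction is recomputed by
`scripts/acceptance.py`), the top-ranked plaque parameter (k_prodAbeta2,
halved) and the top tau-pathway parameters (GSK3β·p53 binding/release,
tau (de)phosphorylation) match, and every scenario-level ordering holds
(untreated has the largest plaque maximum; any immunisation lowers active
GSK3β; plaques never form at the highest clearance rate). Quantitative scan
percentages, however, depend on the exact base-constant values and differ
from the published table values (e.g. halving k_prodAbeta2 reduces the
plaque maximum by ~75% here vs 97.91% published); the corresponding
acceptance tests assert the published numbers and are expected to fail,
deliberately, as an honest record of the reconstruction gap. The same applies
to the model's plaque/soluble rank correlation (0.92 here vs 0.493
published): the published correlation is driven by four aggregation
parameters whose plaque and soluble effects decouple strongly, a regime this
reconstruction only partly reproduces.

The model emulates a cellular system, not an ageing brain: timescales are
compressed, copy numbers are unrealistically small (a real plaque holds far
more than 75 molecules), there is no spatial structure, no synaptic-activity
feedback, no proteasome inhibition by Aβ, and antibody pharmacokinetics are
reduced to first-order clearance. Passing tests therefore demonstrate the
internal correctness of the engines and analysis machinery and the documented
qualitative biology, not quantitative prediction for human disease.

## Degenerate inputs and tie-breaks

Empty networks simulate as constants and export as minimal valid SBML. An
all-zero-propensity state fast-forwards to the horizon. In `summarize_max`
ties on the maximum resolve to the earliest grid point. `rank_by_effect`
breaks percentage ties by scan order (stable sort). Events at t = 0 fire
before the first recorded sample. Event times beyond the horizon are ignored
by the deterministic engine and unreachable in the stochastic one.
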