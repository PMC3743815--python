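# Methods

## Model representation

A network model is a typed set of components (gene, mRNA, protein,
complex, compound, miRNA, pseudo, siRNA; optional compartment tag) and
typed reactions (transcription, translation, decay, complex formation,
translocation, phosphorylation, dephosphorylation, activation, miRNA
binding), each carrying a fixed mass-action law. Component ids are opaque
namespaced strings (Ensembl for gene/mRNA, UniProt for protein, ChEBI for
compound, miRBase for miRNA, internal otherwise); no id mapping is done.

Structural invariants (arity per reaction type, kind expectations,
referential integrity, clamping restricted to compounds and genes) are
checked by `validate_model`, which returns named diagnostics instead of
raising, so a model editor can list every problem at once.

### Template semantics

Transcription reads its gene and translation reads its mRNA without
consuming them: signal originates at the transcriptional level and flows
downward. miRNA binding consumes the target mRNA (repression by
degradation) and recycles the miRNA. All other reactions consume their
substrates. Clamped species (metabolic pools such as arachidonic acid, O₂,
ADP analogues) never change, preventing signal drop-out when byproducts
would otherwise run dry.

### Rate-law details decided here

* **Transcription-factor control.** The base transcription law has no TF
  term; TFs act by promoting/repressing transcription. We use the
  multiplicative form v = [G]·k·(1+Σ[TF⁺])/(1+Σ[TF⁻]), the simplest law
  that reduces to the bare one with no TFs attached.
* **Enzymatic law precedence.** The phosphorylation/activation law is read
  as v = [P]·[E]·k_e/(1+k_i·[I]), so that an absent inhibitor recovers
  plain enzymatic mass action; k_e and k_i are separate constants
  (0.35/0.2 for phosphorylation, 0.4/0.2 for activation). With several
  enzyme modifiers the enzyme term is their product; with several
  inhibitors the inhibition term is their sum. Dephosphorylation has no
  printed constant of its own and shares the phosphorylation pair.
* **Translocation.** The single printed constant 0.5 is taken as
  k_in = k_out = 0.5; a per-reaction override replaces both (one shared
  net constant).
* **Per-reaction overrides.** `RateParameters.overrides` maps a reaction
  id to a replacement for its primary constant. This is the single
  mechanism behind all perturbations and behind fixture-local choices such
  as weak receptor binding.

## Simulation

The state advances by synchronous flux propagation: every rate is
evaluated on the current state and all components are updated at once —
forward Euler on the mass-action ODE system, with the continuous-valued
semantics that the rate-law table implies (the readouts compare
real-valued steady concentrations, so discrete token firing would be the
wrong discretization). The model is compiled once into index arrays plus a
sparse stoichiometry matrix, making a step a handful of vectorized numpy
operations; there is no randomness anywhere, and identical inputs give
bit-identical trajectories.

Numerical choices:

* **Convergence** requires the maximum relative per-step change of all
  unclamped components to stay below `convergence_tol` (default 1e-6) for
  3 consecutive steps — the persistence window guards against declaring
  convergence inside a slow oscillatory transient.
* **Negative guard.** Values are clipped at zero after each step (the
  signed translocation law can overshoot at coarse steps); negative
  concentrations are not meaningful for flux propagation.
* **Stability.** Explicit updates are stable only while
  step_size × (total outflow coefficient) < 2 for every component. The
  generic default step is 0.1; `recommended_settings()` uses 0.01 with
  `max_steps` 60000 and tolerance 1e-9, sized so that fixture-scale
  enzyme cascades (outflow coefficients up to order 100 for strongly
  expressed profiles) stay well inside the stable region and steady-state
  ratios are accurate to about 1e-6. A warning fires when the step/rate
  product looks unsafe, and divergence past an overflow guard raises with
  the runaway component named.
* **Accuracy.** The fixed point of the scheme is the fixed point of the
  underlying ODE system, independent of step size; the suite checks
  agreement with an independently coded stiff integration (LSODA) to
  1e-3 relative on seeded random models, and step-size halving leaves
  steady states unchanged to 1e-4.

## Initialization

Gene components take their expression value (matched by id); miRNA
components likewise when a miRNA table is given; everything else starts at
zero except clamped/fixed species (clamped compounds default to 1.0, a
repository choice — the readout ratios are insensitive to the absolute
scale, only proportionality matters, which the suite verifies literally
for unimolecular subnetworks). Log-ratio tables must be exponentiated
first (`linearize`, base 2 by default; the base is configurable because
upstream pipelines differ). Unmatched genes default to 0 with a logged
report; a small floor can be configured instead to avoid dead subnetworks
in hand-built models.

## Perturbations

All four mechanisms are pure functions returning fresh objects:

* **siRNA**: translation of the target mRNA divided by the siRNA level;
  a bookkeeping siRNA species pinned at that level is added.
* **Degradation-promoting drug**: decay of each target protein multiplied
  by an inhibitor level ≥ 1. The NS-398 preset lists COX-2, VEGFA, IL1,
  TNF. Inhibitor levels are nowhere quantified upstream; the preset
  default of 10 is a repository choice.
* **Kinase inhibition**: the target's enzymatic contributions to
  phosphorylation/activation reactions are nulled (or scaled by a factor
  in [0,1]). Chosen over expression knockdown because the combination
  screen pairs COX-2 inhibition with small-molecule kinase inhibitors,
  and this keeps the two mechanisms orthogonal. The COX-2 arm of a
  combination uses degradation promotion on COX-2 only, matching the
  single-COX-2-inhibition comparator.
* **miRNA overexpression**: the miRNA's initial value × fold (default
  100). A zero baseline becomes fold × 0.01 so the protocol is never a
  silent no-op; with k_mi = 0.01 the floor is negligible unless folded.

Disjoint-target perturbations commute exactly (they touch disjoint
override keys), which the suite checks both algebraically and on steady
states.

## Readouts

`evaluate_hallmark` computes Σcoef·conc over the numerator divided by
(offset + Σcoef·conc) over the denominator; the ratio hallmarks (evading
apoptosis, sustained angiogenesis) carry offset 1, the sum hallmarks
(proliferation, tissue invasion) divide by 1. Missing ids resolve to 0
with a warning so partial models still evaluate.

`fca` reports perturbed/control per component and per hallmark at full
precision; rounding (2 decimals by default) happens only in the writers.
Components with control concentration 0 go to an `undefined_set` rather
than receiving ∞ or a pseudocount — a dead subnetwork has no meaningful
fold change. At steady state the flux through a readout and its
concentration are proportional, so either view gives the same ratios.

## miRNA influence score

MIS = −log₁₀(p) where p is the two-sided Wilcoxon signed-rank p-value over
the paired concentrations of all model components in control vs
overexpression steady states. Two-sided because impact, not direction, is
scored. Zero differences are dropped before ranking (the classical
convention; whole-model comparisons contain large unchanged subnetworks
and keeping zeros, as the Pratt variant does, deflates p systematically —
the variant remains available via `zero_method="pratt"`). The exact
distribution is computed for up to 25 nonzero differences by dynamic
programming over doubled midranks (correct under ties, unlike the
closed-form recursions); beyond that the normal approximation with tie
correction is used. Both branches are cross-checked: the exact one against
brute-force enumeration of all sign assignments, the approximate one
against an independent implementation.

The p-value is a deterministic impact heuristic, not a significance test:
the pairs are model outputs, not a random sample. Two consequences are
worth knowing. First, the score **saturates**: once nearly all changed
components move the same way, p has reached its floor for that n and
larger perturbations cannot raise the score further. Second, it is **not
monotone in perturbation strength**: a strong knockdown also *raises*
some concentrations (enzyme substrates and receptor pools freed from
consumption), and once those compensatory increases rank alongside the
decreases the signed-rank statistic moves back toward balance. The
guaranteed ordering is only that a no-op (fold 1) scores exactly 0 while
any real perturbation scores positive, and that is what the suite
asserts. `rank_and_average` aggregates scores per group (tumor type),
flagging extremes above/below configurable cutoffs (defaults 20 and 3,
the narrative thresholds for biomarker candidates).

## Synthetic fixtures

`build_mini_cox_model()` is a deterministic 106-component, 154-reaction
caricature of the COX pathway: COX-1/2 chains; clamped AA and O₂; the
two-step enzymatic conversion to PGH₂; five synthase-derived
prostaglandins; EP1–4 receptor chains with PGE₂:EP complexes; a PKA-like
branch downstream of the receptor complexes driving anti-apoptotic (BCL2)
and pro-angiogenic (IL8) transcription; a COX-independent EGF→EGFR→MAPK→
MYC cascade (with nuclear translocation) driving proliferation markers; an
NFκB-like arm activated by IL1β and TNF; VEGFA with a KDR-binding complex;
MMPs for invasion; and three miRNAs targeting the COX-2 mRNA. All four
hallmark readouts are wired to fixture species and every reaction type is
exercised at least once (audited by test).

Two wiring decisions matter for interpretation. EP receptor binding uses
a weak per-reaction constant (0.001) so that receptor occupancy tracks
the PGE₂ level instead of being capped by receptor synthesis — with the
default binding constant the complex-formation flux saturates at the
receptor production rate and upstream knockdowns would be invisible
downstream. And the signal-carrying steps use enzymes acting on
renewable substrates, mirroring how clamped metabolite pools prevent
signal drop-out in the full-scale setting. The fixture is larger than a
minimal toy (the mandated subsystems do not fit in fewer chains under the
three-layer discipline) but still three orders of magnitude below a
literature-scale model; passing its tests shows the machinery is correct
and directionally faithful, not that any particular biological
conclusion transfers.

`generate_random_model` builds seeded layered models (chains plus optional
activation cascades, complex links, miRNAs, hallmark wirings) honoring all
arity invariants — used for the ODE-oracle comparison and scaling smoke
tests. `generate_expression_profiles` draws log-normal(0,1) values
truncated at ±2σ (keeping any sample inside the explicit scheme's
stability margin); the distribution is an assumption of this generator,
not an estimate from data. The `low_ep` knob forces EP1–4 two orders of
magnitude below the smallest other value, emulating cell lines whose PGE₂
receptors are essentially silent; what the generator does *not* emulate
is the correlation structure, dropout and batch effects of real
expression matrices, so tests passing on these profiles demonstrate
mechanism, not robustness to real-data noise.

## Known limitations

* Forward Euler needs small steps for stiff, strongly expressed cascades;
  there is no implicit fallback (out of scope — the update discipline is
  part of the method's definition).
* Phospho-site distinctions, paralog differences and epigenetic effects
  are not representable; one protein node per id.
* Hallmark coefficients are all 1; relative influence of components on a
  hallmark is not weighted.
* The MIS saturation/non-monotonicity described above is inherent to the
  rank statistic on raw concentrations.
* The full-scale literature model is an optional external input; the
  reader accepts any model in the documented XML/tabular dialects but
  none is bundled beyond the fixture.
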