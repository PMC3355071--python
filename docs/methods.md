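# Methods

This note documents the semantics the compiler implements, the numerical
choices of the reference runtime, what the built-in fixtures and the random
model generator do and do not represent, and the design decisions taken
where the language left room.

## Language layers and lowering

The language is organized as layers, each lowered into the one below it:

1. **Biophysics layer** — components for capacitance, currents, gates,
   pores/permeabilities, permeating ions, calcium pools, experiments.
2. **Component layer** — typed, named, output-declaring components with
   arbitrary nesting and `input` wiring across components.
3. **Equation layer** — five entity kinds: parameters (`const`), algebraic
   assignments (`x = e`), relations (`fun f (a) = e`), rate equations
   (`d (x) = e`) and mass-action reactions.

Lowering proceeds in two stages. First, the component tree is mirrored as
nested environments; gates, `hh-gating-dynamics` templates and kinetic
schemes are expanded *inside their own scope*, so their equations may refer
to sibling definitions by local name. Second, the nested environments are
flattened: every entity name is prefixed with its component path (segments
joined by `_`; unnamed components contribute their type, with ordinal
suffixes for repeated unnamed siblings), and every expression is rewritten
through a chain of substitution environments (innermost scope wins; names
absent from every scope pass through unchanged, and anything that is neither
reserved nor wired raises an unresolved-reference error). Current,
pool-source and membrane-potential equations are then assembled over the
flattened names, and `input` declarations become algebraic aliases of the
source component's exported output.

Reserved globals that cross component boundaries unmangled: `v` (membrane
potential, also spellable `V` in source), `t` (ms), `celsius` (temperature,
default 22 °C), `stim` (injected current density, default 0), plus all
input-wired local names.

### Structuring rules

Enforced at validation: exactly one membrane-capacitance; at least one
current; each current has exactly one `pore` (Ohmic) *or* one `permeability`
(GHK) and exactly one `permeating-ion`; ion-specific currents need at least
one gating component, while non-specific (leak) currents may omit gating —
the idiomatic compact leak `(Ohmic-current Leak (E = …) (g_max = …))` has
none. GHK currents additionally need a valence and inside/outside
concentrations (component entities named `ci`/`co`, or `<ion>i`/`<ion>o`,
or an input-wired name). The species token of a `permeating-ion` must be a
known ion (`na`, `k`, `ca`, …) or `non-specific`. Compact currents infer
the species from the current's name; anything not recognizably an ion is
treated as non-specific, so kinetically named currents (e.g. `Narsg`)
should declare their `permeating-ion` explicitly.

### Grammar notes

The concrete grammar accepts exactly the constructs above; unknown heads are
grammar errors. Expressions are infix (`+ - * / ^`, `^` right-associative)
with function application in both `(exp x)` and `exp(x)` styles. Unit
annotations (`mV`, `uF/cm*cm`, …) are lexed as a single token when a symbol
immediately follows a numeric literal; they are echoed on output and not
dimensionally checked. Two consequences for authors: identifiers may
contain `-` (a `-` followed by a letter continues the identifier, so write
`a - b` for subtraction), and division of one bare identifier by another
needs spaces or parentheses. The documented units convention — mV, ms,
mS/cm², µF/cm², µA/cm², mM — makes `dv/dt = −Σi/C` dimensionally
consistent.

The concrete `reaction` syntax is this package's own (the concept itself is
standard):

```
(reaction name
 (transitions (<-> S1 S2 fwd rev) (-> S2 S3 fwd) ...)
 (conserve 1)
 (open O (power p)))
```

with `<->` reversible and `->` forward-only transitions, each rate a single
(possibly parenthesized) expression. `conserve` defaults to 1 (occupancy
probabilities). The transition graph must be connected and the open state a
member; the emitted per-state ODEs cancel pairwise, so the occupancy total
is conserved identically, not just numerically.

Decaying pools must define constants named `B`, `steady` and `tau`
(template-style required names, like `m_inf`/`tau_m` in
`hh-gating-dynamics`) and export exactly one concentration.

## Numerical choices

- **Reference integrator**: scipy `solve_ivp` with LSODA (stiff-capable),
  rtol 1e-7 / atol 1e-9 by default; both configurable. Tightening by 10×
  moves the HH voltage trace by ~2·10⁻⁶ mV RMS over 50 ms.
- **Steady-state initialization**: `v = v0`; pools at their resting
  concentration; HH gates at `α/(α+β)` (equivalently `inf(v0)`); kinetic
  schemes by least-squares solution of the rate matrix null space under the
  conservation constraint (singular or inconsistent systems are errors).
  Parameters and assignments are resolved lazily during initialization, in
  phases (resting-value states first, then gates, then schemes), so gate
  rates may read pool concentrations; requesting a not-yet-initialized
  state is an error rather than a silent zero.
- **IEEE semantics**: division by zero and `exp` overflow propagate as
  infinities/NaN in the evaluator, and the emitted Python routes `/`,
  `exp`, `log` and `^` through small guard helpers with identical
  semantics; Octave and NMODL targets inherit this behaviour from their
  runtimes. A side effect is that internal and emitted-code trajectories
  agree bitwise under the same integrator settings.
- **GHK singularity**: for |zFv/RT| < 1e-6 the flux uses the second-order
  series around v = 0, whose leading term is the analytic limit
  `zF(ci − co)`. Physical constants: F = 96485.33212 C/mol,
  R = 8.31446 J/(mol·K).
- **α_m singularity**: the classic removable singularity of
  `(2.5 − 0.1v)/(e^(2.5−0.1v) − 1)` at v = 25 mV is *not* guarded; adaptive
  integrators step over it, and the emitted code matches the evaluator
  exactly at every representable v.
- **Ordering**: parameters/assignments/relations are sorted by a stable
  Kahn topological sort (source order breaks ties, so generated code is
  diff-able); circular assignments, including mutually recursive relations,
  are cycle errors naming the cycle. State indices are assigned in
  insertion order and are dense.

## Code generation

All targets are emitted deterministically (byte-identical for identical
systems; no timestamps).

- **Solver target** (Python): a module with `STATE_INDEX`, `rhs(t, y,
  stim=0)`, `currents(t, y)` and `initial_state(v0)`; initialization
  reproduces the runtime's phases, solving scheme steady states with numpy.
- **Octave target**: one script with the rhs function against the standard
  solver API, one function per relation, a `ghk` helper when needed, an
  initialization function (schemes via `A \ b`) and an `ode15s` driver using
  the model's `simulation` component.
- **NMODL target** (NEURON 7.x dialect): per-current mechanisms
  (`USEION <ion> READ e<ion> WRITE i<ion>`, `NONSPECIFIC_CURRENT` for
  leaks), pools as separate accumulation mechanisms (`READ ica WRITE cai`),
  or a single merged mechanism in which pools stay internal and the file
  writes `cai` itself. HH gates solve with `cnexp`, kinetic schemes emit
  `KINETIC` blocks with `~` reactions, `CONSERVE`, and `sparse`
  (`STEADYSTATE sparse` in `INITIAL`). Reversal potentials map to NEURON's
  `e<ion>` variables, set to the model's value in `INITIAL`. Identifiers
  that cannot be mangled into NMODL-legal names are errors. Block order is
  canonical (NEURON, UNITS, PARAMETER, STATE, ASSIGNED, INITIAL,
  BREAKPOINT, DERIVATIVE, KINETIC, FUNCTION). Integer powers up to 8 are
  emitted as repeated products (NMODL has no `**`).
  A minimal equation reader (`read_nmodl_equations`) re-parses emitted
  files into canonical equation sets; merged and per-mechanism output of
  the same model yield equal sets.

## Experiments

`simulation` components carry `duration` and `stepsize` (both mandatory,
`stepsize < duration`). `voltage-clamp` components must name an existing
current; the protocol holds at `hold` for `holding-duration` ms, then steps
to a command potential for `base-duration` ms. Command potentials ascend
from `base` in `nsteps` increments of `stepsize` — the standard I–V ladder;
the language states only the phase names, so ascending-from-base is this
package's documented convention, as is the absence of a tail step. Clamped
systems differ from the free-running system in exactly one equation
(`dv/dt = 0`); channels are pre-equilibrated at the holding potential.

## Fixtures and the random-model generator

`hh_fixture` is the Hodgkin-Huxley squid-axon model in the shifted
convention (rest 0 mV, E_Na 115 mV, ḡ_Na 120 mS/cm², C 1 µF/cm²), with the
m-gate rates as printed in the compact listing this dialect is modeled on —
including a reverse rate of `0.125·exp(−v/80)` for m. With that rate the
fixture is more excitable than the textbook parameterization and does not
repolarize into repetitive firing; under a sustained suprathreshold
stimulus it crosses +50 mV within 50 ms, which is the behaviour the tests
pin down.

`kr_fixture` is a Purkinje-neuron model of the Khaliq-Raman (2003) family,
*reconstructed* from the published model literature rather than transcribed
from a verified source: the 13-state resurgent-sodium scheme uses the
Raman-Bean topology (5 closed, open, blocked, 6 inactivated states) with
its standard rate constants; the P-type calcium current uses the GHK law
with its internal concentration wired from a Traub-style decaying pool; the
BK current's `z` gate reads the pool concentration; the clamp component
carries the standard protocol (hold −90, base −40, step 10, 5 steps, 5/20
ms). It exercises every language feature — schemes, templates, GHK, pools,
wiring, clamps — but is not a validated reproduction of the original
published dynamics.

`random_model(seed, n_currents)` draws structurally valid models for
property tests: 1–2 gates per current (powers 1–4) or a 2–4-state kinetic
chain, rate expressions restricted to bounded families (sigmoids
`a/(1+e^(−(v−c)/b))` with a ∈ [0.03, 5], b ∈ [5, 20], c ∈ [−60, 40];
exponentials with |slope scale| ≥ 25 mV; constants), Ohmic or calcium-GHK
current laws, and an optional non-specific background current. Same seed,
same text. The generator does not produce pools, input wiring, relations
or multi-scheme gating, so pipeline-robustness results over random models
speak to naming, ordering and emission — the pool/wiring paths are covered
by the Purkinje fixture instead. None of the fixtures model real
experimental noise, temperature dependence (Q10), or multi-compartment
geometry; passing tests demonstrate compiler correctness, not biological
validity.

## Problem sizes used by the acceptance script

The script compiles both fixtures; compares the emitted HH rhs with a
hand-coded oracle at 100 random state points; integrates a 3-state scheme
model for 2000 ms (conservation) and HH for 50 ms (cross-target, spikes);
checks GHK limits at 41 voltages; and runs 500 random models (1–4 currents)
through parse → flatten → order → emit. These sizes make the whole script
run in seconds while leaving every check at its full stated tolerance.

## Known limitations

- No conditional expressions, events, regimes, stochastic equations, or
  spatial/multi-compartment models; no Q10 rate scaling beyond what a model
  writes explicitly.
- Units are syntax, not semantics: annotations are preserved, never checked.
- One permeating ion per current; multiple pools may not export the same
  wired name.
- The NMODL and Octave outputs are structurally correct by construction and
  cross-checked textually, but are not compiled against NEURON or executed
  under Octave in the test suite.
- Relations are kept as callable definitions (no inlining, CSE or algebraic
  simplification).
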