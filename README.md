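# ioncomp

A layer-oriented declarative language and compiler for conductance-based
models of ionic currents.

Computational neuroscientists describe membrane models in terms of
biological concepts — channel gates, maximal conductances, permeating ions,
calcium pools — but every simulator wants something different: a flat ODE
right-hand side (Matlab/Octave/scipy), or NMODL mechanism files (NEURON).
`ioncomp` reads a hierarchical, component-structured model description and
*lowers* it, concept by concept, into a single ordered system of equations,
from which it generates code for several targets. Because every variable is
renamed with its component path during flattening, several channel
mechanisms can be merged into one NMODL file without name collisions — the
layout NEURON users otherwise maintain by hand for speed.

## The model class

A model is a `Membrane-potential` component holding one
`Membrane-capacitance`, one or more current components, and optionally
`decaying-pool` components, wired together with explicit
`input (x from type name)` declarations. The lowering rules are:

- an HH-style gate `(gating m (power p) (forward-rate α) (reverse-rate β))`
  becomes `dm/dt = α(v)(1−m) − β(v)m` (or `(m∞−m)/τ_m` for the
  `hh-gating-dynamics` template, whose body must define entities named
  exactly `m_inf`, `tau_m`, …);
- a Markov kinetic scheme `(reaction …)` becomes one mass-action ODE per
  state, with `Σ occupancies = conserve` holding identically;
- an Ohmic current becomes `g = ḡ·∏ gateᵖ` and `i = g·(v − E)`;
- a GHK current becomes `i = p̄·∏ gateᵖ · Φ(v, ci, co, z, T)` with the
  constant-field flux
  `Φ = z²F²v/(RT) · (ci − co·e^(−zFv/RT)) / (1 − e^(−zFv/RT))`
  (removable singularity at v = 0 handled analytically);
- a decaying pool becomes `dCa/dt = −B·i_src − (Ca − Ca_rest)/τ`;
- the membrane equation collects every current:
  `dv/dt = (i_stim − Σ i)/C`.

Models are written as s-expressions (`.nemo`-style) or an equivalent XML
dialect; the two are interchangeable and round-trip byte-stably.
`simulation` and `voltage-clamp` components describe experiments; clamp
protocols generate scripts that replace only the membrane equation.

## Worked example

```python
from ioncomp import compile_model, fixtures, runtime

compiled = compile_model(fixtures.hh_fixture())
print(compiled.sys.state_index)
# {'Na_gating_m': 0, 'Na_gating_2_h': 1, 'K_gating_n': 2, 'v': 3}

y0 = runtime.steady_state_init(compiled.sys, v0=0.0)
print([round(x, 4) for x in y0])
# [0.6414, 0.5961, 0.3177, 0.0]

res = runtime.simulate(compiled.sys, duration=50.0, stim=15.0)
print(round(res.state("v").max(), 2))
# 111.57
```

The three gates start at their steady state `α/(α+β)` for the chosen
potential; under a sustained 15 µA/cm² stimulus the membrane fires,
crossing +50 mV (shifted convention: rest at 0 mV, E_Na = 115 mV).

The same model from the shell:

```sh
ioncomp validate hh.nemo            # structural + semantic checks
ioncomp compile hh.nemo --target nmodl --merge -o mods/
ioncomp simulate hh.nemo --stim 15 --duration 50 --out traj.tsv
ioncomp convert hh.nemo --to xml
```

`compile --target nmodl --merge` writes one `hh.mod` containing all three
currents (one `SUFFIX`, per-species `USEION`/current sums, `DERIVATIVE` for
gates, `KINETIC` blocks for schemes); without `--merge` it writes one `.mod`
per current plus one per calcium pool.

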