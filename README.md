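# nadyn

Multicompartment conductance-based neuron simulation with intracellular
Na⁺ as a first-class dynamic state variable.

Most compartmental models hold ionic concentrations fixed. `nadyn` couples
the cable equation to slow ion dynamics:

- **Na⁺ accumulation** from channel and synaptic currents
  (`d[Na⁺]ᵢ/dt = I_Na / (F·V)` per compartment),
- **conservative longitudinal Na⁺ diffusion** on the morphology tree, with
  an optional 10-fold "spine correction" of the dendritic diffusion
  coefficient,
- an **electrogenic Na⁺-K⁺ pump** (two-reaction kinetic scheme and its
  closed-form steady-state current; 3 Na⁺ out per unit outward charge),
- **Ca²⁺ handling** through a kinetic plasma-membrane Ca²⁺ pump, first-order
  buffering, GHK-flux Ca²⁺ channels and the **Na⁺-Ca²⁺ exchanger**, whose
  Na⁺-gradient dependence couples Na⁺ loading to the stable-state Ca²⁺
  level,
- dynamic **Nernst driving forces** recomputed from the evolving
  concentrations.

This makes three slow phenomena simulable on reduced "mitral-like",
"pyramidal-like" and "purkinje-like" archetype cells: spike/EPSP amplitude
adaptation via E_Na reduction, prolonged pump-driven after-hyperpolarization,
and synaptic "tagging" by prolonged local Ca²⁺ elevation (intensified by
coincident back-propagating events).

## Package layout

| module | contents |
|---|---|
| `nadyn.morphology` | segments/trees, SWC reader/writer, reduced archetype builders |
| `nadyn.membrane` | channel specs, Nernst/GHK driving forces, HH-style gating |
| `nadyn.ion_dynamics` | accumulation, flux-form diffusion, Na⁺-K⁺ pump, Ca²⁺ pump/buffer, NCX |
| `nadyn.solver` | implicit cable solve + operator-split concentration updates, traces |
| `nadyn.stimuli` | pulse trains, dual-exponential synapses, climbing-fiber volleys, stochastic distributed cortical/thalamic input |
| `nadyn.analytics` | spike metrics, sodium entry ratio, effective capacitance, E_Na / pump-current / stable-state-Ca²⁺ curves |
| `nadyn.experiments` | config-driven protocol reproductions + CLI entry point |
| `nadyn.presets` | named mechanism parameter sets for the archetypes |

## CLI

```bash
# run a YAML-configured experiment (writes a long-format trace CSV)
nadyn run experiment.yaml

# analytic curves as two-column CSV
nadyn curves ena --na-min 5 --na-max 50 --out ena.csv
nadyn curves pump --preset mitral_like --out pump.csv
nadyn curves stable-ca --voltage -70 --out stable_ca.csv

# metrics from a saved trace
nadyn analyze trace.csv spikes

# generate a distributed-input event schedule for exact replay
nadyn make-inputs --n-cortical 1000 --n-thalamic 1000 --seed 1 --out events.csv
```

Example config:

```yaml
experiment: spike_train      # synaptic_train | ca_tagging | distributed_input
cell: mitral_like
protocol: {frequency: 30.0, train_ms: 2000.0, post_ms: 2000.0}
solver: {dt: 0.025, record_every: 8}
seed: 1
output: trace.csv
```

Every experiment takes a `freeze_na` switch (frozen-concentration control);
all concentration-mediated effects vanish under it. Runs are deterministic
for a fixed seed/config; stochastic input schedules can be exported and
replayed bit-for-bit.

## Units

µm (geometry), ms (time), mV (voltage), mM (concentration), mA/cm²
(current density), nA (point current), S/cm² (conductance density),
mol/cm² (pump surface density), µm²/ms (diffusion).
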