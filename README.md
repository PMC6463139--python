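# dualosc

Deterministic modelling of how downstream reporter genes perturb an
upstream synthetic oscillator.  The circuit is the dual-feedback
("Smolen-topology") AraC/LacI oscillator in *E. coli*: an activator gene
(*araC*) and a repressor gene (*lacI*), each driven by its own hybrid
lac/ara promoter (one AraC binding site, two lac operators), so that
arabinose-activated AraC closes a positive feedback loop and LacI a
negative one.  A *gfp* reporter can be attached in three variants —
behind a second lac/ara promoter, behind a lac promoter, or behind a lac
promoter plus a transcription-free AraC decoy site — and perturbs the
oscillator through two separately switchable channels:

* **retroactivity** — reporter/decoy binding sites titrate the free
  regulatory-protein pools;
* **protease sharing** — SsrA-tagged GFP competes with the tagged
  regulators for a limited ClpXP pool, with competitive Michaelis–Menten
  kinetics `flux_x = V_max·x/(K_M + a + l + g)`.

The package is aimed at synthetic-biology modellers who want to ask, for
a given reporter design, *where* in the arabinose × IPTG plane the
circuit oscillates, how the oscillation's amplitude and period change,
and which of the two competition channels is responsible.

## What it computes

* promoter-microstate master equations (including single-tetramer DNA
  looping of LacI) assembled into the full ODE system per circuit variant
  (`dualosc.odes`);
* equilibrium points by Newton–Raphson and their linear stability by
  Jacobian eigenvalues on the conservation manifold, with a
  Routh–Hurwitz cross-check (`dualosc.stability`);
* stiff time-course integration and oscillation metrics — fixed vs
  oscillatory, peak-to-trough amplitude, period (`dualosc.timecourse`);
* two-inducer phase-diagram sweeps (black = stable fixed point, colored
  = oscillation amplitude) and sweep comparisons (`dualosc.sweep`);
* trough-count ("bottom count") scoring of fluorescence time courses and
  per-condition relative bottom counts (`dualosc.scoring`);
* a synthetic microscopy-trace generator for testing the scoring
  pipeline end to end (`dualosc.synthetic`).

## Worked example

```python
from dualosc import (CircuitConfig, ParameterSet, InducerCondition,
                     assemble_odes, integrate, extract_oscillation_metrics,
                     GridSpec, run_sweep, compare_sweeps)

params = ParameterSet()        # recorded default kinetics
cond = InducerCondition(arabinose=1.0, iptg=0.01)   # % w/v, mM

system = assemble_odes(CircuitConfig(reporter_kind="lac_ara"), params, cond)
traj = integrate(system, system.initial_state(), t_end=800.0)
m = extract_oscillation_metrics(traj)
print(m.classification, round(m.period, 1),
      {k: round(v, 1) for k, v in m.amplitude.items()})
```

prints

```
oscillatory 35.4 {'laci_free': 112.1, 'arac_free': 656.9, 'gfp': 1472.8}
```

— at high arabinose and low IPTG the lac/ara-reporter circuit sustains a
35-minute oscillation with a free-LacI swing of ~112 molecules/cell.
Sweeping a reduced 7 × 8 sub-grid of the full inducer ranges for the two
reporter designs:

```python
spec = GridSpec(n_ara=7, n_iptg=8)
la = run_sweep(CircuitConfig(reporter_kind="lac_ara"), params, spec, t_end=800.0)
l = run_sweep(CircuitConfig(reporter_kind="lac"), params, spec, t_end=800.0)
print(la.oscillation_area, l.oscillation_area)
print(compare_sweeps(la, l)["symmetric_difference"])
```

prints `16 12` and `4`: replacing the reporter's lac/ara promoter by a
lac promoter shrinks the oscillatory region (the lac reporter makes more
GFP, loads the shared protease harder, and stabilises the high-IPTG edge
of the region).  Running the same sweeps with the competition toggles off
(`CircuitConfig(..., retroactivity_on=False, protease_sharing_on=False)`)
makes all three reporter variants' maps identical.

The same pipeline is scriptable from the shell:

```sh
dualosc sweep --reporter lac --n-ara 7 --n-iptg 8 --plot --out-dir out/
dualosc simulate --reporter lac_ara --ara 1.0 --iptg 0.01 --out traj.tsv
dualosc gen-panel --regime sustained --out panel.tsv
dualosc score panel.tsv --out scores.json
```

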