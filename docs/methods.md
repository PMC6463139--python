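# Methods

## The circuit and its model

The model describes a dual-feedback synthetic oscillator in *E. coli*: an
activator gene (*araC*) and a repressor gene (*lacI*), each transcribed
from its own copy of the hybrid lac/ara promoter, which carries one AraC
binding site and two lac operators.  AraC (a dimer, active with arabinose)
activates both genes; LacI (a tetramer, inactivated by IPTG) represses
both, closing interlinked positive and negative feedback loops.  A
downstream *gfp* reporter can be attached in three variants: behind a
second lac/ara promoter, behind a lac promoter (two operators, no
activator site), or behind a lac promoter plus a transcriptionally inert
AraC "decoy" site that equalises the total binding-site census with the
lac/ara variant.  All three proteins carry SsrA degradation tags and are
degraded by a limited pool of ClpXP protease.

State variables are molecules per cell and time is in minutes: free AraC
dimers `a`, free LacI tetramers `l`, free GFP `g`, one mRNA pool per gene,
and the occupancy (copies/cell) of every promoter microstate.

### Promoter microstates

Each promoter class is a continuous-time scheme over site-occupancy
patterns, turned into mass-action master equations weighted by plasmid
copy number.  A two-operator promoter takes five LacI patterns — empty,
either single operator bound, both bound by two tetramers, or looped by a
single tetramer bridging both operators — and promoters with an AraC site
take the product with bound/unbound.  Looping follows the
single-tetramer picture: a singly bound tetramer forms the loop at
`k_loop`, the loop opens back to a singly bound pattern at `k_unloop`,
and the looped complex dissociates from DNA entirely at `k_loop_diss`,
releasing its tetramer.  Repressed states are silent; an AraC-dependent
promoter transcribes at the activated rate with AraC bound (basal
otherwise); the lac reporter promoter transcribes at its maximum whenever
unrepressed.  Because every transition moves occupancy between states of
one class, the per-class occupancy sum is conserved exactly — this is
used as a structural invariant in tests and in the stability analysis,
where the conservation laws contribute structural zero eigenvalues that
are projected out before classification.

### Inducer response

Arabinose activates AraC binding through a Hill curve with a small leak
floor; IPTG inactivates LacI through a Hill curve and, independently,
weakly inhibits the arabinose-dependent part of the AraC response (so the
AraC floor is IPTG-independent).  Active fractions multiply the
respective DNA on-rates.

### Degradation, dilution and the two competition channels

All free tagged proteins share one saturable protease:
`flux_x = v_max * x / (k_m + a + l + g)`.  The two perturbation channels
of a downstream reporter are independently switchable:

* **retroactivity off** — downstream (reporter/decoy) sites stop
  sequestering the free pools while their occupancy still evolves
  ("sense but do not consume"), keeping downstream occupancy observable;
* **protease sharing off** — GFP is degraded by an identical but
  independent enzyme channel, leaving the `a`/`l` denominator to the
  regulators alone.

First-order dilution acts on proteins and mRNA, never on DNA copy number
or promoter-state identity.  DNA-bound protein is protected from the
protease.

## Why the oscillation needs slow operator kinetics

Both regulator genes are driven by identical promoters and degraded
symmetrically, so the free AraC and LacI pools ride nearly in phase; with
fast multimerisation the repressor arm has no intrinsic lag and the
deterministic mean-field system relaxes to a fixed point almost
everywhere.  The delay that sustains deterministic oscillation here is
carried by the DNA-binding stage: LacI-operator association and
dissociation (and loop turnover) are slow relative to protein turnover,
so repression occupancy is a low-passed, lagged copy of the LacI pool.
Combined with near-zero-order (saturated) protease degradation this
yields relaxation oscillations: an activation burst, delayed operator
occupation and looping, a production shut-off, a protease-driven crash of
the free pools, and slow loop turnover that releases the promoters for
the next burst.  The default kinetic constants were accordingly fixed in
the slow-operator (LacI-operator residence ~13 min, loop persistence
~23 min), deeply saturated protease regime (K_M of a few molecules),
with a steep arabinose response centred in the upper part of the sweep
range so that sub-threshold arabinose cannot ignite the positive
feedback even when the protease is loaded.  Per-field provenance lives
in `dualosc.params.PROVENANCE`; the set is a model parameterisation of
this package, chosen once so that the default circuit reproduces the
documented regime structure, not a fit to any dataset.

## Stability analysis

Equilibria are found by damped Newton-Raphson on the assembled RHS.  The
per-class conservation laws make the Jacobian structurally singular, so
the Newton step solves the stacked least-squares system `[J; C] s = [-f;
0]` (C = conservation rows), which keeps iterates on the invariant
manifold, and stability is classified from the eigenvalues of the
Jacobian restricted to that manifold's tangent space.  Real parts within
`1e-8` (scaled) of zero are flagged marginal.  A Routh-Hurwitz array on
the characteristic polynomial (standard epsilon substitution for zero
pivots) cross-validates the eigenvalue decision on systems of dimension
<= 12 — beyond that the polynomial coefficients are too ill-conditioned
to be informative — and any disagreement is surfaced as a warning, never
silently resolved.

## Sweeps and classification

Each grid cell of the two-inducer plane (defaults: 21 log-spaced
arabinose points on [0.01, 1.0] %, 46 log-spaced IPTG points on [0.001,
31.6] mM) is classified stability-first: Newton-Raphson equilibria are
sought from a fixed seeding (a low/mid/high protein lattice plus the
endpoint of a 300-min burn-in from the standard low-protein initial
state), roots with negative molecule counts are rejected as unphysical,
and a cell with a stable physical equilibrium is a stable fixed point —
the phase diagram's black region — even when a limit cycle coexists.
Only cells without a stable equilibrium are integrated, to measure
amplitude and period.  Deciding by asymptotic stability rather than by a
finite trajectory matters here: near bifurcation boundaries the loaded
circuits produce weakly damped spirals whose transients ring above any
amplitude threshold for thousands of minutes, and a trajectory-based
verdict at a practical horizon misclassifies them.

For the integrated (unstable) cells, a trajectory is oscillatory iff at
least three peaks are found (two full periods) and the peak-to-trough
amplitude over the last full cycles exceeds 1 molecule per cell — below
one molecule the deterministic description is meaningless, so
sub-molecule swings are never called oscillations.  Amplitude is
peak-to-trough (recorded in metadata); the period is the mean inter-peak
interval.  Tests and the acceptance script run reduced 7 x 8 sub-grids of
the same ranges with a 800-min horizon and solver tolerances 1e-6 — the
problem sizes this package uses for its routine checks; the full grid is
available through the same API and CLI.

## Trace scoring

Fluorescence time courses (3-min sampling over 3 h) are smoothed with a
3-sample moving average; local minima count as oscillation bottoms when
their prominence is at least 0.3 of the post-smoothing range *and* the
trough is at least 6 samples wide at half prominence.  A trace with >= 3
bottoms is scored oscillating; the per-condition fraction of such traces
is the relative bottom count.  Both criteria are trace-relative, so
scoring is invariant to intensity rescaling.  The width criterion is
essential: with uncorrelated multiplicative noise, narrow noise dips pass
any range-relative prominence threshold at a rate independent of the
noise scale, whereas genuine oscillation troughs are wide (about a
quarter period).  With these defaults, measured on 200 fixed-seed
synthetic traces per regime, a flat noisy trace passes the 3-bottom rule
at rate 0.017 while the default sustained oscillation passes at 0.995.
The cost is reduced sensitivity to periods below ~35 min and, within the
3-h window, any oscillator slower than ~60 min can never reach 3 bottoms
— the same window limitation the experimental design has.

## Synthetic traces

The generator emulates per-colony microscopy: a baseline with optional
linear drift, a (possibly damped) sinusoid, i.i.d. multiplicative
Gaussian noise (default scale 0.05, matching "weak fluctuations" of
constitutive expression; the true in-vivo noise magnitude is not known
numerically and the scale is config-exposed), clipped positive.  Defaults:
180 min duration, 3-min interval, baseline 100, amplitude 40, period 40
min.  Per-trace seeds derive from (master seed, cell index, replicate),
so panels are reproducible under partial regeneration.  The generator
does not emulate cell growth, lineage segmentation errors, background
subtraction artefacts or photobleaching — so passing scores on synthetic
panels validate the scoring pipeline's logic, not its robustness to those
real-data effects.  Model-derived traces resample the free-GFP variable
of a trajectory over the final 3-h window at the microscopy interval and
apply the same noise model.

## Known limitations

* The kinetic constants are a recorded, literature-scale default set, not
  a published parameterisation; quantitative amplitudes/periods are
  indicative only, while the structural toggle identities hold for any
  parameters.
* Mean-field master equations ignore molecular noise; the paper-scale
  regime where pools fall below one molecule per cell is treated as
  non-oscillatory by the amplitude threshold rather than resolved
  stochastically.
* Host-level resource competition (RNA polymerase, ribosomes) and
  cell-growth feedback are out of scope.
* The Routh-Hurwitz cross-check is informative only for small systems;
  for the assembled circuits the eigenvalue decision stands alone.
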