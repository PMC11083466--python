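# Methods

## Model

The apparatus is modelled as two gas spaces in series.

**Lung compartment.** A well-mixed volume equal to a residual volume
(default 30 mL — a calibration syringe is never fully emptied) plus the
piston displacement. There is no gas exchange: no oxygen is consumed and no
CO2 added, matching the mechanical bench this package emulates. A
consequence used throughout is that expired gas carries the lung's current
O2 fraction, and the steady state is independent of the residual volume
(verified to < 0.05 pp when the residual is doubled); the residual only
sets the wash-in time constant.

**Upper-airway dead space.** A plug-flow column of fixed total volume,
implemented as exact variable-volume first-in-first-out parcels (adjacent
parcels of identical composition are merged, which loses nothing). This is
the infinite-resolution limit of a discretized column; the `n_cells`
geometry field is retained as a configuration contract but the numerics do
not diffuse the stored-oxygen front at any resolution. The default volume
is 5.2 mL (the airway replica's water-displacement volume), reduced by a
1-mL rod for VT < 10 mL and extended to `0.10 × VT` above VT 50 mL — a
weight-proportional anatomical dead space, exposed as configuration because
the bench's expandable-tube volumes are not published.

**Cannula interaction.** During inspiration with piston flow Q(t), gas
enters the nares as pure supply at rate `min(Fc, Q)` plus room air
(O2 0.21) at rate `max(Q − Fc, 0)`. Whenever the cannula flow exceeds the
instantaneous airway flow (either phase), the excess `Fc − Q` *flushes* the
nares end: it grows a pure-supply front there while an equal volume of
resident gas from beyond the front is vented. The front grows only while
airway flow is below the cannula flow; piston-driven expiratory flow sweeps
it back out. Gas deposited in the low-flow tail of expiration therefore
survives to be inhaled first on the next breath — the upper-airway
reservoir effect that makes measured FiO2 exceed the no-reservoir closed
forms at low minute ventilation. (A strictly local reading of
"replacement at equal volume" — vent exactly what was just injected —
degenerates into a treadmill that stores nothing and makes the steady state
independent of the expiratory profile; it was rejected on those grounds.)
Jet momentum, prong leak geometry and any CPAP effect are not modelled.

**Oxygen bookkeeping.** Lung O2, column O2, cumulative supplied, entrained
and vented O2 are tracked incrementally; the largest relative drift of the
balance at any time step is reported per run (typically < 1e-12, asserted
< 1e-9 in tests).

## Waveforms

Piston flow is integrated at `dt = 1 ms` using exact per-step volumes
(differences of the closed-form cumulative displacement, so each phase
moves exactly VT regardless of dt; halving dt moves the steady state by
< 0.05 pp). Three shapes:

- `square` — constant flow in each phase; the degenerate shape for which,
  with zero dead space, the steady state equals the Benaron–Benitz closed
  form (the oracle used in testing);
- `half_sine` — velocity-ramped piston, symmetric in both phases;
- `passive` (default) — half-sine inspiration and passive exponential
  expiration with time constant `0.22 × Te` (≈ 4.5 time constants per
  expiration, so end-expiratory flow decays to ~1% of its peak).

The true motor velocity profile of the rig this emulates is unpublished,
and the steady state at low MV is governed almost entirely by how long the
expiratory flow stays below the cannula flow. The passive shape is the
physiologically sensible choice (tidal expiration is passive, with a long
low-flow tail), and its time constant is the one deliberately calibrated
parameter of the package: τ/Te = 0.22 minimizes the RMS error (2.9 pp)
against the 24 published bench averages across VT 5–80 mL and flows
0.1–1 L/min, and puts the low-MV reference point (VT 5 mL, Ti 900 ms,
RR 30, 0.1 L/min) at 67.0% against the bench's 65.7%. With a symmetric
half-sine expiration the same point sits ~6 pp lower; remaining cell-level
discrepancies of up to ~6 pp (e.g. VT 10 mL cells) reflect mixing behaviour
of the physical rig that a single-τ profile cannot capture.

## Steady state and convergence

A run starts from a chosen uniform gas state (room air for wash-in; pure O2
with the cannula off reproduces the between-run wash-out, which returns to
21%). The reported FiO2 is the lung fraction at end-inspiration. Breathing
repeats until the end-inspiratory fraction changes by < 0.01 pp over three
consecutive breaths, with two safeguards:

- the test may not fire before the inspired volume has displaced roughly
  three apparatus volumes — with VT below the dead-space volume the wash-in
  front percolates slowly and the trace is deceptively flat early on;
- the reported value is the geometric (Aitken) extrapolation of the last
  three trace points, since multi-breath wash-in is geometric; this makes
  the result insensitive to exactly where the stopping rule fires and to
  the residual volume.

Runs not converged within 500 breaths are flagged (`converged=False`) but
still report the extrapolated value.

## Synthetic dataset

`generate_dataset` reproduces the bench protocol: every feasible grid
scenario × each cannula flow, simulated once, then read in triplicate with
additive Gaussian noise of SD 0.15 pp (the published replicate SDs are
0.1–0.2 pp), clipped to [21, 100], under a caller-supplied seed. The
generator emulates steady-state readings of a noise-free deterministic rig;
it does not emulate breath-to-breath variability, gas exchange (a prior
bench estimate puts that bias at 0.7–1.6%), humidity/temperature effects,
or drift of the oxygen analyzer. Passing tests on this dataset validate the
mixing model and the analysis stages, not in-vivo oxygen delivery.

## Analysis stages

**Power law.** `FiO2(MV) = 21 + k·MV^(−a)` is fitted by bounded
least squares on the original FiO2 scale (k ∈ (0, 1e7], a ∈ (0, 5],
objective tolerance 1e-10); a log–log regression of `FiO2 − 21` on MV over
points more than 0.05 pp above the room-air floor provides starting values
only, while floor points stay in the nonlinear objective. R² is
`1 − SS_res/SS_tot` on the FiO2 scale. Fits use replicate-averaged cells,
matching the protocol's "average of three experiments". Fewer than three
points above the floor raises a degenerate-fit error; no alternative
functional forms are compared.

**Formula bias.** Signed differences (formula − simulated, pp) are computed
per replicate-averaged cell; rank-sum tests take the replicate-level
triplicates. The Mann–Whitney U uses midranks; the two-sided p-value is an
exact full enumeration of rank assignments for n1 + n2 ≤ 12 and the
tie-corrected normal approximation (with continuity correction) above.
Threshold summaries scan the exact grid MVs in increasing order and report
the smallest m such that every MV bin from m upward has |mean bias| within
the threshold (inclusive at the boundary), with an explicit absent value
when no m qualifies.

**Charts.** Each chart cell (weight × RR at fixed VT/kg and flow) is the
simulated steady state at `VT = vt_per_kg × weight` and the representative
Ti for that RR — the largest grid Ti whose Ti/Te ratio stays in the
feasibility window (slower breaths take longer inspirations; this choice
also reproduces how the published chart values line up with the single-Ti
bench readings). Cells with VT above the 30-mL design cap, or at an RR with
no feasible Ti, are absent rather than extrapolated. Cells below the bench's
VT range (e.g. 0.5 kg at 5 mL/kg gives VT 2.5 mL, below the dead-space
volume) are extreme extrapolations of a no-gas-exchange model and converge
toward the supply concentration; they should be read as "rebreathing
dominates", not as clinical predictions. Chart values assume 100% supply;
the blender correction `21 + (chart − 21) × blender/100` rescales them.

## Problem sizes and determinism

The default grid yields 100 scenarios; the full dataset is 400 steady-state
simulations (× 3 replicate readings = 1200 rows) and completes in well
under a minute, as do the acceptance recomputation and the test suite's
shared noise-free dataset. All randomness (replicate noise, sampled oracle
checks, recovery simulations) flows from explicit seeds; pipeline runs with
the same seed are byte-identical, and the run manifest echoes the full
configuration needed to reproduce any output file.

## Known limitations

- The flush model is volumetric; real cannula jets entrain and mix, so the
  stored front is sharper in the model than in reality.
- A single expiratory time constant for all scenarios is a simplification;
  the residual per-cell error against the published bench values is up to
  ~6 pp at intermediate VT.
- No gas exchange means simulated FiO2 is biased slightly high relative to
  a breathing infant, and tiny-VT chart cells saturate unrealistically.
- High-flow cannulas (> 2 L/min), blended-supply simulation (handled only
  through the closed-form correction), humidity/temperature effects and
  analyzer dynamics are out of scope.
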