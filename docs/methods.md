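# Methods

This note documents the models implemented in `colisim`, their
assumptions, the parameters that matter, and where values are literature
constants versus package calibrations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Engine semantics

A simulation state is a tree of stores; leaves are variables with a
schema (units, updater, divider, emission flag, free-form properties such
as molecular weight). Processes view only the stores wired to their
declared ports and return updates; the engine rejects any update touching
a variable outside the issuing process's ports.

Scheduling: every process declares its own time-step. The engine tracks a
temporal front and invokes due processes in sorted-name order, applying
their updates in the same order before advancing. Time is kept as exact
rationals, and all time-steps must be commensurate (share a modest common
cycle); configurations like {1.0 s, π/3 s} are rejected at construction
rather than allowed to drift. Update-order ties between processes writing
one variable in the same front advance are resolved by sorted process
name; additive (`accumulate`) updates are order-independent, and for
`set` updates the rule makes the outcome deterministic and reproducible.
Runtime-adjustable time-steps are not supported; the schedule is declared
at construction.

Randomness: one global seed; each stochastic process draws from a child
stream keyed by (seed, CRC32 of its name), so results do not depend on
how many other processes exist. Identical configuration and seed replay
bit-identically (tested).

Division: a process sends a `divide` topology message; the agent subtree
is split per-variable by the dividers — `halve` for continuous amounts,
`binomial` (exactly conserving) for counts, `copy` for configuration,
`split_list` for sub-compartments such as flagella, which are alternately
assigned — and a registered composer instantiates fresh processes for
each daughter. Polymerase positions held inside expression processes are
thereby reset at division, matching the fixed per-cell polymerase budget.

Emission: variables flagged `emit` are recorded every `emit_interval`
(default 1.0 s) as flat path → value records, written as JSONL or CSV.

## Environment

Bodies are 2D capsules with overdamped dynamics: velocity = force /
translational damping, angular velocity = torque / rotational damping; no
inertial transient, consistent with micron-scale low-Reynolds physics.
Thermal jitter is one force of fixed magnitude per step, uniform random
direction, applied at a uniform random point along the axis (the
distribution is a package choice; only its scale matters here). Volume
exclusion pushes overlapping capsules apart along the minimal
segment–segment separation; walls reflect. Fields diffuse by a flux-form
explicit scheme (stability bound D·dt/h² ≤ 0.25 enforced) with no-flux
boundaries, conserving total content to machine precision. An agent's
local environment is the single bin containing its centroid; uptake is
floored at bin availability with the shortfall reported back.

Damping and jitter defaults are calibrations (see Chemotaxis below);
jitter defaults to 0.002 pN so that a non-motile cell reorients slowly
compared with ~1 s runs.

## Growth and division

Minimal agents grow as m·2^(dt/τ) with τ = 2400 s and divide when
m ≥ 2000 fg from an initial 1000 fg; the check runs once per 1.0 s step,
so up to one step of overshoot is accepted. Daughters inherit the
mother's phylogeny color perturbed by an isotropic Gaussian step
(σ = 0.08 in RGB space, clipped to [0,1]) on their first step, so the two
daughters diverge independently.

## Transport and metabolism (dFBA / iFBA)

FBA maximizes the flux of an implicit biomass reaction that drains the
objective composition from the steady-state network (S·v = 0, bounds),
solved with HiGHS via `scipy.optimize.linprog` — deterministic for a
fixed problem. Degenerate optima are reported as the solver returns them;
tests assert objective values only. Infeasibility is reported explicitly
and treated as a zero-growth step.

Transport computes each sugar's flux by convenience kinetics,
rate = kcat·E·Π_s (s/Km)/(1 + s/Km + Σ I/Ki), and pins it as an equality
bound on the matching exchange reaction, so metabolism uses exactly what
transport supplies. Units: one "count" is a lumped 1e-12 mmol (~6e8
molecules), chosen so a molecular weight in g/mol is numerically fg per
count. With mass-consistent stoichiometry this makes environment mass
loss equal cell mass gain exactly (tested to 1e-9 relative).

The packaged toy network: glucose (180) → 2 precursor (90); lactose (342)
→ glucose + galactose (162); galactose → 1.8 precursor; biomass = the
precursor pool. Kinetic defaults (GalP: kcat 6e-5 s⁻¹·count⁻¹, Km 0.1 mM,
100 transporters; LacY: kcat 2e-5, Km 1.0 mM) and the minimal stochastic
LacY model (Hill-repressed transcription, K = 0.02 mM, h = 2; first-order
mRNA decay 0.02 s⁻¹; translation 0.05 s⁻¹ per mRNA; growth-dilution loss;
chemical-Langevin noise ∝ √(rate·dt)) are calibrated, not literature
constants, so that the single-compartment diauxie shows its three regimes
— glucose-fed growth, a depleted-glucose trough, and LacY-gated lactose
growth — within ~1500 simulated seconds in a 2e-12 L environment bin
(50 × 50 × 0.8 μm). These scaled-down conditions replace genome-scale
runs: the iAF1260b adapter (`load_bigg_json` / `load_sbml`, via cobra)
exists but requires a downloaded model and is not exercised by tests.
The LacY model reads the *external* glucose concentration as its
repression signal; the toy network's internal pools hold only the lumped
precursor, so external glucose is the meaningful catabolite signal at
this resolution.

## Gene expression

Binding is stochastic, elongation deterministic: within each 1.0 s step,
polymerase/ribosome binding events are drawn by the Gillespie direct
method, then every bound polymerase advances at its fixed rate (RNAP
50 bp/s, promoter freed after 30 bp; ribosome 22 aa/s, 50 bp occlusion
between ribosomes on one message), consuming template-matched monomers
and hydrolyzing ATP→ADP (1 per nucleotide transcribed or degraded, 2 per
amino acid). Elongation stalls in place when a monomer or ATP runs out;
partial chains persist. Promoter propensity is the basal affinity times a
binary-sum gate: each TF site is occupied when its TF count exceeds its
threshold and contributes its coefficient (positive activation, negative
repression), floored at zero. Degradation removes whole transcripts at a
Michaelis–Menten rate in transcript count scaled by endoRNAse, with a
fractional carry between steps; proteins are never degraded — their loss
is dilution and division.

The flagellar fixture encodes seven operons in the three-class cascade
(flhDC; five FlhDC-activated class-2 operons with staggered thresholds,
among them fliAZY and flgMN; FliA-dependent fliC) with staged complex
assembly (monomers → basal body → hook → flagellum) at the
order-of-magnitude 1000 s⁻¹ complexation propensity, and FlgM
sequestration of FliA as a complexation reaction. FlgM relief is
triggered: once the first basal body has been assembled, free FlgM is
removed (export) and sequestered FliA released. Operon sequences are
synthetic placeholders at scaled lengths (240–480 bp; real operons are
kilobases) generated deterministically, so per-base accounting is exact
while desk-scale runs finish in seconds; promoter affinities, thresholds
and RBS affinities are calibrated to give sustained flagellar synthesis
with the fixed budget of 10 RNAPs and 20 ribosomes. Passing the
just-in-time ordering test (median first-appearance master < class 2 <
late over replicates) therefore demonstrates the cascade mechanism, not
the real operons' kinetic constants.

## Chemotaxis

**PMF.** Goldman–Hodgkin–Katz over K⁺, Na⁺, Cl⁻ plus a constant pH term
(−2.303·RT/F·ΔpH). The packaged ion concentrations (K 300/5, Na 10/145,
Cl 6/110 mM in/out; permeabilities 1 : 0.02 : 0.01) and ΔpH = 0.6 at
310 K are calibration constants giving −134 mV total. Flagellar rotation
(~100 Hz) moves 1200 protons per revolution; the flux is bookkept and the
gradient treated as instantly restored.

**Receptors.** MWC cluster of 6 Tar + 12 Tsr (1:2). Free energy per
receptor: ε(m) = 1.0 − 0.5·m (kT) plus ln((1+c/K_off)/(1+c/K_on)) with
MeAsp constants K_off/K_on = 0.02/0.5 mM (Tar) and 100/10⁶ mM (Tsr) from
the standard MWC parameterization of this system. P_on = 1/(1+e^F).
Methylation (m ∈ [0, 8]) integrates dm/dt = 0.15·(P₀ − P_on) toward the
baseline activity P₀ = 1/3, giving exact adaptation for any sustained
step within the methylation range; larger steps need larger methylation
shifts and adapt more slowly. Composites initialize m adapted to the
ambient concentration, so uniform-field motility is at baseline from
t = 0.

**CheY-P and switching.** Steady-state CheY-P is a Michaelis map of
activity normalized so P₀ ↦ 2.59 μM. Switch rates follow the free-energy
barrier form ΔG = g0/4 − (g1/2)·Y/(Y+K_d), k± = ω·e^∓ΔG, with
g0 = g1 = 40 kT, K_d = 3.1504 μM, ω = 0.6643 s⁻¹. These are calibrated:
at baseline they give k₊ = 0.250 s⁻¹ and k₋ = 1.763 s⁻¹, chosen so the
veto rule over four flagella yields a 1.0 s mean run (1/(4k₊)) and a
0.70 s mean tumble (birth–death first-passage time back to all-CCW).
The switch requires dt ≤ 0.01 s and rejects larger steps.

**Forces.** Run thrust = 0.31 pN · (|PMF|/140 mV) · (1 + log₁₀ n) for n
bundled flagella — the logarithmic bundling law is anchored to both
printed thrust values (0.31 pN at n = 1; 0.497 pN at n = 4). During a
tumble the CCW flagella's thrust is applied at a random angle drawn once
per tumble episode, producing torque thrust·(L/2)·sin(angle); the tumble
thrust magnitude equals the run formula for the coherent CCW subset (the
choice of equal-magnitude off-axis thrust is a package decision).
Translational damping 0.033707 pN·s/μm sets the 14.1 μm/s run speed from
the ~0.475 pN thrust at the Goldman PMF; rotational damping 0.08
pN·μm·s/rad is calibrated by simulation so the mean reorientation between
runs is ≈70°. These four statistics (speed, run, tumble, angle) are the
calibration's acceptance surface and are measured end-to-end by
`scripts/acceptance.py` and the test suite, over five 300 s seeds at
dt = 0.01 s.

## Problem sizes and scaled-down runs

Desk-scale substitutes for the large simulations: single-compartment
diauxie (1500–1800 s, one cell) in place of population-scale diauxie;
900 s flagellar-expression runs with the scaled seven-operon fixture in
place of 15,000 s colonies; gradient climbing measured over 60 s with six
agents (half with defunct receptors) in place of the eight-minute
twelve-agent arena. The gradient (c₀ = 0.05 mM at the start line,
λ = 150 μm) is chosen so a 1 s run changes ligand by ~10%, inside the
Tar-sensitive range — the paper-scale geometry is configurable but not
the tested default.

## Known limitations

- Ribosome occlusion is enforced per transcript species, not per mRNA
  copy, which is conservative when many copies of one message exist.
- The toy metabolism's transporter counts do not scale with cell mass, so
  toy growth is linear, not exponential; exponential growth is exercised
  by the minimal growth/division agent.
- 2D only; no hydrodynamics, no periodic boundaries, no PMF depletion by
  motor load, no Trg/Aer receptors, no tRNA charging or protein
  degradation.
- Thread/cluster distribution and runtime time-step adaptation are out of
  scope; the scheduler is single-threaded and declarative.
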