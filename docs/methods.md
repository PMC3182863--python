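# Methods

## The model

`sarcsim` represents a muscle fiber as `n_series` half-sarcomeres in
series per myofibril, with `n_myofibrils` myofibrils in parallel that may
be coupled by springs between corresponding z-disks. Each half-sarcomere
produces stress (force per cross-sectional area, N m⁻²) from two sources:

**Cross-bridges.** Myosin heads cycle through three states — detached
(D), attached pre-powerstroke (A₁), attached post-powerstroke (A₂) — in
the tradition of Huxley-style distribution models. Attached states are
resolved on a uniform cross-bridge strain axis (default [−12, 12] nm in
0.25 nm bins); the detached pool is a single number. The head density
available to cycle is `n₀·ζᵢ·ψ(t)·φ(ℓᵢ)`: head density n₀ = 1.15×10¹⁷
m⁻², per-unit strength multiplier ζᵢ, imposed activation ψ, and a
piecewise-linear overlap fraction φ (zero below 800 nm, plateau at 1 for
1150–1300 nm, zero again at 1700 nm — placing the conventional test
lengths on the correct limbs of the length–tension relation). When the
available count changes (activation ramp, overlap change), all pools are
rescaled proportionally. Active stress is
`k_cb·[Σ a₁(x)·x + Σ a₂(x)·(x + x_ps)]` with k_cb = 1.0×10⁻¹² N per head
per nm and powerstroke displacement x_ps = 10 nm.

**Passive elasticity.** `F_pass = ξᵢ·σ_p·(exp((ℓ−ℓ₀)/λ) − 1)` with
(σ_p, ℓ₀, λ) = (112 N m⁻², 625 nm, 136 nm), continued linearly with
matched slope below ℓ₀ so passive stiffness is positive everywhere. ξᵢ
is the passive heterogeneity multiplier.

**Heterogeneity.** ζᵢ ~ 𝒩(1, α²) and ξᵢ ~ 𝒩(1, β²), redrawn while
≤ 0.05; α and β are standard deviations (coefficients of variation).
Heterogeneity is the model's *only* stochastic source: with α = β = 0
every ensemble member is identical and no residual enhancement occurs.
Ensembles derive one child seed per member from a master seed with a
counter-based scheme (`SeedSequence((master, index))`).

## Rate laws

The transition rates (units s⁻¹, strains nm) are:

| transition | law | default |
|---|---|---|
| D → A₁ | total rate f₀, Gaussian weights (width σ_f) around zero strain | f₀ = 8, σ_f = 0.7 |
| A₁ → A₂ | k₃₀ / (1 + exp(−(x + x_ps)/x_k3)) | k₃₀ = 75, x_k3 = 1 |
| A₂ → A₁ | constant k₋₃ | 5 |
| A₁ → D | g_a1 + shared strain term | g_a1 = 8 |
| A₂ → D | g₀ + shared strain term | g₀ = 10 |

The shared strain-sensitive detachment has two parts, capped at
g_cap = 900 s⁻¹ so the explicit update is stable at dt = 1 ms:

* a **detachment barrier** `g_det·(x/x_det)⁸` (g_det = 30, x_det = 6 nm):
  negligible at working strains but overwhelming within a few nm of the
  axis ends. The eighth power matters: a shallower (e.g. quartic) law is
  already strong at +3–5 nm, so stretching depletes bound heads faster
  than attachment replaces them and force *falls* during stretch instead
  of rising.
* a **slip term**: g_slip = 850 s⁻¹ switched on sigmoidally (width
  0.3 nm) below x_slip = −0.3 nm. Compressed heads that oppose
  shortening release quickly — the classic detachment asymmetry of
  Huxley-type schemes. It gives units a realistic maximal shortening
  velocity and makes slow shortening nearly force-neutral; without it,
  the shortening imposed on a chain by one yielding unit collapses the
  chain's force and the network oscillates violently.

These laws are structural stand-ins, calibrated once against the
single-unit ramp-and-hold shape (force rises during stretch, then decays
back to the isometric value within a second) and the magnitude of the
standard-protocol ensemble enhancement, then frozen. At the defaults the
isometric working point at full activation on the plateau has duty ratio
≈ 0.10 and active stress ≈ 8×10⁴ N m⁻²; passive stress is 9.5% of active
at 1200 nm and dominates beyond ≈ 1600 nm.

## Numerics

Each time step (default dt = 1 ms) is operator-split: (1) refresh
available pools at the current lengths and activation, (2) one explicit
kinetics step (stability guard: dt × max total exit rate < 1; negative
occupancies from round-off are clipped into D), (3) re-balance lengths at
the imposed total length, advecting bound profiles by each unit's length
change with conservative linear interpolation, which preserves the total
and the first strain moment exactly. Because of that exactness, within a
step each unit's force is *exactly* `A + K·Δℓ + F_pass(ℓ)` with
K = k_cb × bound count, a strictly increasing function of length; the
chain balance is therefore solved to machine accuracy by a nested Newton
iteration on the common tension (total length matched to < 10⁻⁷ nm). The
z-line-coupled lattice uses a damped Newton iteration on node positions
with a banded Jacobian; coupling springs act between corresponding
z-disks of all myofibril pairs, with stiffness k_im × (isometric
reference stress at 1200 nm) per nm of misregistration — k_im = 0.1
registers z-lines to sub-nm.

Bound mass dragged past the strain-axis ends during rapid "popping"
excursions is forcibly detached into D. This is the physical closure of
the capped barrier (uncapped, those heads would have detached already);
the cumulative fraction is tracked in run diagnostics and is ≲ 10⁻³ of
detachment events in standard protocols. The public `shift_distribution`
operation keeps a strict 10⁻⁶ leak tolerance.

The numpy operations are the reference implementation; a numba-compiled
fused step reproduces them to ~10⁻¹³ (tested) and carries the production
runs. Halving dt changes quasi-steady tension traces by < 0.5%; the
ramp transient carries up to a few % local step error from the stiff
barrier kinetics, and the headline ensemble enhancement moves by ~0.6
percentage points between dt = 1 ms and 0.5 ms — small against the
ensemble tolerance.

## Protocols and statistics

The standard trial pair: linear activation 0→1 over 1 s; isometric hold
1 s; stretch at constant velocity to the final length; hold. Magnitude
(default 8%) and velocity (default 0.1 s⁻¹) are expressed relative to the
*final* length; the standard run starts at mean half-sarcomere length
1200 nm (final ≈ 1304 nm). The isometric companion runs the same
activation at the final length throughout. Enhancement is evaluated 6 s
after the end of the length change, on ensemble-averaged tension traces
(per-seed values are reported alongside). Sweeps over magnitude and
velocity hold the final length fixed and vary the stretch history — with
varying final lengths the magnitude dependence would be confounded by the
length–tension relation.

Default ensemble sizes are 10 seeds per condition (4 for the lattice, 3
for the long-hold persistence run), sized so the full reproduction script
completes in minutes on one CPU; `--full` in the CLI switches to 60.

## What the generator emulates — and what passing tests show

The Gaussian multipliers emulate biological unit-to-unit variability of
unspecified molecular origin (myosin content, filament lengths, isoform
or phosphorylation gradients). They are static in time, spatially
uncorrelated, and identical across a unit's two force systems only
through their draws — real variability is likely correlated along the
fiber and between active and passive properties. Passing tests therefore
show that *static, independent* strength variability reproduces the
enhancement phenomenology; they do not identify its molecular source,
and quantitative agreement inherits the stand-in rate laws.

## Emergent behaviour and known limitations

With the frozen defaults the model reproduces: ensemble enhancement
≈ 13–14% for the standard protocol (α = 0.2); > 5% at α = 0.02 with
saturation above α ≈ 0.1; linear growth with stretch magnitude (slope
≈ 1.5–1.7 %RFE per % stretch, R² > 0.99); weak velocity dependence
(max/min ratio ≈ 1.1–1.3 over a ten-fold range); enhancement from
passive-only heterogeneity (≈ 4–6% at β = 0.1–0.2); persistence of the
stretched/isometric difference beyond 30 s with eventual convergence; and
the two-unit mechanism signature (weak unit above, strong unit below its
steady-state curve, with continuing antagonistic motion).

Known limitations, all traceable to the calibration compromise between
enhancement amplitude (favouring slow cross-bridge cycling) and the speed
with which small heterogeneity must express itself (favouring fast
cycling):

* **Ascending-limb stretches.** Trials ending at 1134–1160 nm show
  mildly *negative* enhancement (−3 to −9%): the stretch transient pops
  the weakest units onto passive support early, leaving a lower-tension
  configuration while the isometric companion diverges more slowly.
  Experiments and the reference phenomenology show small positive
  enhancement there.
* **Slow stretches and the coupled lattice.** The model's enhancement
  decays with τ ≈ 8 s, so pumping it with a 4-s ramp loses roughly half
  of it, and z-line registration across myofibrils suppresses the
  sarcomere-symmetric share of the divergence; the lattice experiment
  retains ≈ 5–6% enhancement instead of the ≈ 13% seen with the fast
  standard ramp. Whole-sarcomere length variation in the lattice is
  smaller than half-sarcomere variation, but only modestly so.
* The total steady-state length–tension curve rises a few % across the
  plateau (growing passive share); only the active component is flat
  there.
* No Ca²⁺ kinetics (ψ is imposed), no ATP accounting, no explicit
  tendon compliance, no shortening-induced force depression protocols.
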