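# Methods

## Model

`mztsim` is a deterministic, mean-field, discrete-time model of genome-wide
CpG methylation during early development of a dioecious species. One
"generation" is the cell lineage from zygote to gamete, discretized into `D`
cell divisions. Two lineages (male and female) start from the same zygotic
methylation state — they are offspring of one fertilization — and are
simulated in parallel; the sexes differ only in their post-ZGA rate values,
never qualitatively. Sex is a fixed genetic property here: methylation levels
carry no sex-determining role, and male and female levels may cross or
coincide freely.

Key assumptions, stated as such:

- **Mean-field proportions.** The state (X, Y, Z) is the expected fraction of
  sites in each methylation class; there is no per-cell or per-locus
  stochasticity and no locus heterogeneity. Rates are genome-wide averages.
- **Real-valued cell counts.** Logistic growth is deterministic, so N is a
  real number (N₀ = 1, a single-cell zygote); rounding happens only in
  reporting (the "cell count rounds to K" diagnostic uses N ≥ K − 0.5).
- **Hemimethylation is transitional.** Hemimethylated sites arise only from
  replication of homomethylated sites and are resolved by the repair step;
  there is no active hemimethylation.
- **Conserved cytoplasmic volume.** Early cleavages divide a fixed cytoplasm,
  so the nucleocytoplasmic ratio is ν = 1/N and ZGA timing can be tied to a
  threshold ν_t.
- **Repressor-gated dynamics.** A maternal repressor ρ (dimensionless)
  doubles the initial division rate when ρ₀ = 1 (μ = (1 + ρ)r), decays
  geometrically, gates repair demethylation through its effect
  ρ_c = (ρ₀ − ρ)/ρ₀, and drives the pre→post rate transition through the
  ratio ρ_power·ρ₀/ρ compared against 1/ν_t.

## Order of events within a division

The per-division update evaluates ρ_c and the four instantaneous rates from
the repressor level at the *start* of division d, applies
replication → repair → active demethylation to the methylation state, and
only then advances N and ρ. Division indices run d = 1..D with ρ₁ = ρ₀ and
N₁ = N₀; trajectory row d records the start-of-division embryo quantities
together with the post-division methylation state. This indexing is what
places the transition midpoint (the first d with ρ_power·ρ₀/ρ_d ≥ 1/ν_t) at
division 45 under the default parameters, and the growth equilibrium at
divisions 146 (ρ₀ = 0) and 136 (ρ₀ = 1).

## Default parameters

| parameter | meaning | default |
|---|---|---|
| `D` | divisions per generation | 250 |
| `r` | intrinsic division rate (per division) | 0.1 |
| `K` | equilibrium cell number | 1024 |
| `rho0` | initial repressor (1.0 ⇒ twofold initial speed-up) | 1.0 |
| `rho_deg` | repressor decay per division | 0.1 |
| `rho_power` | repressor trigger magnitude | 1.0 |
| `nu_t` | nucleocytoplasmic threshold | 0.01 |
| `Q_*` | transition slopes (all four rates) | 100 |
| pre-ZGA rates | α₀ = 1, β₀ = δ₀ = ζ₀ = 0 (level-preserving) | fixed |
| post-ZGA α, δ | maintenance / repair demethylation | 0.99 / 0.01 |
| post-ZGA β | de novo methylation, per sex | 0.04 (male), 0.1 (female) |
| post-ZGA ζ | active demethylation | 0 |
| env ranges | additive drift interval for α₁, δ₁ | [−0.01, 0.01] |

The default β values give gametic equilibria X* = β/(1 − α + β) of 0.80 and
0.909091 — zebrafish-level gametes. The `human` preset pins
(α, β, δ) = (0.77, 0.27, 0.23) and (0.87, 0.12, 0.13), whose fixed points are
exactly 0.54 and 0.48; `hypothetical_0.30` pins (0.93, 0.03, 0.07) → 0.30.
These triples were selected with the parameter-space explorer among the many
grid combinations matching each level (α + δ = 1 triples with exact fixed
points were preferred); any other explorer hit is equally valid as a preset.
Note the default presets keep the conventional male/female labeling of the
β values (male 0.04 → 0.80); since sperm are the more methylated zebrafish
gamete, analyses that care about the biology should interpret equilibria by
value, not by label, or swap the per-sex β values in a config file.

## Numerical choices

- **Saturating rate transition.** The logistic transition argument reaches
  ≈ +9900 at the start of a generation (Q(1/ν_t − 1) at defaults), which
  would overflow a naive exponential. Arguments with |Q·arg| ≥ 700 return
  the pre/post asymptote *exactly*, so pre-ZGA divisions preserve the
  methylation level to the last bit and the plateau is exact, not
  approximate.
- **ρ₀ = 0.** The repressor-ratio trigger is undefined without repressor; the
  transition then degrades to a step function of ν (pre while ν > ν_t, post
  once ν ≤ ν_t), preserving the nucleocytoplasmic reading of ZGA.
- **Equilibrium detection.** `divisions_to_equilibrium` returns the first
  division from which |X − target| < tol *and stays* below tol (half-width
  default 0.005). Run summaries detect against each sex's analytic
  equilibrium rounded to two decimals — the levels' reporting accuracy of
  0.01 — which is the convention under which generation 2 reaches 0.91 at
  division 67 (22 post-ZGA) and 0.80 at division 91 (46 post-ZGA). Detecting
  against the unrounded fixed point 0.909091 instead flags division 65; the
  0.80 counts are insensitive because that level is already two-decimal.
- **ZGA onset** is operationalized as the transition midpoint crossing
  (first d with ρ_power·ρ₀/ρ_d ≥ 1/ν_t); the model itself has a gradual
  switch, so any onset definition is a convention.
- **Fixed points.** The constant-rate division map is affine; the solver uses
  the closed form X* = β/(1 − α + β) when ζ = 0 and α + ρ_c δ = 1
  (the hemimethylated pool then empties every division) and otherwise
  iterates to 1e-12. The perfect-maintenance corner (α = 1, β = 0, δζ = 0)
  has no unique fixed point — every level is stationary — and is rejected,
  and excluded from explorer grids. Steady-state analyses take ρ_c at its
  late-development limit of 1.
- **Explorer.** The (α, β, δ) grid scan (ζ = 0, step 0.01, feasibility
  α + δ ≤ 1) evaluates equilibria with a vectorized closed form
  (W* = β/(β + (1 − α + δ)/2), X* = β + W*(α − β)) rather than the iterative
  solver, for speed; the two routes are cross-checked in the test suite.
  Divisions-to-equilibrium for retained triples are measured by simulating
  the full model from the standard generation-2 zygotic state
  (X = 0.854545, the average of the two default gametic equilibria), which is
  configurable.
- **Rate validation.** Rates are validated into [0, 1] (snapping only float
  dust within 1e-9); an (α, δ) pair with α + δ > 1 is rejected with an
  error, never silently clamped. Random environmental draws violating the
  invariants are redrawn (up to 100 times) so accepted draws remain uniform
  on the feasible set; directional shifts are clamped per-rate and rejected
  if the pair becomes infeasible.

## Environmental variation and inheritance

At the end of each generation the post-ZGA α and δ of flagged sexes receive
an additive perturbation: uniform on a configured interval (`random`) or a
constant shift (`directional`). By default perturbations accumulate (a random
walk on the current rates); `accumulate: false` instead perturbs the original
base rates independently each generation. Only post-ZGA rates are perturbed —
pre-ZGA rates are structurally fixed at the level-preserving values.
Perturbing one sex never alters the other sex's rates; the signal reaches the
other sex only through the averaged zygotic state (cis transmission). Because
a lineage's adult level is pulled to its own fixed point at a geometric rate
(factor α − β per post-ZGA division when Y = 0), the constant-rate sex's
adult level is insensitive to that zygotic variation to within its
finite-generation convergence residual — e.g. ≈ 2·10⁻¹² for the 0.91 lineage
(factor 0.89 over ~205 post-onset divisions) but only ≈ 10⁻⁶ for the 0.80
lineage (factor 0.95) at D = 250. Fertilization can optionally be taken at
the first division where both sexes have settled
(`fertilize_at="equilibrium"`) instead of at d = D; the default is d = D.

## What passing tests do and do not show

The model consumes no sequence data; all inputs are parameter
configurations, so there is no synthetic-data/real-data gap in the usual
sense. What the simulator emulates is the *mean* genome-wide methylation
trajectory under homogeneous average rates; it does not emulate locus-to-
locus rate variation, per-cell stochasticity, partially maintained
hemimethylation, enzyme-level kinetics, or any feedback from methylation to
sex or fitness. Agreement with the reference division counts therefore
validates the recurrences and their composition, not the biological
sufficiency of global average rates. Parameter inference from real methylome
data is out of scope.

## Problem sizes used in the test suite

The suite runs the canonical two-generation, 250-division scenario once
(shared fixture); property tests use 10⁴ random states for conservation,
10³ vectorized draws for the closed-form/simulation equilibrium comparison,
and 200 scalar draws (α ≤ 0.95, 500 divisions) for the full-model
fixed-point cross-check. Explorer soundness is checked at grid steps
0.01–0.05 depending on whether per-triple division counts are also needed.

## Known limitations

- Rates are constant within a generation (they represent zygote→gamete
  averages); developmental-stage-specific rate changes other than the single
  pre→post switch are not representable.
- With μ > 1 the logistic map can overshoot K; the model validates μ ≤ 1
  rather than modeling overshoot.
- The transition slopes Q are shared across presets; if configured per-rate
  with very different values, the instantaneous (α, δ) pair can transiently
  violate α + ρ_c δ ≤ 1 mid-transition, which the repair step rejects with
  an error rather than clamping.
- Generations converge to a steady cycle geometrically, not exactly: at
  D = 250 successive unperturbed generations differ by ~10⁻⁶ through the
  slower (0.80) lineage's convergence residual.
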