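# Methods

## The phospho-circuit model

The circuit couples the three PAGE4 phospho-forms to the androgen
receptor (AR) axis. Wild-type PAGE4 (`W`) is produced at a constant rate
and converted by the HIPK1 kinase to the double-phosphorylated form `H`;
the CLK2 kinase (`K`) converts `H` to the hyper-phosphorylated form `C`
by mass action (`k_C·K·H`). `H` represses AR activity (`A`) through a
Hill term (HIPK1-PAGE4 potentiates c-Jun/AP-1, a negative AR regulator;
c-Jun carries no independent dynamics and is lumped into the repression),
and `A` represses CLK2 production through a second Hill term. HIPK1
itself is unregulated in this model and is absorbed into the rate
constant `k_H`.

Assumptions worth making explicit:

* AR activity is a dynamical variable with its own turnover `δ_A`, not an
  instantaneous function of `H`. The extra lag is physiologically
  plausible (AR signaling involves transcription) and is one of the three
  stages that carry the feedback delay.
* Concentrations are dimensionless; time is in hours. The only absolutely
  anchored rate is the WT-PAGE4 degradation `δ_W = ln 2 / 150 h⁻¹`
  (≈150 h half-life), the slow timescale of the system.
* No cell death, division, or cell–cell communication; cohort cells are
  i.i.d. copies of one deterministic system differing only in phase.

## Why Hill coefficients of 8

The loop `H ⊣ A ⊣ K ⊣ H` (the last arm via `K` consuming `H`) is a
three-stage negative feedback of Goodwin type. For such loops a linear
stability (secant) criterion applies: with three comparable first-order
stages, the product of the stage gains must exceed `sec(π/3)³ = 8` for
the fixed point to destabilize. A repressive Hill term with coefficient
`n` contributes at most an elasticity of `n/2` (attained at its
threshold), and the bilinear consumption stage contributes at most 1, so
with `n = 4` on both Hill arms the loop gain is bounded by
`2 × 2 × 1 = 4` — no oscillation, which a grid scan over the plausible
rate ranges confirmed numerically. With `n = 8` the attainable gain is
16 and the circuit oscillates robustly across a broad parameter region.
Steep effective cooperativity is biologically defensible here because
each arm compresses a multi-step cascade (phosphorylation of c-Jun,
AP-1 assembly, transcriptional repression).

## Calibration

Two anchors: the 150 h half-life (fixing `δ_W` exactly) and a
no-treatment limit-cycle period of one week (168 h) in `H`. Fixed
template values: `k_H = 0.01 h⁻¹` (so conversion, not degradation,
dominates W turnover and the H influx is `≈ k_H`), `δ_H = 0.003 h⁻¹`
(free `H` outlives `W` conversion), `δ_C = 0.02 h⁻¹` (~35 h half-life for
the hyper-phosphorylated form, which the cell degrades), `A₀ = 0.5`
(production scales `g_A = δ_A`, `g_K = δ_K` put the repressed species on
a unit scale, so mid-scale thresholds sit on the steep part of the Hill
curves), `β_OE = 0.05` (overexpression drive ≈ 2.5× the maximal normal AR
production, enough to pin `A` high under BAT). The grid search runs
lexicographically over the AR/CLK2 turnover `δ_A = δ_K ∈ {0.02, 0.025,
0.03}`, the conversion rate `k_C ∈ {0.05, 0.1, 0.2}` and the repression
threshold `H₀ ∈ {0.4, 0.6, 0.8}`; the first grid point whose period falls
within ±10% of 168 h wins, followed by bisection on `δ_A = δ_K` (period
is monotone decreasing in it) until the period is within 2 h of target.
The shipped default (`δ_AK = 0.02`, `k_C = 0.05`, `H₀ = 0.4`) has a
period of 166.3 h and a peak-to-peak `H` amplitude of ~52% of its mean.

## Numerics

Single-cell integration uses LSODA (stiff-capable, adaptive) with
`rtol = 1e-8`, `atol = 1e-10`, integrating piecewise over each constant
protocol segment and sampling every 0.5 h; a fixed-step RK4 oracle at
`dt = 0.01 h` agrees to better than 1e-4 relative over 2000 h (tested).
Non-negativity holds from the vector field (every inflow saturates and
every outflow vanishes at zero); no clipping anywhere. The repressive
Hill function clamps its argument at zero to guard against solver
round-off probing infinitesimally negative states — a domain guard, not
state modification. Cohorts are integrated as one stacked block-diagonal
system with RK45 (`rtol = 1e-6`, `atol = 1e-9`, vectorised right-hand
side); a one-cell cohort matches the single-cell path to <5e-4.

Period detection is peak-based: local maxima with prominence ≥5% of the
post-burn-in range, period = mean successive spacing, "oscillating"
requires ≥3 peaks and peak-to-peak ≥1% of the mean. The quench time under
treatment is the first time the peak-to-peak range within a sliding
one-period window drops below 5% of the pre-treatment amplitude; both
thresholds are fixed conventions of this package. Treatment onset in the
quench analyses is placed at 600 h so that more than three full periods
establish the reference amplitude.

Protocol segments are left-closed/right-open; "two weeks" is fixed at
336 h; intermittent ADT defaults to 168 h on / 168 h off (the durations
are configurable — no canonical clinical schedule is implied).

Phases and synchrony: cells are seeded at uniform-random phases of the
no-treatment limit cycle (computed once by integrating past the transient
and slicing between the last two `H` peaks). The per-cell phase is the
angle of `(H−H̄, C−C̄)` around the cycle centroid, and synchrony is the
Kuramoto order parameter `R = |⟨e^{iφ}⟩|`. Phenotype labels use the
cycle midranges as thresholds: androgen-dependent iff `H > h_mid` and
`C < c_mid`, androgen-independent for the mirrored condition, otherwise
indeterminate (boundary hits included). Population CV uses the population
(ddof = 0) standard deviation.

## Synthetic ensembles

The generator emulates — it does not simulate — the phospho-form
ensembles: conformers are i.i.d. draws from a persistent self-avoiding
random walk (fixed 3.8 Å virtual bonds, 3.0 Å non-bonded exclusion,
persistence weight 0.9·expansion on the previous bond direction). Loop
restraints (region-centroid separation ≤ 9 Å) are imposed by rejection:
the chain grows to residue 62, the N-loop condition is checked and the
prefix regrown on failure, then the tail grows with the C-loop condition
checked analogously — a valid factorization because each restraint
involves only the segment it gates. Presets: WT `p_N = 0.6`; HIPK1
`p_N = p_C = 0.45` drawn mutually exclusively (at most one restraint per
conformer, which is what produces the anti-correlated contact-PCA
loadings); CLK2 no loops, expansion 1.8. The occupancies and the
expansion factor are emulation knobs chosen once for clear qualitative
contrast; only orderings and sign structure are meaningful. What passing
tests show is therefore that the *metrics* recover planted structure
(loop contact blocks, anti-correlation, expansion ordering, N-half
dominance), not that these walks resemble real PAGE4 chains: real
ensembles have sequence-dependent local structure, solvent effects and
conformational autocorrelation that i.i.d. walks lack, and the absolute
Rg values here (≈24 Å WT, ≈36 Å CLK2) carry no physical calibration.

Metric conventions: contacts are Cα–Cα within 9.5 Å at sequence
separation ≥3 (a standard coarse-grained convention; the cutoff is
configurable). Contact PCA runs on binary contact vectors; modes come
from an SVD of the centered conformer × pair matrix (equivalent to the
covariance eigendecomposition, checked against an explicit `eigh` oracle
to 1e-8), with each mode's largest-magnitude coefficient flipped
positive for determinism. Free-energy profiles use `kT = 1` and mask
empty bins as NaN rather than ±inf. The turn criterion — `d(i, i+3) <
7 Å` with both intervening virtual-bond angles < 150° — is a geometric
stand-in for secondary-structure assignment, usable on Cα-only chains;
the first and last three residues are reported missing. Degenerate
inputs raise typed errors (all-identical ensembles for PCA, zero-mean
populations for CV, fixed-point dynamics for phase sampling) except the
all-identical free-energy profile, which warns and returns the single
occupied bin.

## Problem sizes

Cohort analyses use 1,000 cells for distribution statistics and 200 for
synchronization/phenotype time courses; ensembles use 150 conformers per
preset (the analysis scripts) and 120 in the test fixtures. These sizes
put sampling noise well below every margin tested (the cells are i.i.d.,
so larger cohorts change only tail noise) while keeping any run at the
scale of seconds to tens of seconds.

## Known limitations

* The circuit is deterministic; there is no molecular noise, cell death,
  or proliferation, so "cohort homogenization" means phase collapse, not
  selection.
* Oscillation requires the calibrated steepness; the package makes no
  claim about where the physiological system sits relative to the
  bifurcation.
* The quench criterion and the turn criterion are conventions; absolute
  numbers depending on them (quench time, turn propensities) should be
  compared only within this package.
* The ensemble generator cannot produce sequence-specific effects (e.g.
  the exact phospho-site chemistry); it reproduces topological signatures
  only.
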