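# page4-dynamics

Dynamics of the PAGE4 phosphorylation circuit in prostate cancer cells,
and structural order metrics for conformational ensembles of the
intrinsically disordered PAGE4 protein.

PAGE4 is a 102-residue intrinsically disordered protein whose
phospho-forms sit inside a regulatory loop with the androgen receptor
(AR): the HIPK1 kinase double-phosphorylates wild-type PAGE4 (W → H), the
CLK2 kinase hyper-phosphorylates HIPK1-PAGE4 (H → C), HIPK1-PAGE4
potentiates c-Jun/AP-1 and thereby represses AR activity, and AR in turn
represses CLK2 expression. The closed loop H ⊣ A ⊣ K (with K consuming H)
is a delayed negative feedback; anchored by the unusually long WT-PAGE4
half-life of ~150 h, it relaxes into a limit cycle with a period of about
one week, alternating an androgen-dependent phenotype (high HIPK1-PAGE4,
low CLK2-PAGE4) with an androgen-independent one. This package implements
that circuit, the treatment protocols that perturb it, population-level
statistics over cohorts of unsynchronized cells, and the ensemble-level
structural observables that distinguish the three phospho-forms.

## Model

Five species (dimensionless concentrations, time in hours):

    dW/dt = g_W − k_H·W − δ_W·W
    dH/dt = k_H·W − k_C·K·H − δ_H·H
    dC/dt = k_C·K·H − δ_C·C
    dA/dt = g_A · 1/(1+(H/H₀)^n_H) · (1 − u_ADT(t)) + β_OE·u_OE(t) − δ_A·A
    dK/dt = g_K · 1/(1+(A/A₀)^n_A) − δ_K·K

with W, H, C the wild-type, HIPK1- and CLK2-phosphorylated PAGE4 forms, A
the AR activity and K the CLK2 kinase. Androgen-deprivation therapy (ADT)
multiplies AR production by `1 − u_ADT`; bipolar androgen treatment (BAT)
adds an overexpression drive `β_OE·u_OE`. The default parameter set fixes
δ_W = ln2/150 h⁻¹ exactly and is calibrated by grid search so the
no-treatment limit cycle has a ~168 h period (shipped in
`src/page4/params/default.yaml`).

The structural half operates on Cα ensembles (conformers × 102 residues ×
xyz): radius of gyration and free-energy profiles F = −k_BT log P,
inter-residue distance distributions for the FRET-probed pairs (18, 63)
and (63, 102), ensemble contact maps (9.5 Å cutoff, |i−j| ≥ 3),
contact-based PCA over binary contact vectors, and a geometric turn
propensity. A constrained self-avoiding-walk generator supplies synthetic
ensembles whose presets emulate the three phospho-forms: WT forms an
N-motif(4–12)↔central-region(43–62) loop, HIPK1 adds a mutually exclusive
C-motif(82–95) loop (anti-correlated PC1 loadings), and CLK2 forms no
loops and is globally expanded.

## Worked example

```bash
python analysis/02_single_cell_dynamics.py
```

prints

```
Free-running HIPK1-PAGE4 period: 166.3 h (amplitude 52% of mean)
Full ADT at t=600 h quenches the oscillation after 174 h (~1.0 weeks)
Post-ADT state is androgen-independent-like: H=0.189, C=0.472
```

i.e. the untreated cell cycles between phenotypes roughly weekly; a
constant full ADT signal kills the oscillation within about one week
(well inside the two-week bound) and parks the cell at low HIPK1-PAGE4 /
high CLK2-PAGE4 — the androgen-independent, therapy-resistant state. The
other drivers follow the same pattern: `03_cohort_adt.py` shows the CLK2
coefficient of variation of 1,000 unsynchronized cells collapsing from
~36% to <1% within two weeks of ADT, `04_alternative_protocols.py` shows
intermittent ADT phase-locking the population (Kuramoto R → 1) and BAT
steering it between 100% androgen-dependent and 100%
androgen-independent, and `05_ensemble_signatures.py` reports the
phospho-form ensembles' Rg ordering, contact blocks and anti-correlated
PC1 loadings.

The same functionality is available as a CLI:

```bash
page4 simulate --protocol adt:t_on=600 --t-end 1600 --out traj.csv
page4 analyze traj.csv --species H --burn-in 100
page4 cohort --n 1000 --seed 42 --protocol adt:t_on=0 --out cohort.csv
page4 ensemble --preset clk2 --n 500 --seed 7 --out clk2.xyz
page4 report --out page4_run
```

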