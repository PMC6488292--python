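# proofkin

Quantifying kinetic proofreading in receptor signaling from optogenetically
tuned ligand binding half-lives.

## The problem

T cells discriminate ligands largely by how *long* a ligand stays bound to the
receptor, not merely by how many receptors are occupied. Kinetic proofreading
explains this: after ligand binding, the receptor must traverse `n`
irreversible biochemical steps that proceed only while the ligand remains
bound and reset on dissociation. Each step is a race between the forward
transition (half-life τ_p) and ligand dissociation (half-life τ_off), with
per-step success probability

```
α = τ_off / (τ_off + τ_p),
```

so a fraction `α^n` of bound receptors signals productively. With the LOV2/Zdk
photoswitch as the ligand–receptor interface, blue light tunes the
dissociation rate directly — the apparent off-rate is

```
k_obs(ν) = k1·ν·k2 / (k1·ν + k2) + k3,        τ_off = ln2 / k_obs,
```

where ν is the blue-light intensity — which decouples binding half-life from
occupancy and bond mechanics. Modeling the downstream DAG readout as a
saturable response to the proofread signal (the strong-proofreading limit,
where α ∝ τ_off),

```
DAG = A · R·τ^n / (K + R·τ^n) + β,
```

with `R` the receptor occupancy, `K` the half-maximal upstream signal and `β`
basal signaling, fitting single-cell (R, τ, DAG) measurements yields the
degree of proofreading `n` with a 95% confidence interval.

The package is for quantitative cell biologists running (or re-analyzing) such
experiments: it implements the photokinetic half-life model, the TIRF/RICM
image quantification chain (flat-field correction, footprint/ribbon
segmentation, laser-normalized occupancy, PP2- and drift-corrected DAG),
the proofreading model fit, occupancy-gated correlation and kernel-regression
analyses, absolute ligand-density and receptor-count calibrations — plus a
fully seeded synthetic-data generator and a stochastic binding-event simulator
so every stage is testable without external data.

## Worked example

```python
import proofkin as pk

# a 3-day synthetic study: 4 ligand densities/day, 30 cells/dataset,
# 8-intensity light program spanning half-lives 10 s -> 0.56 s, true n = 2.7
table = pk.generate_cell_table(pk.SimulationConfig(seed=42))

# occupancy arbitrary units drift between days, so fits are grouped per day
fits = pk.fit_proofreading_model(table)
for day, fit in fits.items():
    print(f"{day}: n = {fit.n:.2f} (95% CI {fit.ci95_n[0]:.2f}-{fit.ci95_n[1]:.2f}, "
          f"dof = {fit.dof})")
```

prints

```
day00: n = 2.50 (95% CI 1.59-3.42, dof = 116)
day01: n = 2.32 (95% CI 1.49-3.15, dof = 116)
day02: n = 3.02 (95% CI 2.01-4.03, dof = 116)
```

Each line is one imaging day's independent estimate of the degree of
proofreading; all three intervals bracket the generative truth n = 2.7. An
`n` of this size is consequential: far from pathway saturation a 10-fold
difference in binding half-life is amplified into

```python
pk.amplification_factor(2.7, 10, include_occupancy=True)   # 5011.87... ≈ 5,000-fold
```

difference in DAG output (one factor of 10 from occupancy, 10^2.7 from the
proofreading steps) — enough for a few long-lived foreign ligands to outweigh
abundant short-lived self ligands.

The same estimators are exposed sklearn-style
(`KineticProofreadingRegressor`, `PhotoKineticModel`, `ExponentialDecayModel`,
`NadarayaWatsonRegressor`) with `fit`/`predict` and fitted attributes, and a
CLI covers the pipeline end to end:

```bash
proofkin simulate --seed 0 --out sim/
proofkin fit-photokinetics --traces sim/traces --out photokinetics.json
proofkin fit-proofreading --table sim/cell_table.csv --out report.json
```

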