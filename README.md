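# lumistab

Analysis toolkit for the biophysics and cell biology of STIM luminal-domain
stability: how cysteine modifications (e.g. *S*-nitrosylation by the NO donor
GSNO) change the thermal and thermodynamic stability of the EF-SAM Ca²⁺-sensing
region, perturb its structure, and alter basal Ca²⁺ and store-operated Ca²⁺
entry (SOCE) in cells. It is written for protein biophysicists and Ca²⁺
signalling labs who collect four kinds of data and want one tested pipeline
for all of them:

1. **Thermal melts** (far-UV CD ellipticity vs temperature) — fit with the
   4-parameter Boltzmann sigmoid
   θ(T) = θ_post + (θ_pre − θ_post) / (1 + exp((T − Tm)/s)),
   yielding an apparent melting midpoint Tm; condition differences ΔTm carry
   quadrature-propagated standard errors.
2. **Equilibrium urea denaturation** (intrinsic fluorescence, replicates) —
   fit globally with the two-state linear-extrapolation model (LEM):
   ΔG([D]) = ΔG_H₂O − m·[D], K_U = exp(−ΔG/RT), observed signal the
   population-weighted average of two linear baselines. ΔG_H₂O and the
   m-value are shared across replicates; each replicate keeps its own
   baselines. Cmid = ΔG_H₂O/m; ΔΔG between conditions gets
   √(se₁² + se₂²) errors.
3. **¹H-¹⁵N HSQC peak lists** (two conditions) — per-residue weighted
   chemical-shift perturbations CSP = √(ΔH² + (0.14·ΔN)²), an iteratively
   trimmed mean + SD significance threshold, sequence-cluster detection, and
   structure mapping by writing 100·CSP into a PDB B-factor column.
4. **Fura-2 ratiometric Ca²⁺ traces** — R = F340/F380, F/F₀ baselining,
   the ratiometric calibration [Ca²⁺] = K_d·β·(R − R_min)/(R_max − R)
   (K_d = 225 nM), basal Ca²⁺ and peak-SOCE window statistics under both a
   cuvette (suspension) and a plate protocol.

Every arm has a synthetic-data generator (`lumistab.simulate`) with explicit
ground truth, so the full pipeline is exercisable and testable without any
instrument data.

## Worked example

```python
from lumistab.denaturation import delta_delta_g, fit_two_state_global
from lumistab.simulate import DenatTruth, gen_denaturation_replicates

dtt = fit_two_state_global(
    gen_denaturation_replicates(DenatTruth(dg=4.82, m=1.69), seed=1))
gsno = fit_two_state_global(
    gen_denaturation_replicates(DenatTruth(dg=5.98, m=1.92), seed=2,
                                condition="nitrosylating"))
d = delta_delta_g(dtt, gsno)
```

prints (via `python examples/fit_urea_denaturation.py`):

```
DTT  dG_H2O = 4.83 +/- 0.11 kcal/mol | Cmid = 2.84 M | m = 1.70 +/- 0.04 kcal/mol/M
GSNO dG_H2O = 5.88 +/- 0.16 kcal/mol | Cmid = 3.11 M | m = 1.89 +/- 0.05 kcal/mol/M
ddG_H2O = +1.05 +/- 0.19 kcal/mol
```

The three replicates per condition were simulated at 1% multiplicative noise
from ground truths (4.82, 1.69) and (5.98, 1.92); the global fit recovers both
within its standard errors, and the positive ΔΔG_H₂O says the nitrosylating
condition stabilised the domain by about 1 kcal/mol in water. The other
`examples/` scripts do the same for thermal melts (`fit_thermal_melt.py`),
CSP profiling and clustering (`csp_mapping.py`) and Fura-2 trace summaries
(`fura_trace_analysis.py`).

## Command line

A thin CLI wraps the same functions:

```bash
lumistab simulate denat --seed 1 --out sim/
lumistab fit-denat sim/denat.csv
lumistab csp --ref ref.list --mod mod.list --pdb structure.pdb --chain A
lumistab fura trace.csv --events "egta_add=100,tg_add=200,ca_addback=400" \
    --r-min 0.3 --r-max 6.0
lumistab report config.yaml
```

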