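# nmtqsar

GA-MLR QSAR modeling of human *N*-myristoyltransferase (Hs-NMT) inhibition by
nitrogen heterocycles.

Hs-NMT is a drug target for cancer, malaria and leishmaniasis. Published
structure–activity work on a 309-compound nitrogen-heterocycle series fits
five-descriptor ordinary-least-squares models of pIC50 = −log₁₀(molar IC50),
selecting the descriptors with a genetic algorithm whose fitness is the
leave-one-out Q², and validating them with the full modern battery
(Q²LOO/Q²LMO, Y-scrambling, Q²F1/F2/F3, CCC, Golbraikh–Tropsha origin
regressions, r²m, Kxx/ΔK, Williams-plot applicability domain). This package
is a reusable, tested implementation of that entire workflow for anyone who
wants to rebuild, audit or extend such models:

* **chem_prep** — CSV/SMI/SDF ingestion, IC50 → pIC50, single MMFF94-optimized
  3D conformer with MMFF94 partial charges (deterministic per seed).
* **descriptors** — per-atom Shrake–Rupley solvent-accessible surface area
  (probe 1.4 Å, Bondi radii, configurable point density), the five model
  descriptors (`C_AbSA`, `all_HASA2`, `fNH4B`, `fringNH2A`, `flipoH3B`) and
  the parametric families behind them: charge-binned SASA
  (`qSASA_{lo}_{hi}`), topological H-environment counts (`f<center>H<k>B`,
  H atoms whose nearest center of a class is exactly *k* bonds away) and
  geometric shells (`f<center>H<k>A`, nearest center in [k−1, k) Å).
* **feature_selection** — objective pruning (constants, ≥95 % near-constants,
  |R| > 0.90 collinearity) and subjective selection: a fixed-cardinality
  subset GA scored by Q²LOO, an exhaustive reference search, and the
  breaking-point rule for choosing the model size.
* **validation** — OLS with 95 % t-interval half-widths and every statistic
  of a published model block, plus the rule-based acceptance check
  (R²tr ≥ 0.6, Q²LOO ≥ 0.5, Q²LMO ≥ 0.6, RMSEtr < RMSEcv, ΔK ≥ 0.05,
  CCC ≥ 0.80, Q²Fn ≥ 0.60, r²m ≥ 0.5, k/Ro² branch, |Ro²−R′o²| < 0.3).
* **pipeline** — the 50/50 split-and-exchange strategy (select on one half,
  validate externally on the other, swap, compare descriptor sets), reports,
  and the two published five-descriptor equations shipped as prediction
  fixtures (`MODEL_1`, `MODEL_2`).
* **synthetic** — planted-signal descriptor matrices with declared
  degeneracies, and hand-enumerable fixture molecules.

The core model is

```
pIC50 = b0 + Σj bj · xj ,   fitness(S) = Q²LOO(S) = 1 − PRESS(S)/TSS
```

with PRESS from the hat-matrix identity e₍ᵢ₎ = eᵢ/(1−hᵢᵢ), and e.g. the
published Model-1 equation

```
pIC50 = 0.928 (±0.703) + 0.028 (±0.008)·C_AbSA + 0.009 (±0.001)·all_HASA2
        − 0.142 (±0.069)·fNH4B + 0.554 (±0.311)·fringNH2A − 0.241 (±0.133)·flipoH3B
```

## Worked example

```python
import numpy as np
import nmtqsar as q

# a planted-signal dataset: 120 molecules, 20-column pool, 3 true descriptors
ds = q.gen_descriptor_dataset(q.SyntheticSpec(n_molecules=120, seed=17))
cfg = q.WorkflowConfig(model_size=3,
                       ga=q.GAConfig(model_size=3, population=40,
                                     generations=60, seed=2),
                       lmo_reps=200, yscramble_reps=100)
res = q.run_exchange_workflow(ds.X, ds.y, cfg)
arm = res.arms[0]
print(arm.candidate.descriptor_names,
      round(arm.report.r2tr, 3), round(arm.report.q2_loo, 3),
      round(arm.report.ccc_ex, 3), arm.acceptance.passed)
print(res.consensus_descriptors, ds.truth.planted_names)
```

prints

```
['d003', 'd007', 'd011'] 0.999 0.998 0.999 True
['d003', 'd007', 'd011'] ['d003', 'd007', 'd011']
```

— both exchange arms select exactly the planted subset (`d003, d007, d011`),
the fit explains ~99.9 % of the variance at this signal-to-noise, and the
model passes every acceptance rule.

Predicting with a shipped published equation:

```python
pred, in_domain = q.predict_with_published(
    {"C_AbSA": 0, "all_HASA2": 0, "fNH4B": 0, "fringNH2A": 0, "flipoH3B": 0},
    model="model1")
print(pred)   # 0.928  (the Model-1 intercept)
```

Descriptor values fed to the published equations should come from this
package's own preparation/SASA stack only for qualitative exploration: SASA
descriptors depend on the conformer and surface implementation, so absolute
values differ between software stacks (see `docs/methods.md`).

A thin CLI wraps the same functions:

```bash
qsar prep --in data.csv --out prepared.sdf --seed 42 --max-steps 1000
qsar descriptors --in prepared.sdf --out X.csv --n-points 960
qsar select --x X.csv --y y.csv --size 5 --generations 10000 --seed 1 --out cands.csv
qsar predict --model model1 --desc "C_AbSA=100,all_HASA2=100,fNH4B=0,fringNH2A=0,flipoH3B=0"
```

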