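# filadose

Design toolkit for **passively drug-loaded FDM filaments** and 3D-printed
tablets. Instead of hot-melt extruding a drug/polymer mix, a commercial
printing filament is soaked in a saturated drug solution; the drug partitions
into the polymer by passive diffusion and the loaded filament is then printed
into a tablet. `filadose` implements the quantitative workflow around that
idea, for formulation scientists exploring solvent/filament combinations:

* **Hansen screening** (`filadose.hsp`) — Hansen solubility parameters
  (δd, δp, δh, MPa^1/2), tabulated or estimated by the Hoftyzer–van Krevelen
  group-contribution method, and the Hansen distance
  `Ra = sqrt(4Δδd² + Δδp² + Δδh²)`. Good loading wants a *high* drug–solvent
  Ra (> 10: the solvent holds the drug weakly) and an *intermediate*
  solvent–filament Ra (≈ 10: the solvent swells but does not dissolve the
  filament); `screen_combinations` ranks every pair by that rule.
* **Diffusion kinetics** (`filadose.diffusion`) — steady-state flux
  `Jss = dM/(S·dt)` from the linear portion (default 0–4 h) of a cumulative
  uptake time course, permeability `P = Jss/Csat`, solvent enhancement
  ratios, and cylinder dose geometry for sizing tablets.
* **Dissolution modelling** (`filadose.dissolution`) — zero-order,
  first-order, Hixson–Crowell and Korsmeyer–Peppas (`Qt/Q∞ = K·tⁿ`) release
  laws, model selection by R², and transport-mechanism classification from
  the exponent *n* (Fickian below the geometry threshold 0.50/0.45/0.43 for
  film/cylinder/sphere; zero-order at n ≥ 1).
* **Accelerated stability** (`filadose.stability`) — five degradation laws
  per chamber condition, the humidity-corrected Arrhenius surface
  `ln k = ln A − Ea/RT + B·RH` (R = 0.00198 kcal K⁻¹ mol⁻¹), and shelf-life
  extrapolation to storage conditions (default 25 °C / 60 % RH, 10 %
  specification limit).
* **Mechanics** (`filadose.mechanics`) — profilometry roughness (Rav, Rz)
  and three-point-bend bending modulus / toughness.
* **Multivariate model** (`filadose.multivariate`) — the six-variable
  feature table (Ra, roughness, bending modulus, toughness, Jss, P), PCA
  with correlation loadings, and MLR/PLS/RBF-SVM regressions of flux on the
  material descriptors.
* **Synthetic data** (`filadose.simulate`) — deterministic generators for
  every raw-data input, with known ground truth, so the whole pipeline is
  testable without instrument data.

Model-fitting stages follow the statsmodels convention: construct a model
object from data, call `.fit()`, read estimates and `summary()` off the
results object.

## Worked example

Screen nifedipine (a poorly water-soluble BCS-II antihypertensive) in two
food-grade solvents against four commercial filaments, using the bundled
reference material set:

```python
import filadose as fd
from filadose import datasets

mats = datasets.load_reference_materials()
res = fd.screen_combinations(
    mats["NFD"],
    [mats["ethanol"], mats["ethyl_acetate"]],
    [mats[f] for f in ("PVA", "HS", "PLA", "TPU")],
)
for r in res[:3]:
    print(r.solvent, r.filament, round(r.ra_drug_solvent, 1),
          round(r.ra_solvent_filament, 1), r.verdict)
```

```
      ethanol/PVA  Ra(d-s)= 13.7 Ra(s-f)=  8.7 score=12.39 favoured
      ethanol/HS   Ra(d-s)= 13.7 Ra(s-f)=  8.3 score=12.02 favoured
      ethanol/PLA  Ra(d-s)= 13.7 Ra(s-f)= 14.6 score= 9.13 borderline
```

Ethanol with the two PVA-derived filaments wins: the drug–solvent distance
13.7 exceeds 10 (weak solvation, strong driving force into the polymer) and
the solvent–filament distances sit near 10 (enough swelling to admit the
drug). Ethyl acetate, despite dissolving twice as much nifedipine, fails the
screen with a drug–solvent Ra of 3.3 — it binds the drug too well to release
it into any filament.

Fitting the tuned RBF-SVM to the eight-row feature table of measured fluxes:

```python
from filadose.multivariate import assemble_feature_table, fit_flux_model
ft = assemble_feature_table(res, datasets.reference_mechanics_table(),
                            datasets.reference_flux_table(),
                            datasets.SATURATION_SOLUBILITY)
print(fit_flux_model(ft, "svm_rbf").summary())
```

```
Flux regression (svm_rbf)
==================================
features        ra_solvent_filament, roughness_rav, bending_modulus, toughness
target          jss
training R^2    1.0000
training RMSE   7.938e-05
LOO R^2         -0.1487
hyperparameters C=10.0, gamma=2.0, epsilon=0.001
```

The training R² is a training-set fit (eight rows permit no honest held-out
estimate — the negative leave-one-out R² printed alongside says exactly
that); PCA on the same table shows flux and permeability loading opposite in
sign to the solvent–filament Ra, toughness and bending modulus on the
dominant component: stiff, poorly-swollen filaments load slowly.

A synthetic accelerated-stability study (six chambers, 50–80 °C, 10–75 % RH,
2 % assay noise) round-trips through the degradation and Arrhenius fits:

```
Humidity-corrected Arrhenius fit
==================================
ln A            32.67
Ea              23.49 kcal/mol
B (humidity)    0.007919 per %RH
R^2             1.0000

Shelf-life prediction
==================================
storage         25.0 degC / 60% RH
kinetic model   zero
k (storage)     0.0013
limit           10% degraded
shelf life      7691 days (21.06 years)
```

against a generator truth of ln A = 32.5, Ea = 23.38 kcal/mol, B = 0.008
(analytic shelf life 7533 days) — a 2 % error after extrapolating the rate
constant by 25–55 °C.

## Command line

Every stage is also a subcommand emitting JSON:

```bash
filadose screen --out screen.json
filadose simulate timecourse --seed 3 --out tc.csv
filadose flux --input tc.csv
filadose dissolution --input diss.csv
filadose stability --input stab.csv --storage 25 60 --limit 10
filadose mechanics --roughness prof.csv --force curve.csv
filadose model --features bundled --method svm_rbf
filadose run --config run.yaml --out report.json
```

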