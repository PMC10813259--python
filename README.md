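# capsulereg

Instantaneous, subject-specific calibration of hip-capsule models from hip
laxity, for computational biomechanics researchers and surgical-planning tool
builders working on total hip arthroplasty (THA).

Calibrating a capsule model to a patient's measured laxity by optimization
takes hours to days per subject. `capsulereg` replaces that optimization with
a statistical surrogate: a probabilistic population of capsule models is
simulated once, and a multilinear regression learned from it then maps a
subject's laxity and attachment-site shape directly to their capsule
parameters in milliseconds.

## The model

**Capsule mechanics.** The implanted hip capsule is a cylindrical sleeve of
nonlinear tension-only springs running from an ellipse around the acetabular
rim to an ellipse around the femoral intertrochanteric crest, wrapping the
femoral-head sphere along tangent–arc–tangent shortest paths. The sleeve is
divided into six circumferential sectors (approximating the named capsular
ligaments), each with an independent stiffness `k_s` (N/mm) and pre-strain
`p_s` (dimensionless tautness; the slack length of a line in sector *s* is
`L0 = L_ref · p_s^(-α)` with α = 0.2). Laxity — the rotation reached under a
1 or 5 Nm torque in internal/external rotation or ab/adduction at 0–90°
flexion — is solved by a quasi-static torque ramp on the capsule's
torque–rotation curve, giving 40 laxity metrics per hip from 20 (direction ×
flexion) cases.

**Shape model.** Attachment geometry varies across subjects. Both attachment
loops are resampled into 360 corresponded nodes starting at the most superior
point, and a PCA over the concatenated coordinates yields a statistical shape
model; the first four standardized mode scores `PC_1..PC_4` describe a hip's
attachment anatomy.

**Surrogate.** A Monte Carlo study (Latin hypercube sampling of the 12
mechanical parameters and 4 shape scores, truncated normals covering 95% of
the population) produces trials linking the 16 inputs to the 40 laxity
metrics. For each capsule parameter `p^k`, stepwise multilinear regression
(partial F-tests, enter p < 0.05 / remove p > 0.10) selects terms of

    p^k = b0 + Σ_i l_i · L_i + Σ_i q_i · PC_i

where the candidate laxities `L_i` come from one of nine registered training
sets (both rotation families or one, at 2–4 flexion angles). Closed-loop
validation predicts parameters for held-out trials, re-simulates their
full 40-metric laxity, and scores the round-trip RMSE in degrees.

## Worked example

```python
import numpy as np
import capsulereg as cr

# synthetic 4-mode attachment population and its shape model
population = cr.synthetic_attachment_population(cr.PopulationConfig(n_subjects=150, seed=12))
shape_model = cr.fit_shape_model(population, n_modes=4)

# probabilistic trials: 16 inputs -> 40 laxity metrics each
records = cr.generate_trial_dataset(200, shape_model, seed=3)
train, val = records[:170], records[170:]

model = cr.train_surrogate(train, cr.TRAINING_SETS[1])       # baseline training set
report = cr.closed_loop_validate(model, val, shape_model)    # predict -> re-simulate -> RMSE
print(f"composite RMSE {report.composite_mean:.2f} ± {report.composite_sd:.2f} deg")

rec = val[0]
pred = cr.predict_parameters(model, rec.laxity, rec.scores, clip=True)
print(np.round(pred.stiffness, 1), np.round(rec.params.stiffness, 1))
```

Output from this exact script:

```
composite RMSE 0.48 ± 0.26 deg
[43.3 71.3 56.1 65.  79.9 38.9] [43.1 70.4 54.6 65.  82.2 48.4]
```

The composite RMSE is the mean over held-out trials of each trial's RMSE
across all 40 laxity metrics: 0.48° here means the re-simulated laxity of the
surrogate-calibrated capsules reproduces the "measured" laxity to well under
a degree. The last line compares predicted and true sector stiffnesses (N/mm)
for one held-out hip — sectors that barely engage within the tested rotation
range (here sector 6) are predicted less precisely, yet contribute equally
little to laxity, which is why the laxity-level round-trip error stays small.

The same workflow is available from the shell:

```bash
capsulereg generate --n-trials 500 --seed 0 --out dataset.csv --shape-model-out shape.json
capsulereg train --set-id 1 --dataset dataset.csv --out model.json
capsulereg validate --model model.json --dataset dataset.csv --shape-model shape.json
capsulereg converge --dataset dataset.csv --shape-model shape.json --sizes 100,200,300,400,450
capsulereg predict --model model.json --laxity-csv laxity.csv --scores 0.3,-1.2,0.0,0.5
```

## Layout

- `capsulereg.geometry` — ellipse fitting, arc-length resampling, the
  six-sector capsule mesh, intertrochanteric-plane construction
- `capsulereg.wrapping` — sphere-wrapping shortest-path primitive
- `capsulereg.mechanics` — spring law, restoring torque, torque-ramp laxity
- `capsulereg.ssm` — attachment-site statistical shape model
- `capsulereg.sampling` — parameter distributions, LHS, trial generation
- `capsulereg.regression` — training-set registry, stepwise fits, prediction
- `capsulereg.validation` — closed loop, convergence study, set comparison
- `capsulereg.synthetic` — synthetic populations and specimens
- `capsulereg.io`, `capsulereg.cli` — file formats and the `capsulereg` CLI

See `docs/methods.md` for modeling assumptions, parameter choices, and known
limitations.
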