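# pettcp

Voxel-based tumor-control modeling from serial FDG-PET in esophageal cancer.

`pettcp` implements a radiobiological analysis of paired pre- and
post-chemoradiotherapy FDG-PET SUV volumes. Treating each voxel's
post/pre SUV ratio as a surrogate for the local clonogen survival
fraction, the per-patient mean voxel ratio **⟨SUV_R⟩** acts as the mean
survival ⟨S⟩ in a Poisson tumor-control model,

```
TCP = ∏_k exp(−N₀ f_k S_k) = exp(−N₀ ⟨S⟩),
```

and the probability of tumor recurrence is modeled directly as an
erf sigmoid of the surrogate,

```
TRP(⟨SUV_R⟩) = ½ [1 + erf(√π · γ₅₀ · (⟨SUV_R⟩ − SUVR₅₀))],    TCP = 1 − TRP,
```

parameterized so that the normalized slope at the midpoint equals γ₅₀
exactly. The two free parameters (SUVR₅₀, γ₅₀) are estimated from binary
recurrence outcomes by maximum likelihood on a parameter grid, with
joint two-degree-of-freedom likelihood-ratio confidence regions and
marginal confidence intervals obtained as region projections.

Because the underlying clinical images are not distributable, the
package ships a **synthetic cohort generator** that renders paired SUV
volumes whose per-patient surrogates follow configurable group
(responder / nonresponder) distributions, including the observed
correlation between baseline uptake and uptake decrease. See
[docs/methods.md](docs/methods.md) for the model, generator design,
assumptions and limitations.

## Package layout

| Module | Contents |
|---|---|
| `pettcp.tcp` | Poisson TCP forms, `SigmoidParams`, TRP/TCP curves |
| `pettcp.surrogates` | SUV volumes, tumor delineation (SUV > 2.5), `SurrogateSet`, cohort tables, NIfTI I/O |
| `pettcp.simulate` | `GeneratorConfig`, patient target sampling (Gaussian copula), volume rendering, `generate_cohort` |
| `pettcp.model` | `TumorRecurrenceModel` / `TumorRecurrenceResults` (statsmodels-style), grid ML, LR confidence regions |
| `pettcp.stats` | Welch t group comparisons, Pearson correlations, binned calibration with Wilson intervals |
| `pettcp.pipeline`, `pettcp.cli` | End-to-end reproducible pipeline and the `pettcp` command-line tool |

## Worked example

```python
from pettcp import (GeneratorConfig, generate_cohort, build_cohort_table,
                    TumorRecurrenceModel)

cfg = GeneratorConfig(n_patients=20, seed=42)   # 9 responders, 11 nonresponders
patients, manifest = generate_cohort(cfg)
table = build_cohort_table(patients)            # one row per patient

model = TumorRecurrenceModel.from_cohort_table(table)  # surrogate: mean_ratio
res = model.fit()                                      # 241×241 grid, 90% CIs
print(res.summary())
```

which prints:

```
Tumor Recurrence Probability (erf sigmoid) — maximum likelihood
==================================================================
surrogate: mean_ratio    n = 20 (11 nonresponders)
max log-likelihood: -11.1154
------------------------------------------------------------------
parameter   estimate      90% CI (joint LR region projection)
suvr50        0.4525      [0.0500, 0.6681]
gamma50       2.3000      [0.1500, 5.1250]
------------------------------------------------------------------
identifiable: True   region touches grid boundary: True   refined: False
clamped probability terms on grid: 23441
```

`res.predict_trp(x)` / `res.predict_tcp(x)` evaluate the fitted curves,
`res.confidence_region(level)` returns the boolean region mask plus
marginal CIs, and `res.save_json(path)` writes a deterministic record.

## Command line

The `pettcp` tool chains the stages; every output carries a config hash
and seed for provenance:

```sh
pettcp simulate --n-patients 20 --seed 42 --out cohort/     # NIfTI volumes + manifest
pettcp surrogates --outcomes cohort/manifest.csv --out cohort.csv
pettcp fit --table cohort.csv --out fit.json
pettcp report --config run.yaml                              # full pipeline from YAML
pettcp all --seed 42 --out run/                              # simulate→surrogates→fit→report
```

`pettcp surrogates --pre pre.nii --post post.nii` also scores a single
image pair, printing the surrogate set as JSON.

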