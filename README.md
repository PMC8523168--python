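# invasim

**Composition, productivity and invasion resistance in bacterial
microcosms** — a tested Python re-implementation of the inference chain
that asks: when a bacterial community resists an invading strain, how
much of that resistance is explained by *who* was inoculated
(composition) versus *how much the community grew* (productivity)?

The pipeline targets the data anatomy of common-garden microcosm
invasion experiments: an OTU count table describing each community's
starting composition, a rooted 16S phylogeny, per-community phenotype
assays (cell yield, respiration, ATP, enzyme activities at days 7/14),
and luminescence-based survival assays of two lux-tagged *Pseudomonas*
invaders at three time points with a detection threshold below which
readings are sterile background.

It is written for microbial ecologists who want each stage as a reusable,
unit-tested function rather than a one-off analysis script.

## What it computes

| Stage | Contents |
|---|---|
| `invasim.simulate` | synthetic studies with a known composition → productivity → invasion causal structure (planted OTU groups, phylogeny, censored replicate luminescence) |
| `invasim.preprocess` | rare-OTU/low-depth filtering, lux→cells calibration, detection-limit flagging, replicate averaging, log transforms |
| `invasim.diversity` | Gini–Simpson, Rao's quadratic entropy, abundance-weighted invader–community phylogenetic distance |
| `invasim.dimreduce` | taxonomic aggregation (5 ranks), Jensen–Shannon PCoA, SparCC signed co-occurrence network → functional groups |
| `invasim.rf` | random-forest regressions, out-of-bag permutation importance (%IncMSE), pseudo-R², reduction comparison |
| `invasim.sem` | maximum-likelihood latent-variable SEMs for the No/Partial/Complete mediation hypotheses; AICc, CFI, LRT; product-of-coefficients mediation decomposition |
| `invasim.sensitivity` | permutation sensitivity analysis of below-detection survival values |
| `invasim.pipeline` / CLI `invasim` | configuration-driven orchestration with a reproducibility manifest |

The core statistical model is a three-latent structural equation model.
With Composition **C** (measured by functional-group abundances and
Simpson diversity), Productivity **P** (cell yields at days 7 and 14) and
Invasion **I** (six survival endpoints), the Partial Mediation structure is

```
P = a·C + ζ_P
I = b·P + c′·C + ζ_I
```

estimated by minimising the normal-theory discrepancy
`F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p`. The indirect (mediated) effect
is `a·b`, the total composition effect `c′ + a·b`, and the proportion
mediated their ratio. Complete Mediation fixes `c′ = 0` (nested, 1 df);
No Mediation drops the productivity paths. Models are compared by AICc,
CFI and the likelihood-ratio test, and the robustness of the winner to
detection-limit noise is checked by refitting all three models under
permutations of the censored survival values.

## Worked example

```python
from invasim.simulate import SynthConfig, simulate_dataset
from invasim.sem import build_mediation_models, fit_sem, \
    compare_models, mediation_decomposition
from invasim.preprocess import TransformSpec, convert_and_flag, \
    average_replicates
from invasim.simulate import calibration_models
import pandas as pd

cfg = SynthConfig(seed=1009)          # 680 communities, 200 OTUs
data = simulate_dataset(cfg)
print(data["ground_truth"].summary()["proportion_mediated"])
# 0.5440196422307961                  <- planted truth

# calibrate, flag and average the invasion assays
inv = average_replicates(convert_and_flag(
    data["invasion"], calibration_models(cfg), cfg.detection_threshold_lux))
endpoints = inv.endpoint_wide()

# indicators: composition features + yields + transformed endpoints
spec = TransformSpec()
yields = spec.transform_explanatory(
    data["phenotypes"].values[["cell_yield_d7", "cell_yield_d14"]])
survival = endpoints.apply(spec.transform_response)
```

Running the three mediation models on the assembled indicator table (see
`invasim.pipeline.run_pipeline` for the full assembly including the
network-derived composition features) prints, for the seed above:

```
             model     chi2  df     aicc   cfi
complete_mediation 1253.425 150 8697.808 0.753
 partial_mediation 1251.980 149 8698.626 0.753
      no_mediation 1342.571 151 8784.827 0.733
recovered: 0.37 truth: 0.544
```

Both mediation models decisively beat No Mediation (ΔAICc ≈ 87), and
Complete edges out Partial by under one AICc unit — exactly the
behaviour expected when the planted direct composition effect (−0.13) is
small and the composition latent only partly captures the planted driver
score. The end-to-end recovered proportion mediated (0.37 against a
planted 0.544) reflects that attenuation; fitting the same models on
indicators drawn directly from the latent structure recovers the planted
proportion to within about 0.05 when averaged over ten datasets (the
`latent_model_recovered_proportion_mediated` entry of the acceptance
output; see `docs/methods.md`, "Known limitations").

The same chain is available from the shell:

```bash
invasim simulate --seed 1 --outdir sim/
invasim run-all --seed 1 --outdir run/     # full chain + manifest.json
```

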