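# drugcombo

Quantitative analysis of two-drug combination experiments: median-effect
dose–response fitting, the Chou–Talalay combination index (CI),
dose-reduction index (DRI), isobologram and curve-shift analysis,
checkerboard summaries, and time-resolved IC50 estimation from
impedance-based (real-time cell analyzer) traces. A synthetic-data module
generates MTT-style viability plates and kinetic cell-index traces with
known ground truth, so every stage of the pipeline can be verified in a
closed loop without laboratory data.

## Who this is for

Pharmacologists and computational biologists analysing in vitro drug
combination studies — e.g. a potent natural product paired with a standard
chemotherapeutic in a constant-ratio (diagonal) design — who want a
scriptable, tested alternative to point-and-click tools for the standard
CI/isobologram workflow.

## The model

Single-agent cytotoxicity follows the mass-action median-effect equation

```
fa / fu = (D / Dm)^m,        fu = 1 − fa,
```

where `fa` is the fraction of cells affected at dose `D`, `Dm` the
median-effect dose (IC50) and `m` the shape exponent. Taking log10 of both
sides linearises the relation, so `(Dm, m)` are estimated by ordinary least
squares on the median-effect plot `log10(fa/fu)` vs `log10 D`; the plot's
correlation coefficient `r` measures conformity to the model.

For a constant-ratio mixture fitted on total molar dose, the combination
index at effect level `fa` is

```
CI(fa) = d_a / Dx_a(fa) + d_b / Dx_b(fa)
```

with `(d_a, d_b)` the component doses of the mixture achieving `fa` and
`Dx_i(fa)` the single-agent doses achieving the same effect. CI < 1
indicates synergism, CI = 1 additivity, CI > 1 antagonism. The
dose-reduction index `DRI_i = Dx_i(fa) / d_i` obeys
`1/DRI_a + 1/DRI_b = CI` exactly.

The synthetic generator plants an interaction level α on the Loewe scale —
a mixture dose produces the `fa` solving
`d_a/Dx_a(fa) + d_b/Dx_b(fa) = α` — so the true CI of the generated
surface equals α at every effect level, and pipeline recovery of α is a
complete end-to-end test.

## Worked example

```python
import drugcombo as dc
from drugcombo import reporting
import pandas as pd

# two agents: a steep nanomolar drug and a ~60-fold less potent one
rm  = dc.MedianEffectFit(dm=6.0,   m=2.0, drug_label="RM")
dox = dc.MedianEffectFit(dm=356.0, m=1.0, drug_label="DOX")
ratio, equip = dc.potency_ratio(rm, dox)
print(f"potency ratio {ratio:.2f}, equipotent design {equip[0]}:{equip[1]}")
# -> potency ratio 59.33, equipotent design 1:60

# simulate a 1:60 constant-ratio experiment with planted synergy (alpha=0.5)
truth  = dc.SyntheticTruth(alpha=0.5, viability_sd=3.0, seed=1)
design = dc.CombinationDesign("RM", "DOX", 1, 60)
table = pd.concat([
    dc.generate_single_drug_plate(truth, "a"),
    dc.generate_single_drug_plate(truth, "b"),
    dc.generate_combination_plate(truth, design, include_single_controls=False),
], ignore_index=True)

profile = reporting.ci_profile_from_tables(table, design, dc.AnalysisConfig())
print(profile.to_frame())
#    fa_level   ci_mean    ci_sem classification  n_trials
# 0      0.50  0.463503  0.001994      synergism         3
# 1      0.75  0.480353  0.018509      synergism         3
# 2      0.90  0.533170  0.037058      synergism         3
# 3      0.95  0.591583  0.052622      synergism         3
```

The recovered CI tracks the planted interaction (0.5) across inhibition
levels and is classified as synergism throughout; the residual spread
around α reflects per-well noise and the linearised fit, quantified in the
test suite.

The same pipeline is available from the shell:

```
drugcombo simulate --kind combination --alpha 0.5 --ratio 1:60 --seed 1 --out sim
drugcombo ci sim/combination.csv --drug-a RM --drug-b DOX --ratio 1:60 --out results
drugcombo fit sim/combination.csv --out results
drugcombo kinetics traces.csv --t-treat 24 --out results
```

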