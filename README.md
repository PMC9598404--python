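# opea

Analysis pipeline for the **oxidative potential of exhaled air (OPEA)** — a
candidate non-invasive biomarker of oxidative stress in the respiratory tract.

## The problem

An electrochemical sensor measures how strongly an air sample oxidizes a probe
solution. The raw signal is a kinetic trace: an absorption index sampled every
2 s over 3 minutes. The oxidation rate (the slope of that trace in a fixed
window) is converted through a linear calibration into an oxidative potential
(OP) in pmol of H₂O₂-equivalents per litre of air. Because the instrument
response drifts with ambient conditions, each participant's exhaled-air OP is
normalized by an ambient-air OP measured in the same session:

```
OPEA = log10(OP_exhaled / OP_ambient)          (dimensionless)
```

A negative OPEA means exhaled air oxidizes the probe less than the ambient
air — the expected situation in healthy adults, whose respiratory tract lining
fluid scavenges oxidants. To make the biomarker usable, a population study must
(a) describe OPEA across participant characteristics, (b) test whether groups
with respiratory abnormality (airway obstruction below the spirometric lower
limit of normal, recent seroconversion) have higher OPEA, and (c) establish a
**reference interval** — the central 95 % range in healthy adults — following
the CLSI C28-A3 approach: exclude unhealthy participants, remove statistical
outliers by Tukey fences, compute mean ± 1.96 SD, and smooth the limits by
bootstrap.

This package implements that entire chain as a library plus a thin CLI:

| module | purpose |
|---|---|
| `opea.io` | trace / cohort / calibration / LMS file formats |
| `opea.kinetics` | windowed OLS slope fit, R² QC, calibration, replicate pooling |
| `opea.normalize` | exhaled/ambient pairing and log10 normalization |
| `opea.spirometry` | LMS percentile curves, LLN flags at the 5th percentile |
| `opea.stats` | health classification, descriptive tables, one-sided t / ANOVA |
| `opea.reference` | Tukey outlier removal, mean ± 1.96 SD, bootstrap CIs |
| `opea.simulate` | synthetic cohort + trace generator with known ground truth |
| `opea.pipeline`, `opea.cli` | end-to-end runner and command-line interface |

## Worked example

From raw triplicate traces to one participant's OPEA
(`examples/01_trace_to_opea.py`):

```python
from opea import aggregate_replicates, calibrate, fit_slope, normalize
from opea.simulate import DEFAULT_CALIBRATION, TraceSpec, gen_trace

cal = DEFAULT_CALIBRATION
exhaled = gen_trace(TraceSpec(true_op=1.87, cal=cal), seed=1, start_id=1, role="exhaled")
ambient = gen_trace(TraceSpec(true_op=2.00, cal=cal), seed=2, start_id=4, role="ambient")

ops_exh = [calibrate(fit_slope(t), cal) for t in exhaled]
ops_amb = [calibrate(fit_slope(t), cal) for t in ambient]
record = normalize(aggregate_replicates(ops_exh), aggregate_replicates(ops_amb),
                   participant_id="demo")
print(f"OPEA = {record.opea:+.4f}")
```

Output (deterministic):

```
id 1 (exhaled): slope 1.868e-03 s^-1, R^2 0.9988, OP 1.868 pmol/L_air, QC pass
id 2 (exhaled): slope 1.885e-03 s^-1, R^2 0.9985, OP 1.885 pmol/L_air, QC pass
id 3 (exhaled): slope 1.875e-03 s^-1, R^2 0.9992, OP 1.875 pmol/L_air, QC pass
id 4 (ambient): slope 1.987e-03 s^-1, R^2 0.9986, OP 1.987 pmol/L_air, QC pass
id 5 (ambient): slope 1.993e-03 s^-1, R^2 0.9990, OP 1.993 pmol/L_air, QC pass
id 6 (ambient): slope 1.987e-03 s^-1, R^2 0.9981, OP 1.987 pmol/L_air, QC pass

pooled exhaled OP : 1.876 pmol/L_air
pooled ambient OP : 1.989 pmol/L_air
OPEA = log10(exhaled/ambient) = -0.0253 (dimensionless)
```

The population-level flow (`examples/04_reference_interval.py`) reproduces the
study design on a synthetic cohort of 247 participants — 26 excluded as
unhealthy, one Tukey outlier removed, 220 in the reference sample:

```
participants            : 247
healthy                 : 247 - 26 unhealthy = 221
outliers removed (Tukey): 1 ['P0192']
reference sample        : 220
mean                    : -0.0292372
standard deviation      : 0.0105765
lower limit             : -0.0499135  90% CI (-0.051636, -0.0483185)
upper limit             : -0.0087072  90% CI (-0.0109951, -0.0068466)
```

The other examples cover spirometry LLN flagging (`02`), descriptive and
comparison tables (`03`), and the full file-to-artifact pipeline (`05`).
The same pipeline is scriptable from the shell:

```sh
opea simulate --n 60 --seed 7 --outdir fx/
opea run-all --cohort fx/cohort.csv --traces fx/traces.txt \
    --pairing fx/pairing.json --calibration fx/calibration.yaml \
    --lms fx/lms.csv --outdir out/ --seed 7
```

Every run with the same inputs and seed reproduces its outputs byte for byte
(the manifest records counts and parameters, never timestamps).

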