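"""From raw kinetic traces to one participant's normalized OPEA value.

Simulates triplicate exhaled-air and ambient-air measurements (absorption
index sampled every 2 s for 180 s), fits the 60-150 s slope of each, converts
slopes to pmol/L of air through the linear calibration, pools the replicates,
and forms the dimensionless log10(exhaled/ambient) ratio.
"""

from opea import aggregate_replicates, calibrate, fit_slope, normalize
from opea.simulate import DEFAULT_CALIBRATION, TraceSpec, gen_trace

cal = DEFAULT_CALIBRATION  # 1000 pmol/L_air per s^-1, zero intercept

exhaled = gen_trace(TraceSpec(true_op=1.87, cal=cal), seed=1, start_id=1, role="exhaled")
ambient = gen_trace(TraceSpec(true_op=2.00, cal=cal), seed=2, start_id=4, role="ambient")

ops_exh, ops_amb = [], []
for trace, sink in [(t, ops_exh) for t in exhaled] + [(t, ops_amb) for t in ambient]:
    fit = fit_slope(trace)  # OLS on the 46 points inside [60, 150] s
    op = calibrate(fit, cal)
    sink.append(op)
    print(
        f"id {trace.measurement_id} ({trace.role}): slope {fit.slope:.3e} s^-1, "
        f"R^2 {fit.r2:.4f}, OP {op.value:.3f} pmol/L_air, QC {'pass' if op.qc_pass else 'FAIL'}"
    )

op_exhaled = aggregate_replicates(ops_exh)
op_ambient = aggregate_replicates(ops_amb)
record = normalize(op_exhaled, op_ambient, participant_id="demo")

print(f"\npooled exhaled OP : {op_exhaled:.3f} pmol/L_air")
print(f"pooled ambient OP : {op_ambient:.3f} pmol/L_air")
print(f"OPEA = log10(exhaled/ambient) = {record.opea:+.4f} (dimensionless)")
print("A negative OPEA means the exhaled air oxidizes the probe less than the ambient air.")
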