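"""The full workflow from instrument files to result tables.

Writes a self-consistent fixture set (trace dump, cohort CSV, pairing map,
calibration, LMS coefficients) into a temporary directory, then runs every
stage — trace reduction, spirometry flagging, health classification, summary
tables, reference interval — and prints the per-stage counts.

The same workflow is available from the shell:
    opea simulate --n 60 --seed 7 --outdir fx/
    opea run-all --cohort fx/cohort.csv --traces fx/traces.txt \
        --pairing fx/pairing.json --calibration fx/calibration.yaml \
        --lms fx/lms.csv --outdir out/ --seed 7
"""

import json
import tempfile
from pathlib import Path

from opea import RunConfig, run_all
from opea.simulate import CohortSpec, write_fixtures

with tempfile.TemporaryDirectory() as tmp:
    # Group effects off: with the narrow healthy spread they would dominate the
    # Tukey fences and most of the shifted group would be excluded as outliers.
    fx = write_fixtures(
        Path(tmp) / "fx",
        spec=CohortSpec(n=60, seed=7, serology_effect=0.0, obstruction_effect=0.0),
    )
    outputs = run_all(
        RunConfig(
            cohort=str(fx["cohort"]),
            traces=str(fx["traces"]),
            pairing=str(fx["pairing"]),
            calibration=str(fx["calibration"]),
            lms=str(fx["lms"]),
            outdir=str(Path(tmp) / "out"),
            seed=7,
        )
    )
    manifest = json.loads(outputs["manifest"].read_text())
    table3 = json.loads(outputs["table3"].read_text())

print("artifacts:", ", ".join(sorted(outputs)))
print("stage counts:", manifest["counts"])
print(
    f"reference interval: [{table3['lower']:+.4f}, {table3['upper']:+.4f}] "
    f"from n={table3['n_reference']} healthy participants"
)
print("Re-running with the same config and seed reproduces every output byte for byte.")
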