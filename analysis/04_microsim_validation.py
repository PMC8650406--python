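"""Validate the deterministic cohort recursion against the
individual-level microsimulation oracle.

The microsimulation pushes simulated patients through the same
transition matrices, costs, utilities and discount factors, so the two
must agree within Monte-Carlo error; systematic disagreement would
indicate a defect in the cohort recursion itself.
"""

import dataclasses
import sys
from pathlib import Path

import pandas as pd

from trd_cea import Arm, Perspective, Variant, default_parameters, run_cohort
from trd_cea.io_utils import run_manifest, write_manifest
from trd_cea.synthetic import microsimulate

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

N = int(sys.argv[1]) if len(sys.argv) > 1 else 100_000
SEED = int(sys.argv[2]) if len(sys.argv) > 2 else 20260930

bundle = default_parameters()
rows = []
for variant, arm in (
    (Variant.MAIN, Arm.ECT),
    (Variant.MAIN, Arm.ESKETAMINE),
    (Variant.MAINTENANCE, Arm.ECT),
):
    settings = dataclasses.replace(
        bundle.settings, arm=arm, variant=variant, perspective=Perspective.SOCIETAL
    )
    cohort = run_cohort(settings, bundle)
    micro = microsimulate(settings, bundle, N, seed=SEED)
    z_cost = (micro.mean_cost - cohort.total_cost) / micro.se_cost
    z_qaly = (micro.mean_qaly - cohort.total_qaly) / micro.se_qaly
    rows.append(
        {
            "variant": variant.value,
            "arm": arm.value,
            "n": N,
            "cohort_cost": cohort.total_cost,
            "microsim_cost": micro.mean_cost,
            "se_cost": micro.se_cost,
            "z_cost": z_cost,
            "cohort_qaly": cohort.total_qaly,
            "microsim_qaly": micro.mean_qaly,
            "se_qaly": micro.se_qaly,
            "z_qaly": z_qaly,
        }
    )
    print(
        f"{variant.value:>11}/{arm.value:<10} cohort {cohort.total_cost:>9,.0f} GBP, "
        f"microsim {micro.mean_cost:>9,.0f} +- {micro.se_cost:,.0f} (z={z_cost:+.2f}); "
        f"QALY {cohort.total_qaly:.3f} vs {micro.mean_qaly:.3f} (z={z_qaly:+.2f})"
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "microsim_validation.csv", index=False)
write_manifest(
    OUT / "microsim_validation.manifest.json",
    run_manifest("analysis/04_microsim_validation.py", bundle, seeds={"microsim": SEED}),
)
ok = (df.z_cost.abs() < 3).all() and (df.z_qaly.abs() < 3).all()
print(f"\nAll configurations within 3 Monte-Carlo SE of the cohort totals: {ok}")
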