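"""Simulate a small two-site cohort and produce the full report bundle.

Generates ~4 x 800 patients under the default study conditions, runs
ascertainment, alerting, cohort filtering and all the impact statistics,
and prints the flow accounting, the incidence table and the adjusted
difference-in-differences summaries.
"""
import json
import tempfile
from pathlib import Path

from aki_impact.pipeline import RunConfig, run_pipeline

out = Path(tempfile.mkdtemp()) / "report"
bundle = run_pipeline(
    RunConfig(out_dir=out, simulate={"n_patients_per_cell": 800, "seed": 7})
)

print("flow accounting:")
print(json.dumps(bundle.exclusion_tally, indent=2))

print("\nincident HA-AKI by site (post vs pre, Woolf CI, exact p):")
print(bundle.incidence.to_string(index=False))

print("\nadjusted DiD interaction estimates:")
for name, r in bundle.did_summaries.items():
    if isinstance(r, dict) and "effect" in r:
        print(
            f"  {name:28} effect={r['effect']:.3f} "
            f"({r['ci_low']:.3f}-{r['ci_high']:.3f}) p={r['p_value']:.3f} "
            f"[{r['scale']}, {r['method']}]"
        )

# With the default planted effects (OR 0.93 on incidence, 0.73 on mortality
# given HA-AKI) a cohort this small will usually show point estimates in the
# right direction with wide intervals -- mirroring why the source design
# needed ~7,000 admissions per cell.
print(f"\nfull bundle written under {out}")
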