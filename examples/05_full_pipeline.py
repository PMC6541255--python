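"""One-command pipeline run from a YAML configuration.

Builds a small synthetic run configuration, executes every stage (wind,
event, drift, catchment, mortality scenarios), and prints the per-
scenario mortality table the pipeline writes to its report.
"""

import tempfile
from pathlib import Path

import yaml

from carcassdrift.pipeline import run_all, validate_config

with tempfile.TemporaryDirectory() as tmp:
    cfg_path = Path(tmp) / "run.yaml"
    cfg_path.write_text(yaml.safe_dump({
        "seed": 7,
        "out_dir": str(Path(tmp) / "out"),
        "n_day": 21,
        "n_perm": 500,
        "n_particles": 200,
        "dmax_list": [5, 10, 20],
        "float_medians": [7.0, 9.0],
        "synth": {"deaths_per_day": 100, "survey_interval": 5},
    }))
    cfg = validate_config(cfg_path)
    report = run_all(cfg)

print(f"truth total: {report['truth_total']}")
print("d_max  float  median  95% CI")
for row in report["mortality"]:
    lo, hi = row["ci95"]
    print(f"{row['d_max_km']:>5.0f}  {row['float_median_days']:>5.0f}  "
          f"{row['median']:>6.0f}  ({lo:.0f}, {hi:.0f})")
# Medians grow with the assumed offshore extent d_max (a wider at-sea
# distribution means fewer of the dead reach the beach) and shrink
# slightly from the 7- to the 9-day float scenario.
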