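"""Project intervention coverage 2015-2025 under BAU and the four scale-ups."""

import argparse
import json
from pathlib import Path

from u5mproj.panel import CountyYearPanel
from u5mproj.scenarios import build_scenario


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # uniform interface; stage is deterministic
    ap.add_argument("--outdir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.outdir)

    panel = CountyYearPanel.from_csv(out / "panel.csv")
    factors = json.loads((out / "selection.json").read_text())["model_factors"]
    model_panel = CountyYearPanel(panel.data, factors)

    for sid in ("BAU", "S1", "S2", "S3", "S4"):
        traj = build_scenario(sid, model_panel)
        traj.to_csv(out / f"trajectory_{sid.lower()}.csv")
        mean_2025 = traj.data[traj.data.year == 2025]["value"].mean()
        print(f"{sid}: mean projected coverage 2025 = {100 * mean_2025:.1f}%")


if __name__ == "__main__":
    main()
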