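"""Reduce the candidate factors to the set entering the Bayesian model.

Bivariate p<0.2 screen, redundancy exclusions, the ANC-delivered
intervention index, and the two elastic-net models (individual components
vs. the PCA index) compared by county-grouped cross-validated MSE.
"""

import argparse
import json
from pathlib import Path

from u5mproj.panel import CountyYearPanel
from u5mproj.pipeline import ANC_COMPONENTS
from u5mproj.selection import ScreeningConfig, run_model_pair


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)  # uniform interface; stage is deterministic
    ap.add_argument("--outdir", default="results/analysis")
    args = ap.parse_args()
    out = Path(args.outdir)

    panel = CountyYearPanel.from_csv(out / "panel.csv")
    sel = run_model_pair(panel, ScreeningConfig(), anc_components=ANC_COMPONENTS)

    payload = {
        "screened": sel.screened,
        "excluded_redundant": sel.excluded_redundant,
        "anc_index_loadings": sel.anc_index_loadings,
        "chosen_model": sel.chosen_model,
        "cv_mse": {str(k): v for k, v in sel.cv_mse.items()},
        "retained": sel.retained,
        "model_factors": [f for f in sel.retained if f in panel.factors],
    }
    (out / "selection.json").write_text(json.dumps(payload, indent=2))

    print(f"screened {len(sel.screened)}/{len(panel.factors)} factors at p<0.2")
    print(
        f"model {sel.chosen_model} won (CV MSE {sel.cv_mse[1]:.4f} vs "
        f"{sel.cv_mse[2]:.4f}); retained: {', '.join(sel.retained)}"
    )


if __name__ == "__main__":
    main()
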