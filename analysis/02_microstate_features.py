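"""Two-level microstate segmentation and the 24 dynamics features.

Stage 1 (patients vs controls): individual GFP-peak clustering, per-group
pooling, canonical A-D labelling, windowed back-fit, feature extraction.
Stage 2 repeats the clustering on the two patient subtypes only.

Writes results/stage{1,2}_features.csv, the group maps, and a GEV summary.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, SEED, build_clean_cohort
from microdyn.pipeline import PipelineConfig, microstate_stage


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort, clean = build_clean_cohort()
    meta = cohort.metadata.set_index("subject_id")
    cfg = PipelineConfig(n_restarts_individual=10, n_restarts_group=30)

    summary = {}
    stages = {
        "stage1": (clean, meta.index, meta["group"]),
        "stage2": (
            [r for r, g in zip(clean, meta["group"]) if g == "ADHD"],
            meta.index[meta["group"] == "ADHD"],
            meta.loc[meta["group"] == "ADHD", "subtype"],
        ),
    }
    for stage, (recs, ids, groups) in stages.items():
        feats, models, mean, _, gev = microstate_stage(
            recs, list(ids), groups, cfg, SEED
        )
        feats.to_csv(RESULTS / f"{stage}_features.csv")
        for g, model in models.items():
            pd.DataFrame(
                model.maps.T, index=recs[0].channel_names, columns=model.labels
            ).to_csv(RESULTS / f"{stage}_maps_{g}.csv")
        summary[stage] = {
            "mean_gev_pct": round(100 * float(np.mean(gev)), 2),
            "per_group_gev_pct": {
                g: round(
                    100 * float(np.mean(gev[(groups == g).to_numpy()])), 2
                )
                for g in models
            },
        }
        print(f"{stage}: mean GEV {summary[stage]['mean_gev_pct']:.2f}% "
              f"({', '.join(f'{g}: {v}%' for g, v in summary[stage]['per_group_gev_pct'].items())})")

    (RESULTS / "gev_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
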