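"""Group statistics on the microstate features, plus the demographic
worked examples.

Reads results/stage{1,2}_features.csv (from 02) and metadata (from 01);
writes results/stage{1,2}_stats.json and results/demographics.json.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS
from microdyn import anova_interaction, chi_square_2x2, posthoc_t_tests, two_sample_t

FAMILIES = {
    "duration": "dur_",
    "occurrence": "occ_",
    "coverage": "cov_",
    "transitions": "tp_",
}


def stage_stats(stage: str, groups: pd.Series) -> dict:
    feats = pd.read_csv(RESULTS / f"{stage}_features.csv", index_col=0)
    groups = groups.reindex(feats.index)
    report = {"anova_interaction": {}, "significant_features": []}
    for family, prefix in FAMILIES.items():
        cols = [c for c in feats.columns if c.startswith(prefix)]
        res = anova_interaction(feats[cols].to_numpy(), groups.to_numpy())
        report["anova_interaction"][family] = {
            "F": round(res.statistic, 2),
            "df": list(res.df),
            "p": float(res.p),
        }
    posthoc = posthoc_t_tests(feats, groups, alpha=0.05, n_comparisons=24)
    posthoc.to_csv(RESULTS / f"{stage}_posthoc.csv")
    report["significant_features"] = list(
        posthoc.index[posthoc["significant"]]
    )
    return report


def main() -> None:
    meta = pd.read_csv(RESULTS / "metadata.csv").set_index("subject_id")

    demo = {}
    for name, table in {
        "sex_patients_vs_controls": [[40, 14], [84, 21]],
        "sex_subtypes": [[42, 9], [42, 12]],
        "hand_patients_vs_controls": [[0, 53], [8, 99]],
    }.items():
        res = chi_square_2x2(np.array(table))
        demo[name] = {"chi2": round(res.statistic, 2), "p": round(res.p, 3)}
    t = two_sample_t(summary=((11.6, 1.81, 54), (12.0, 1.71, 107)))
    demo["age_patients_vs_controls"] = {
        "t": round(t.statistic, 2), "p": round(t.p, 3)
    }
    (RESULTS / "demographics.json").write_text(json.dumps(demo, indent=2))
    print("demographics:", json.dumps(demo))

    report = {
        "stage1": stage_stats("stage1", meta["group"]),
        "stage2": stage_stats(
            "stage2", meta.loc[meta["group"] == "ADHD", "subtype"]
        ),
    }
    (RESULTS / "group_stats.json").write_text(json.dumps(report, indent=2))
    for stage in report:
        anova = report[stage]["anova_interaction"]
        sig = report[stage]["significant_features"]
        print(f"{stage}: interaction F "
              + ", ".join(f"{k}={v['F']}" for k, v in anova.items()))
        print(f"{stage}: {len(sig)} of 24 features significant after "
              f"Bonferroni: {sig}")


if __name__ == "__main__":
    main()
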