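"""SVM-RFE classification of patients vs controls and of the subtypes.

Stage 1 feeds the 24 microstate features plus significant delta and
theta/beta-ratio component loadings; stage 2 the 24 features plus
significant gamma loadings.  Writes results/classification.json with the
fold metrics and fold-wise feature-selection counts.
"""

import json
from pathlib import Path

import pandas as pd

from common import RESULTS, SEED
from microdyn import assemble_inputs, svm_rfe_cv


def _loadings(stage: str, bands: list[str]) -> list[pd.DataFrame]:
    tables = []
    for band in bands:
        path = RESULTS / f"{stage}_loadings_{band}.csv"
        if path.exists():
            tables.append(pd.read_csv(path, index_col=0))
    return tables


def main() -> None:
    meta = pd.read_csv(RESULTS / "metadata.csv").set_index("subject_id")
    report = {}
    for stage, bands, labels in (
        ("stage1", ["delta", "tbr"], (meta["group"] == "ADHD").astype(int)),
        (
            "stage2",
            ["gamma"],
            (meta.loc[meta["group"] == "ADHD", "subtype"] == "C").astype(int),
        ),
    ):
        feats = pd.read_csv(RESULTS / f"{stage}_features.csv", index_col=0)
        merged = assemble_inputs(feats, *_loadings(stage, bands))
        res = svm_rfe_cv(merged, labels.reindex(merged.index), seed=SEED)
        report[stage] = res.to_dict()
        top = sorted(
            res.selection_counts.items(), key=lambda kv: -kv[1]
        )[:5]
        print(f"{stage}: {merged.shape[1]} input features; best accuracy "
              f"{res.best_accuracy:.3f} (sensitivity {res.sensitivity:.3f}, "
              f"specificity {res.specificity:.3f})")
        print(f"{stage}: most-selected features {top}")

    (RESULTS / "classification.json").write_text(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
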