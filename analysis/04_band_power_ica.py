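"""Band power matrices and group ICA, with component tests.

Rebuilds the cohort, computes the seven subject x channel power matrices
(six bands + theta/beta ratio), decomposes each with extended-Infomax ICA
at M = 5, orients components (controls > patients; combined > inattentive
for stage 2), and Bonferroni-tests the loadings.  Writes power matrices,
significant-component loadings for the classifier, and a summary.
"""

import json

import numpy as np
import pandas as pd

from common import RESULTS, SEED, build_clean_cohort
from microdyn.spectral import (
    build_power_matrices,
    ica_decompose,
    orient_and_zscore,
    test_components,
)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort, clean = build_clean_cohort()
    meta = cohort.metadata.set_index("subject_id")
    mats = build_power_matrices(clean, list(meta.index))
    for band, pm in mats.items():
        pm.values.to_csv(RESULTS / f"power_{band}.csv")

    summary = {}
    stages = {
        "stage1": (meta.index, meta["group"], "HC"),
        "stage2": (
            meta.index[meta["group"] == "ADHD"],
            meta.loc[meta["group"] == "ADHD", "subtype"],
            "C",
        ),
    }
    for stage, (ids, groups, ref) in stages.items():
        summary[stage] = {}
        for band, pm in mats.items():
            sub = pm.__class__(values=pm.values.loc[ids], band=band)
            ica = orient_and_zscore(
                ica_decompose(sub, 5, seed=SEED), groups, ref
            )
            tests = test_components(ica, groups)
            sig = list(tests.index[tests["significant"]])
            summary[stage][band] = {
                "significant": sig,
                "p": {c: float(tests.loc[c, "p"]) for c in tests.index},
                "selected_channels": {
                    c: tests.loc[c, "selected_channels"] for c in sig
                },
            }
            if sig:
                loadings = ica.loadings[sig].copy()
                loadings.columns = [f"{band}_{c}" for c in loadings.columns]
                loadings.to_csv(RESULTS / f"{stage}_loadings_{band}.csv")
        found = {b: v["significant"] for b, v in summary[stage].items()
                 if v["significant"]}
        print(f"{stage}: significant components {found}")

    (RESULTS / "ica_summary.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
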