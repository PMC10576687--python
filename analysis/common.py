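"""Shared study configuration for the analysis drivers.

One scaled synthetic cohort (36 subjects, 60 s each) is used throughout so
the numbered scripts can be run independently yet stay consistent: each
script rebuilds the cohort deterministically from COHORT_SPEC and reads any
tables earlier scripts wrote under results/.
"""

from pathlib import Path

from microdyn import CohortSpec
from microdyn.preprocess import PreprocessConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"

COHORT_SPEC = CohortSpec(
    n_hc=12, n_adhd_c=12, n_adhd_i=12, duration_s=60.0, seed=7
)
PREPROCESS = PreprocessConfig(keep_s=60.0)
SEED = 7


def build_clean_cohort():
    """Simulate and preprocess the study cohort (deterministic)."""
    from microdyn import simulate_cohort
    from microdyn.preprocess import preprocess

    cohort = simulate_cohort(COHORT_SPEC)
    clean = [preprocess(rec, PREPROCESS) for rec in cohort.recordings]
    return cohort, clean
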