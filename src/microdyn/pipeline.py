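"""End-to-end orchestration of the two-stage analysis.

Stage 1 clusters group-level microstate maps across all patients and
controls, back-fits, extracts the 24 dynamics features, runs the
statistical battery and the band-power ICA (patients vs controls), and the
SVM-RFE classification.  Stage 2 repeats the clustering, features, stats,
ICA and classification on the two patient subtypes only, with freshly
clustered subtype maps.

Every run writes a manifest (seeds, shapes, content hashes of all outputs)
from which the run is reproducible.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import assemble_inputs, svm_rfe_cv
from .microstates import (
    backfit,
    cluster_microstates,
    compute_gev,
    compute_gfp,
    extract_features,
    features_to_frame,
    find_gfp_peaks,
    group_level_model,
    reorient_to_abcd,
)
from .preprocess import PreprocessConfig, preprocess
from .spectral import build_power_matrices, ica_decompose, orient_and_zscore, test_components
from .stats import (
    anova_interaction,
    kruskal_wallis_topography,
    posthoc_t_tests,
    subject_map_similarities,
)
from .synthetic import CohortSpec, simulate_cohort


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of a full run; every stage seed derives from ``seed``."""

    simulate: CohortSpec = field(default_factory=CohortSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    k: int = 4
    n_restarts_individual: int = 20
    n_restarts_group: int = 50
    backfit_half_width: int = 1   # ±1-sample evidence window for labelling
    ica_components: int = 5
    alpha: float = 0.05
    svm_c: float = 1.0
    n_folds: int = 5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config block(s): {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulate" in kwargs:
            kwargs["simulate"] = CohortSpec(**kwargs["simulate"])
        if "preprocess" in kwargs:
            pp = dict(kwargs["preprocess"])
            if "band" in pp:
                pp["band"] = tuple(pp["band"])
            if "exclude_channels" in pp:
                pp["exclude_channels"] = tuple(pp["exclude_channels"])
            kwargs["preprocess"] = PreprocessConfig(**pp)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        out = asdict(self)
        out["simulate"] = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in asdict(self.simulate).items()
        }
        return out


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _individual_models(recordings, k, n_restarts, seed):
    models = []
    for i, rec in enumerate(recordings):
        gfp = compute_gfp(rec)
        peaks = find_gfp_peaks(gfp)
        models.append(
            cluster_microstates(
                rec.data.T[peaks], k=k, n_restarts=n_restarts, seed=seed + i
            )
        )
    return models


def microstate_stage(
    recordings,
    subject_ids,
    group_labels,
    cfg: PipelineConfig,
    seed: int,
):
    """Individual -> per-group -> labelled maps -> back-fit -> features.

    Returns (feature frame, per-group labelled models, mean model,
    individual models, per-subject GEV).
    """
    individual = _individual_models(
        recordings, cfg.k, cfg.n_restarts_individual, seed
    )
    groups = pd.Series(group_labels, index=subject_ids)
    levels = sorted(groups.unique())
    group_models = {}
    for g in levels:
        members = [m for m, lab in zip(individual, groups) if lab == g]
        group_models[g] = group_level_model(
            members, k=cfg.k, n_restarts=cfg.n_restarts_group, seed=seed
        )
    labeled, mean = reorient_to_abcd([group_models[g] for g in levels])
    group_models = dict(zip(levels, labeled))

    feats, gevs = [], []
    for rec, sid in zip(recordings, subject_ids):
        model = group_models[groups[sid]]
        seq = backfit(rec, model, evidence_half_width=cfg.backfit_half_width)
        feats.append(extract_features(seq))
        gevs.append(compute_gev(model, rec, seq))
    frame = features_to_frame(feats, list(subject_ids))
    return frame, group_models, mean, individual, np.asarray(gevs)


def stats_stage(feature_frame, group_labels, individual, mean, alpha=0.05):
    """ANOVA interaction per family, post-hoc t, Kruskal-Wallis topography."""
    groups = pd.Series(group_labels, index=feature_frame.index)
    families = {
        "duration": [c for c in feature_frame.columns if c.startswith("dur_")],
        "occurrence": [c for c in feature_frame.columns if c.startswith("occ_")],
        "coverage": [c for c in feature_frame.columns if c.startswith("cov_")],
        "transitions": [c for c in feature_frame.columns if c.startswith("tp_")],
    }
    anova = {
        fam: anova_interaction(feature_frame[cols].to_numpy(), groups.to_numpy())
        for fam, cols in families.items()
    }
    posthoc = posthoc_t_tests(
        feature_frame, groups, alpha=alpha, n_comparisons=feature_frame.shape[1]
    )
    sims = subject_map_similarities(individual, mean)
    kw = kruskal_wallis_topography(sims, groups.to_numpy())
    return anova, posthoc, kw


def spectral_stage(recordings, subject_ids, group_labels, cfg, seed, reference_group):
    """Power matrices -> ICA -> orientation -> Bonferroni component tests."""
    matrices = build_power_matrices(recordings, list(subject_ids))
    groups = pd.Series(group_labels, index=subject_ids)
    results = {}
    for band, pm in matrices.items():
        ica = ica_decompose(pm, cfg.ica_components, seed=seed)
        ica = orient_and_zscore(ica, groups, reference_group)
        tests = test_components(ica, groups, alpha=cfg.alpha)
        results[band] = (ica, tests)
    return matrices, results


def _significant_loadings(results, bands):
    tables = []
    for band in bands:
        ica, tests = results[band]
        sig = tests.index[tests["significant"]]
        if len(sig):
            tab = ica.loadings[list(sig)].copy()
            tab.columns = [f"{band}_{c}" for c in tab.columns]
            tables.append(tab)
    return tables


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full two-stage analysis; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {
        "package_version": __version__,
        "config": PipelineConfig.to_dict(cfg),
        "stages": {},
        "outputs": {},
    }

    def log(stage, **info):
        manifest["stages"][stage] = {"elapsed_s": round(time.time() - t0, 2), **info}

    # --- simulate -----------------------------------------------------
    sim_spec = replace(cfg.simulate, seed=_stage_seed(cfg.seed, "simulate"))
    cohort = simulate_cohort(sim_spec)
    meta = cohort.metadata.set_index("subject_id")
    log("simulate", n_subjects=len(meta), seed=sim_spec.seed)

    # --- preprocess ---------------------------------------------------
    clean = [preprocess(rec, cfg.preprocess) for rec in cohort.recordings]
    log("preprocess", n_samples=clean[0].n_samples, fs=clean[0].fs)

    outputs: dict[str, Path] = {}

    def save_frame(frame: pd.DataFrame, name: str):
        path = out / name
        frame.to_csv(path, float_format="%.10g")
        outputs[name] = path

    meta_path = out / "metadata.csv"
    cohort.metadata.to_csv(meta_path, index=False)
    outputs["metadata.csv"] = meta_path

    # --- stage 1: patients vs controls --------------------------------
    sids = list(meta.index)
    groups1 = meta["group"]
    ms_seed = _stage_seed(cfg.seed, "microstates1")
    feats1, models1, mean1, indiv1, gev1 = microstate_stage(
        clean, sids, groups1, cfg, ms_seed
    )
    save_frame(feats1, "stage1_features.csv")
    for g, model in models1.items():
        frame = pd.DataFrame(
            model.maps.T, index=clean[0].channel_names, columns=model.labels
        )
        save_frame(frame, f"stage1_maps_{g}.csv")
    log(
        "microstates1",
        seed=ms_seed,
        mean_gev=float(np.mean(gev1)),
        group_gev={
            g: float(np.mean(gev1[(groups1 == g).to_numpy()])) for g in models1
        },
    )

    anova1, posthoc1, kw1 = stats_stage(feats1, groups1, indiv1, mean1, cfg.alpha)
    save_frame(posthoc1, "stage1_posthoc.csv")

    sp_seed = _stage_seed(cfg.seed, "spectral1")
    matrices, results1 = spectral_stage(clean, sids, groups1, cfg, sp_seed, "HC")
    for band, pm in matrices.items():
        save_frame(pm.values, f"power_{band}.csv")
    for band, (ica, tests) in results1.items():
        save_frame(ica.loadings, f"stage1_ica_{band}_loadings.csv")

    clf_tables = _significant_loadings(results1, ["delta", "tbr"])
    clf_input1 = assemble_inputs(feats1, *clf_tables)
    report1 = svm_rfe_cv(
        clf_input1,
        (groups1 == "ADHD").astype(int),
        n_folds=cfg.n_folds,
        seed=_stage_seed(cfg.seed, "classify1"),
        c=cfg.svm_c,
    )

    # --- stage 2: subtypes --------------------------------------------
    sub_mask = (meta["group"] == "ADHD").to_numpy()
    sub_ids = [s for s, m in zip(sids, sub_mask) if m]
    sub_recs = [r for r, m in zip(clean, sub_mask) if m]
    groups2 = meta.loc[sub_ids, "subtype"]
    ms2_seed = _stage_seed(cfg.seed, "microstates2")
    feats2, models2, mean2, indiv2, gev2 = microstate_stage(
        sub_recs, sub_ids, groups2, cfg, ms2_seed
    )
    save_frame(feats2, "stage2_features.csv")
    anova2, posthoc2, kw2 = stats_stage(feats2, groups2, indiv2, mean2, cfg.alpha)
    save_frame(posthoc2, "stage2_posthoc.csv")

    sp2_seed = _stage_seed(cfg.seed, "spectral2")
    matrices2, results2 = spectral_stage(
        sub_recs, sub_ids, groups2, cfg, sp2_seed, "C"
    )
    clf_tables2 = _significant_loadings(results2, ["gamma"])
    clf_input2 = assemble_inputs(feats2, *clf_tables2)
    report2 = svm_rfe_cv(
        clf_input2,
        (groups2 == "C").astype(int),
        n_folds=cfg.n_folds,
        seed=_stage_seed(cfg.seed, "classify2"),
        c=cfg.svm_c,
    )

    # --- report --------------------------------------------------------
    def stat_dict(res):
        return {"statistic": res.statistic, "df": list(res.df), "p": res.p}

    report = {
        "stage1": {
            "anova_interaction": {k: stat_dict(v) for k, v in anova1.items()},
            "kruskal_wallis": {k: stat_dict(v) for k, v in kw1.items()},
            "significant_components": {
                band: list(tests.index[tests["significant"]])
                for band, (ica, tests) in results1.items()
            },
            "classification": report1.to_dict(),
            "mean_gev": float(np.mean(gev1)),
        },
        "stage2": {
            "anova_interaction": {k: stat_dict(v) for k, v in anova2.items()},
            "kruskal_wallis": {k: stat_dict(v) for k, v in kw2.items()},
            "significant_components": {
                band: list(tests.index[tests["significant"]])
                for band, (ica, tests) in results2.items()
            },
            "classification": report2.to_dict(),
            "mean_gev": float(np.mean(gev2)),
        },
    }
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
    outputs["report.json"] = report_path

    manifest["outputs"] = {name: _sha256(path) for name, path in outputs.items()}
    log("done", n_outputs=len(outputs))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
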