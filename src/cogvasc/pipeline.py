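"""End-to-end runner: simulate -> preprocess -> GLM -> FC -> behavior ->
EV -> statistics -> classification.

A single :class:`RunConfig` (YAML-loadable, unknown keys rejected) is the
only source of parameters; every stage derives its seed deterministically
from the master seed, and every output CSV carries the config hash as a
leading ``#`` comment line, so identical config + seed reproduce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import pandas as pd

from . import behavior as beh
from . import classify as clf
from . import connectivity as conn
from . import cytometry as cyt
from . import glm
from . import preprocess as pre
from . import stats as st
from .io import CONDITIONS, make_task_design
from .simulate import (
    SimConfig,
    simulate_behavior,
    simulate_cohort,
    simulate_ev_sample,
    simulate_fnirs_session,
    subseed,
)

__all__ = [
    "RunConfig",
    "run_pipeline",
    "subject_features",
    "cohort_feature_matrix",
]


@dataclass
class RunConfig:
    """Parameters of one end-to-end run."""

    seed: int = 0
    n_cn: int = 8
    n_mci: int = 8
    out_dir: str | None = None
    # stage toggles
    run_nvc: bool = True
    run_fc: bool = True
    run_behavior: bool = True
    run_ev: bool = True
    run_classify: bool = True
    # analysis parameters
    fc_alpha: float = 0.05
    fc_n_surrogates: int = 200
    coupling_threshold: float = pre.DEFAULT_COUPLING_THRESHOLD
    dct_cutoff_hz: float = 0.009
    motion_correction: bool = True
    loocv_trees: int = 100
    final_trees: int = 500
    n_split_runs: int = 100
    top_k: int = 3
    n_events: int | None = None  # override EV events per aliquot

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where results land does not change them
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha1(text.encode()).hexdigest()[:12]


def _sim_config(config: RunConfig) -> SimConfig:
    sim = SimConfig(n_cn=config.n_cn, n_mci=config.n_mci, seed=config.seed)
    if config.n_events is not None:
        sim.ev = dict(sim.ev, n_events=config.n_events)
    return sim


def subject_features(
    subject: pd.Series,
    design,
    sim: SimConfig,
    config: RunConfig,
) -> dict:
    """All per-subject measurements used downstream (one session)."""
    out: dict = {"subject_id": subject["subject_id"]}
    rec = simulate_fnirs_session(subject, design, sim)
    quality = pre.assess_quality(rec, threshold=config.coupling_threshold)
    out["excluded"] = quality.excluded
    out["exclusion_reason"] = quality.reason
    if quality.excluded:
        return out
    if config.run_nvc:
        series = pre.nvc_preprocess(
            rec, motion_correction=config.motion_correction,
            dct_cutoff_hz=config.dct_cutoff_hz,
        )
        X = glm.build_design(design, rec.fs_hz, rec.n_time)
        out["betas"] = glm.first_level(series, X, subject_id=subject["subject_id"])
    if config.run_fc:
        fc_series = pre.fc_preprocess(rec)
        _, _, averaged = conn.subject_connectivity(
            fc_series, design, rec.montage, alpha=config.fc_alpha,
            n_surr=config.fc_n_surrogates,
            seed=subseed(sim.seed, "surr", subject["subject_id"]),
        )
        out["fc"] = averaged
    if config.run_behavior:
        trials = simulate_behavior(subject, design, sim)
        perf = [
            beh.block_performance(trials, condition=c) for c in CONDITIONS
        ]
        out["behavior"] = pd.DataFrame([vars(p) for p in perf])
    if config.run_ev:
        stained, fmo = simulate_ev_sample(subject, sim)
        gates = cyt.derive_gates(fmo)
        summaries = [cyt.summarize_aliquot(t, gates) for t in stained]
        out["ev"] = cyt.average_replicates(summaries)
    return out


def cohort_feature_matrix(
    seed: int,
    n_per_group: int = 17,
    n_events: int = 10_000,
    fc_n_surrogates: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort and push it through the full measurement chain.

    Returns (feature matrix, cohort table, beta table).  The defaults are
    the desk-scale problem size used by the validation suites: 17+17
    subjects (the classification sample size), 10k EV events per aliquot,
    100 surrogates per edge.
    """
    config = RunConfig(
        seed=seed, n_cn=n_per_group, n_mci=n_per_group,
        run_behavior=False, run_classify=False,
        n_events=n_events, fc_n_surrogates=fc_n_surrogates,
    )
    sim = _sim_config(config)
    cohort = simulate_cohort(sim)
    design = make_task_design(seed=subseed(seed, "design"))
    rows = [subject_features(r, design, sim, config) for _, r in cohort.iterrows()]
    rows = [r for r in rows if not r["excluded"]]
    betas = pd.concat([r["betas"] for r in rows], ignore_index=True)
    nvc = glm.ldlpfc_average(betas, sim.montage)
    ids = [r["subject_id"] for r in rows]
    fc = pd.DataFrame([r["fc"] for r in rows], index=ids)
    ev = pd.DataFrame([r["ev"] for r in rows], index=ids)
    features = clf.assemble_features(nvc, fc, ev, cohort)
    return features, cohort, betas


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns (and
    optionally writes) the report bundle."""
    sim = _sim_config(config)
    design = make_task_design(seed=subseed(config.seed, "design"))
    cohort = simulate_cohort(sim)
    results = [subject_features(row, design, sim, config) for _, row in cohort.iterrows()]
    report: dict = {"cohort": cohort, "config_hash": config.hash()}

    kept = [r for r in results if not r["excluded"]]
    report["exclusions"] = pd.DataFrame(
        [
            {"subject_id": r["subject_id"], "reason": r["exclusion_reason"]}
            for r in results
            if r["excluded"]
        ]
    )

    if config.run_nvc and kept:
        betas = pd.concat([r["betas"] for r in kept], ignore_index=True)
        report["betas"] = betas
        report["nvc_ldlpfc"] = glm.ldlpfc_average(betas, sim.montage)
        report["contrast_load_group"] = glm.cognitive_load_contrast(betas, cohort)
        report["contrast_2b"] = glm.second_level(
            betas, cohort, glm.group_difference_contrast("2b")
        )
    if config.run_fc and kept:
        fc = pd.DataFrame([r["fc"] for r in kept], index=[r["subject_id"] for r in kept])
        report["fc_metrics"] = fc
    if config.run_behavior and kept:
        rows = []
        for r in kept:
            b = r["behavior"].copy()
            b.insert(0, "subject_id", r["subject_id"])
            rows.append(b)
        report["behavior"] = pd.concat(rows, ignore_index=True)
    if config.run_ev and kept:
        report["ev"] = pd.DataFrame(
            [r["ev"] for r in kept], index=[r["subject_id"] for r in kept]
        )

    # statistics layer on the headline per-subject metrics
    tests = {}
    grp = cohort.set_index("subject_id")["group"]

    def _groups(series: pd.Series):
        g = grp.loc[series.index]
        return series[g == "CN"].to_numpy(), series[g == "MCI"].to_numpy()

    if "nvc_ldlpfc" in report and report["nvc_ldlpfc"].size > 3:
        cn, mci = _groups(report["nvc_ldlpfc"])
        tests["ldlpfc_beta"] = st.mann_whitney(cn, mci)
    if "fc_metrics" in report:
        for col in ("d_bar", "wd_bar", "d_ldp", "wd_ldp"):
            cn, mci = _groups(report["fc_metrics"][col])
            if cn.size and mci.size:
                tests[col] = st.mann_whitney(cn, mci)
    if "ev" in report:
        cn, mci = _groups(report["ev"]["ceev_ratio_pct"])
        if cn.size and mci.size:
            tests["ceev_ratio_pct"] = st.mann_whitney(cn, mci)
    report["tests"] = pd.DataFrame(
        [
            {
                "metric": k, "method": v.method, "statistic": v.statistic,
                "p_value": v.p_value,
            }
            for k, v in tests.items()
        ]
    )

    if config.run_classify and kept:
        have_ev = "ev" in report
        if not have_ev:
            warnings.warn("EV stage disabled: classification uses a reduced feature set")
        features = clf.assemble_features(
            nvc=report.get("nvc_ldlpfc", pd.Series(dtype=float)),
            fc_metrics=report.get("fc_metrics", pd.DataFrame()),
            ev_summaries=report["ev"] if have_ev else pd.DataFrame(
                {"ceev_ratio_pct": pd.Series(dtype=float)}
            ),
            cohort=cohort,
        ) if ("nvc_ldlpfc" in report and "fc_metrics" in report and have_ev) else None
        if features is None:
            cols = ["group", "age", "sex", "hypertension", "depression_prior"]
            features = cohort[["subject_id"] + cols].copy()
            if "nvc_ldlpfc" in report:
                features["ldlpfc_beta"] = report["nvc_ldlpfc"].reindex(
                    features["subject_id"]
                ).to_numpy()
            if "fc_metrics" in report:
                for col in ("wd_ldp", "d_ldp", "d_bar", "wd_bar"):
                    features[col] = report["fc_metrics"][col].reindex(
                        features["subject_id"]
                    ).to_numpy()
            features = features.dropna().reset_index(drop=True)
        feature_cols = [
            c for c in clf.NUMERIC_FEATURES + clf.CATEGORICAL_FEATURES
            if c in features.columns
        ]
        importances = clf.loocv_importance(
            features, feature_cols, n_trees=config.loocv_trees,
            seed=subseed(config.seed, "loocv"),
        )
        selected = clf.select_top_k(importances, k=config.top_k)
        single = clf.evaluate_split(
            features, selected, n_trees=config.final_trees,
            seed=subseed(config.seed, "single-split"),
        )
        repeated = clf.repeated_splits(
            features, selected, n_runs=config.n_split_runs,
            n_trees=config.final_trees, seed=subseed(config.seed, "splits"),
        )
        report["features"] = features
        report["importances"] = importances
        report["selected_features"] = selected
        report["single_split"] = single
        report["repeated_splits"] = repeated

    if config.out_dir:
        _write_outputs(report, Path(config.out_dir), config)
    return report


def _write_outputs(report: dict, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    h = config.hash()

    def dump(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# config_hash={h}\n")
            df.to_csv(fh, index=index)

    for name in ("cohort", "betas", "behavior", "tests", "exclusions",
                 "contrast_load_group", "contrast_2b", "features"):
        if name in report and isinstance(report[name], pd.DataFrame):
            dump(report[name], name)
    for name in ("fc_metrics", "ev"):
        if name in report:
            dump(report[name], name, index=True)
    if "nvc_ldlpfc" in report:
        dump(report["nvc_ldlpfc"].rename_axis("subject_id").reset_index(), "nvc_ldlpfc")
    if "importances" in report:
        dump(
            report["importances"].rename("gini_importance")
            .rename_axis("feature").reset_index(),
            "importances",
        )
    summary = {
        "config_hash": h,
        "selected_features": report.get("selected_features"),
        "single_split": report.get("single_split"),
        "repeated_splits": report.get("repeated_splits"),
        "n_excluded": int(len(report.get("exclusions", []))),
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, default=str))
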