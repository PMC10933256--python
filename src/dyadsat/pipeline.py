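"""End-to-end runner wiring the analysis stages in order.

simulate/ingest → temporal cleaning → RSFC → dyad similarity → repeated-CV
prediction with permutation inference → coefficient / importance
interpretation → session ANOVA.  Each stage's outputs are written under the
output directory as it completes, so a failure preserves finished stages.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, interpretation, io, prediction, preprocess, similarity
from .connectivity import compute_rsfc
from .synthetic import N_SESSIONS, SyntheticCohort, SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_all", "satisfaction_table", "target_vector"]

TARGET_CHOICES = ("pair_mean", "agreement", "subject_1", "subject_2")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    With ``cohort_dir=None`` a synthetic cohort is generated from
    ``synthetic`` (seeded by ``seed``) and written under the output
    directory.  Permutation counts default to a scaled-down test profile;
    ``full_scale=True`` switches to the full-scale setting (10,000
    permutation/null iterations, 100 importance baselines).
    """

    out_dir: str = "dyadsat-run"
    cohort_dir: str | None = None
    synthetic: SyntheticConfig | None = None
    model: prediction.ModelSpec = field(default_factory=prediction.ModelSpec)
    k: int = 10
    n_repeats: int = 20
    n_perm: int = 200
    n_null: int = 50
    K_importance: int = 5
    n_importance_baseline: int = 50
    target: str = "pair_mean"
    session: int = 1
    seed: int = 0
    cutoff_hz: float | None = 0.01
    write_intermediate: bool = True
    full_scale: bool = False

    def __post_init__(self):
        if self.target not in TARGET_CHOICES:
            raise ValueError(f"target must be one of {TARGET_CHOICES}")
        if self.session not in (1, 2, 3):
            raise ValueError("session must be 1, 2 or 3")
        for name in ("k", "n_repeats", "n_perm", "n_null", "K_importance"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.full_scale:
            self.n_perm = 10000
            self.n_null = 10000
            self.n_importance_baseline = 100


@dataclass
class RunReport:
    config: dict
    stage_files: dict
    satisfaction: dict
    anova: behavior.AnovaResult
    posthoc: behavior.PosthocResult
    prediction: dict
    permutation: dict
    coefficients: dict
    importance: dict
    version: str = ""
    seed: int = 0


def satisfaction_table(cohort: SyntheticCohort) -> pd.DataFrame:
    """Pair × session table of pair scores, per-subject scores and agreement."""
    rows = []
    for p, (a, b) in enumerate(cohort.pairs):
        for sess in range(N_SESSIONS):
            sa = float(np.mean(cohort.satisfaction_items[a][sess]))
            sb = float(np.mean(cohort.satisfaction_items[b][sess]))
            rows.append(
                {
                    "pair": p,
                    "session": sess + 1,
                    "subject_1": sa,
                    "subject_2": sb,
                    "pair_score": similarity.pair_satisfaction(
                        cohort.satisfaction_items[a][sess],
                        cohort.satisfaction_items[b][sess],
                    ),
                    "agreement": similarity.agreement_score(sa, sb),
                }
            )
    return pd.DataFrame(rows)


def target_vector(table: pd.DataFrame, target: str, session: int) -> np.ndarray:
    """Extract the prediction target for one session, in pair order."""
    block = table[table["session"] == session].sort_values("pair")
    column = {
        "pair_mean": "pair_score",
        "agreement": "agreement",
        "subject_1": "subject_1",
        "subject_2": "subject_2",
    }[target]
    return block[column].to_numpy(float)


def _stage(name, t0):
    logger.info("stage %-12s done in %.1fs", name, time.perf_counter() - t0)


def run_all(config: RunConfig) -> RunReport:
    """Run the full pipeline and write all stage outputs."""
    from . import __version__

    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict = {}

    # --- simulate / ingest -------------------------------------------------
    t0 = time.perf_counter()
    if cfg.cohort_dir is None:
        syn = cfg.synthetic or SyntheticConfig(seed=cfg.seed)
        cohort = generate_cohort(syn)
        if cfg.write_intermediate:
            files["cohort"] = str(io.write_cohort(cohort, out / "cohort"))
    else:
        cohort = io.read_cohort(cfg.cohort_dir)
        files["cohort"] = str(cfg.cohort_dir)
    _stage("cohort", t0)

    # --- preprocess + connectivity ----------------------------------------
    t0 = time.perf_counter()
    rsfc_by_subject = {}
    rsfc_dir = out / "rsfc"
    if cfg.write_intermediate:
        rsfc_dir.mkdir(exist_ok=True)
    for subj in cohort.subjects:
        clean = preprocess.clean_timeseries(
            cohort.timeseries[subj],
            cohort.motion[subj],
            cohort.wm[subj],
            cohort.csf[subj],
            tr_seconds=cohort.config.tr_seconds,
            cutoff_hz=cfg.cutoff_hz,
            region_labels=cohort.region_labels,
        )
        rsfc_by_subject[subj] = compute_rsfc(clean.data, cohort.region_labels)
        if cfg.write_intermediate:
            pd.DataFrame(
                rsfc_by_subject[subj],
                index=cohort.region_labels,
                columns=cohort.region_labels,
            ).to_csv(rsfc_dir / f"{subj}_rsfc.csv", float_format="%.17g")
    if cfg.write_intermediate:
        files["rsfc"] = str(rsfc_dir)
    _stage("connectivity", t0)

    # --- similarity ---------------------------------------------------------
    t0 = time.perf_counter()
    X = similarity.build_similarity_matrix(rsfc_by_subject, cohort.pairs)
    pers_sim = np.vstack(
        [
            similarity.personality_similarity(
                cohort.personality[a], cohort.personality[b]
            )
            for a, b in cohort.pairs
        ]
    )
    table = satisfaction_table(cohort)
    if cfg.write_intermediate:
        pd.DataFrame(
            X,
            index=pd.Index(range(len(cohort.pairs)), name="pair"),
            columns=cohort.region_labels,
        ).to_csv(out / "similarity.csv", float_format="%.17g")
        pd.DataFrame(
            pers_sim,
            index=pd.Index(range(len(cohort.pairs)), name="pair"),
            columns=[f"trait{t + 1}" for t in range(pers_sim.shape[1])],
        ).to_csv(out / "personality_similarity.csv", float_format="%.17g")
        table.to_csv(out / "satisfaction.csv", index=False, float_format="%.17g")
        files["similarity"] = str(out / "similarity.csv")
        files["personality_similarity"] = str(out / "personality_similarity.csv")
        files["satisfaction"] = str(out / "satisfaction.csv")
    _stage("similarity", t0)

    # --- prediction ---------------------------------------------------------
    t0 = time.perf_counter()
    y = target_vector(table, cfg.target, cfg.session)
    cv = prediction.repeated_cv(
        X, y, cfg.model, k=cfg.k, n_repeats=cfg.n_repeats, seed=cfg.seed
    )
    perm = prediction.permutation_test(
        X, y, cfg.model, k=cfg.k, n_repeats=cfg.n_repeats,
        n_perm=cfg.n_perm, seed=cfg.seed,
    )
    pred_summary = {
        "target": cfg.target,
        "session": cfg.session,
        "per_repeat_rmse": cv.per_repeat_rmse,
        "mean_rmse": cv.mean_rmse,
    }
    perm_summary = {
        "n_perm": perm.n_perm,
        "p_value": perm.p_value,
        "p_smoothed": perm.p_smoothed,
        "null_median": float(np.median(perm.null_rmses)),
        "null_quantiles": {
            "q025": float(np.percentile(perm.null_rmses, 2.5)),
            "q975": float(np.percentile(perm.null_rmses, 97.5)),
        },
    }
    io.write_json(
        {"prediction": pred_summary, "permutation": perm_summary},
        out / "prediction.json",
    )
    files["prediction"] = str(out / "prediction.json")
    _stage("prediction", t0)

    # --- interpretation -----------------------------------------------------
    t0 = time.perf_counter()
    coef = interpretation.coefficient_report(
        X, y, cfg.model, k=cfg.k, n_repeats=cfg.n_repeats,
        n_null=cfg.n_null, seed=cfg.seed, feature_labels=cohort.region_labels,
    )
    imp = interpretation.importance_report(
        X, y, cfg.model, k=cfg.k, n_repeats=cfg.n_repeats,
        K=cfg.K_importance, n_null=cfg.n_importance_baseline, seed=cfg.seed,
        feature_labels=cohort.region_labels,
    )
    coef_summary = {
        "mean_weights": coef.mean_weights,
        "mean_intercept": coef.mean_intercept,
        "null_median": coef.null_median,
        "null_lower": coef.null_lower,
        "null_upper": coef.null_upper,
        "flagged": coef.flagged,
        "feature_labels": cohort.region_labels,
    }
    imp_summary = {
        "importance": imp.importance,
        "K": imp.K,
        "baseline_median": imp.baseline_median,
        "baseline_lower": imp.baseline_lower,
        "baseline_upper": imp.baseline_upper,
        "flagged": imp.flagged,
        "feature_labels": cohort.region_labels,
    }
    io.write_json(coef_summary, out / "coefficients.json")
    io.write_json(imp_summary, out / "importance.json")
    files["coefficients"] = str(out / "coefficients.json")
    files["importance"] = str(out / "importance.json")
    _stage("interpretation", t0)

    # --- behavior stats -----------------------------------------------------
    t0 = time.perf_counter()
    scores = np.column_stack(
        [target_vector(table, "pair_mean", s) for s in (1, 2, 3)]
    )
    anova = behavior.rm_anova(scores)
    posthoc = behavior.shaffer_posthoc(scores)
    io.write_json({"anova": anova, "posthoc": posthoc}, out / "anova.json")
    files["anova"] = str(out / "anova.json")
    _stage("anova", t0)

    cfg_echo = dataclasses.asdict(cfg)
    if cfg_echo.get("synthetic") and cfg_echo["synthetic"].get("signal_weights") is not None:
        cfg_echo["synthetic"]["signal_weights"] = np.asarray(
            cfg_echo["synthetic"]["signal_weights"]
        ).tolist()
    report = RunReport(
        config=cfg_echo,
        stage_files=files,
        satisfaction={
            "per_session_mean": scores.mean(axis=0),
            "per_session_median": np.median(scores, axis=0),
        },
        anova=anova,
        posthoc=posthoc,
        prediction=pred_summary,
        permutation=perm_summary,
        coefficients=coef_summary,
        importance=imp_summary,
        version=__version__,
        seed=cfg.seed,
    )
    io.write_json(report, out / "report.json")
    return report
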