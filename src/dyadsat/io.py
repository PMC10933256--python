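"""Cohort directory formats and result serialization.

A cohort directory holds plain text only:

* ``manifest.json`` — subjects, pairs, sessions, seed and a config echo
* ``sub-<id>_ts.tsv`` — T×N raw time series (header = region labels)
* ``sub-<id>_motion.tsv`` — T×6 rigid-body parameters
* ``sub-<id>_wmcsf.tsv`` — T×2 mean WM and CSF series
* ``personality.csv`` — subject × trait_item (5 traits × 12 items wide)
* ``satisfaction_items.csv`` — subject × session × 18 items (wide)
* ``ground_truth.json`` — planted weights/support (written by the simulator)

Floats are written with ``%.17g`` so a write/read round trip is exact and a
fixed seed yields byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import (
    N_SATISFACTION_ITEMS,
    N_SESSIONS,
    N_TRAIT_ITEMS,
    N_TRAITS,
    SyntheticCohort,
    SyntheticConfig,
)

__all__ = ["write_cohort", "read_cohort", "to_jsonable", "write_json"]

_FLOAT_FMT = "%.17g"


def to_jsonable(obj):
    """Recursively convert dataclasses / ndarrays / numpy scalars for JSON."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_jsonable(v) for v in obj]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(to_jsonable(obj), indent=2, sort_keys=True))


def _motion_columns():
    return ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]


def write_cohort(cohort: SyntheticCohort, out_dir) -> Path:
    """Write a cohort directory; returns its path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(cohort.config)
    cfg["signal_weights"] = (
        None
        if cohort.config.signal_weights is None
        else np.asarray(cohort.config.signal_weights).tolist()
    )
    manifest = {
        "subjects": cohort.subjects,
        "pairs": [list(p) for p in cohort.pairs],
        "pair_sex": cohort.pair_sex,
        "n_sessions": N_SESSIONS,
        "seed": cohort.config.seed,
        "region_labels": cohort.region_labels,
        "config": cfg,
    }
    write_json(manifest, out / "manifest.json")
    write_json(
        {
            "signal_weights": cohort.signal_weights,
            "signal_support": cohort.signal_support,
            "latent_similarity": cohort.latent_similarity,
            "pair_targets": cohort.pair_targets,
        },
        out / "ground_truth.json",
    )

    for subj in cohort.subjects:
        pd.DataFrame(cohort.timeseries[subj], columns=cohort.region_labels).to_csv(
            out / f"{subj}_ts.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame(cohort.motion[subj], columns=_motion_columns()).to_csv(
            out / f"{subj}_motion.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
        pd.DataFrame(
            {"wm": cohort.wm[subj], "csf": cohort.csf[subj]}
        ).to_csv(
            out / f"{subj}_wmcsf.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )

    pers_cols = [
        f"trait{t + 1}_item{i + 1:02d}"
        for t in range(N_TRAITS)
        for i in range(N_TRAIT_ITEMS)
    ]
    pers = pd.DataFrame(
        [cohort.personality[s].reshape(-1) for s in cohort.subjects],
        index=pd.Index(cohort.subjects, name="subject"),
        columns=pers_cols,
    )
    pers.to_csv(out / "personality.csv")

    rows = []
    for subj in cohort.subjects:
        for sess in range(N_SESSIONS):
            rows.append(
                [subj, sess + 1, *cohort.satisfaction_items[subj][sess].tolist()]
            )
    item_cols = [f"item{i + 1:02d}" for i in range(N_SATISFACTION_ITEMS)]
    pd.DataFrame(rows, columns=["subject", "session", *item_cols]).to_csv(
        out / "satisfaction_items.csv", index=False
    )
    return out


def _read_table(path: Path, expected_cols: int, n_timepoints: int | None):
    if not path.exists():
        raise FileNotFoundError(f"missing cohort file: {path}")
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] != expected_cols:
        raise ValueError(
            f"{path.name}: expected {expected_cols} columns, found {df.shape[1]}"
        )
    if n_timepoints is not None and df.shape[0] != n_timepoints:
        raise ValueError(
            f"{path.name}: expected {n_timepoints} rows, found {df.shape[0]}"
        )
    if df.isna().any().any():
        row = int(df.isna().any(axis=1).idxmax())
        raise ValueError(f"{path.name}: missing value at row {row}")
    return df


def read_cohort(cohort_dir) -> SyntheticCohort:
    """Read and validate a cohort directory back into memory."""
    d = Path(cohort_dir)
    manifest_path = d / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing cohort file: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    subjects = manifest["subjects"]
    pairs = [tuple(p) for p in manifest["pairs"]]

    seen = set()
    for a, b in pairs:
        for s in (a, b):
            if s not in subjects:
                raise ValueError(
                    f"manifest.json: pair subject {s!r} not in subject list"
                )
            if s in seen:
                raise ValueError(
                    f"manifest.json: subject {s!r} appears in more than one pair"
                )
            seen.add(s)

    cfg_dict = dict(manifest["config"])
    if cfg_dict.get("signal_weights") is not None:
        cfg_dict["signal_weights"] = np.asarray(cfg_dict["signal_weights"])
    cfg_dict["session_effects"] = tuple(cfg_dict["session_effects"])
    config = SyntheticConfig(**cfg_dict)
    t, n = config.n_timepoints, config.n_regions

    timeseries, motion, wm, csf = {}, {}, {}, {}
    for subj in subjects:
        timeseries[subj] = _read_table(d / f"{subj}_ts.tsv", n, t).to_numpy(float)
        motion[subj] = _read_table(d / f"{subj}_motion.tsv", 6, t).to_numpy(float)
        wmcsf = _read_table(d / f"{subj}_wmcsf.tsv", 2, t)
        wm[subj] = wmcsf["wm"].to_numpy(float)
        csf[subj] = wmcsf["csf"].to_numpy(float)

    pers_path = d / "personality.csv"
    if not pers_path.exists():
        raise FileNotFoundError(f"missing cohort file: {pers_path}")
    pers = pd.read_csv(pers_path, index_col="subject")
    personality = {}
    for subj in subjects:
        if subj not in pers.index:
            raise ValueError(f"personality.csv: missing subject {subj!r}")
        personality[subj] = (
            pers.loc[subj].to_numpy(float).reshape(N_TRAITS, N_TRAIT_ITEMS).astype(int)
        )

    sat_path = d / "satisfaction_items.csv"
    if not sat_path.exists():
        raise FileNotFoundError(f"missing cohort file: {sat_path}")
    sat = pd.read_csv(sat_path)
    item_cols = [f"item{i + 1:02d}" for i in range(N_SATISFACTION_ITEMS)]
    satisfaction_items = {}
    for subj in subjects:
        block = sat[sat["subject"] == subj].sort_values("session")
        if len(block) != N_SESSIONS:
            raise ValueError(
                f"satisfaction_items.csv: subject {subj!r} has "
                f"{len(block)} sessions, expected {N_SESSIONS}"
            )
        items = block[item_cols].to_numpy(int)
        if items.min() < 1 or items.max() > 8:
            row = int(block.index[((items < 1) | (items > 8)).any(axis=1)][0])
            raise ValueError(
                f"satisfaction_items.csv: out-of-range item at row {row}"
            )
        satisfaction_items[subj] = items

    truth_path = d / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())
        signal_weights = np.asarray(truth["signal_weights"], dtype=float)
        signal_support = np.asarray(truth["signal_support"], dtype=int)
        latent_similarity = np.asarray(truth["latent_similarity"], dtype=float)
        pair_targets = np.asarray(truth["pair_targets"], dtype=float)
    else:
        signal_weights = np.zeros(n)
        signal_support = np.array([], dtype=int)
        latent_similarity = None
        pair_targets = None

    return SyntheticCohort(
        config=config,
        subjects=subjects,
        pairs=pairs,
        pair_sex=manifest["pair_sex"],
        region_labels=manifest["region_labels"],
        timeseries=timeseries,
        motion=motion,
        wm=wm,
        csf=csf,
        personality=personality,
        satisfaction_items=satisfaction_items,
        signal_weights=signal_weights,
        signal_support=signal_support,
        latent_similarity=latent_similarity,
        pair_targets=pair_targets,
    )
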