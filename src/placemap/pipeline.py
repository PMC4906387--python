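"""End-to-end analysis runs: maps -> classification -> scores -> statistics.

``analyze_dataset`` drives the full sequence on an in-memory dataset;
``run_familiar`` / ``run_novel`` load a dataset directory, run the analysis
and write the output tables (classifications.tsv, remap_scores.tsv,
field_bias.tsv, stats_report.tsv, summary.json and the resolved config).
Every numeric in the summary is taken from a row of an intermediate table.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import classify as clf
from . import remap, stats
from .arena import ArenaSpec, LightZone
from .errors import InsufficientDataError, ManifestError
from .io import load_dataset
from .ratemap import compute_rate_map, mobility_mask, zone_masks
from .synth import Dataset, Trajectory

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Results", "analyze_dataset", "run_familiar", "run_novel", "validate_inputs"]

GROUPS = ("suppressed", "disinhibited", "unaffected")

_FAMILIAR_ROLES = ("a1", "a2", "a3")
_NOVEL_ROLES = ("b1", "b2", "b3")


@dataclass
class RunConfig:
    """Resolved analysis parameters (the printed defaults of the method)."""

    sigma_bins: float = 1.0
    speed_min_cm_s: float = 3.0
    sleep_change_threshold: float = 0.33
    exploration_change_threshold: float = 0.5
    alpha: float = 0.05
    sparsity_max: float = 0.3
    coherence_min: float = 0.55
    rate_min_hz: float = 0.25
    field_threshold_hz: float = 1.0
    min_overlap_bins: int = 10
    min_pulses: int = 20
    min_group_n: int = 5
    pfs_method: str = "pearson"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in data.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Results:
    classifications: pd.DataFrame
    pair_scores: pd.DataFrame
    bias_scores: pd.DataFrame
    stats_report: pd.DataFrame
    summary: dict


def _light_sample_mask(traj: Trajectory, intervals: np.ndarray) -> np.ndarray:
    m = np.zeros(len(traj.t), dtype=bool)
    for on, off in intervals:
        m |= (traj.t >= on) & (traj.t < off)
    return m


def _roles(ds: Dataset) -> dict[str, str]:
    return {sess["role"]: sid for sid, sess in ds.sessions.items()}


def analyze_dataset(
    ds: Dataset,
    config: RunConfig = RunConfig(),
    group_by: str = "classified",
) -> Results:
    """Full analysis of one recording day.

    ``group_by="classified"`` groups score tables by the pipeline's own
    paradigm labels; ``group_by="truth"`` groups by the simulator's
    ground-truth phenotypes (used for null-calibration runs, where the
    classifier correctly leaves nearly every unit in "remaining").
    """
    roles = _roles(ds)
    expected = _FAMILIAR_ROLES if ds.paradigm == "familiar" else _NOVEL_ROLES
    missing = [r for r in expected if r not in roles]
    if missing or len(ds.pulse_onsets) == 0:
        raise ManifestError(f"manifest lacks required sessions: {missing or ['pulse-test']}")

    in_mask, out_mask = zone_masks(ds.arena, ds.zone)
    logger.info("zone masks: %d bins in, %d bins out", in_mask.sum(), out_mask.sum())

    # --- sleep (pulse-test) classification, all units -----------------------
    sleep_rows = []
    for uid in ds.unit_ids:
        resp = clf.pulse_response(
            ds.pulse_spikes[uid],
            ds.pulse_onsets,
            ds.pulse_duration_s,
            unit_id=uid,
            min_pulses=config.min_pulses,
        )
        label = clf.classify_by_pulses(resp, config.sleep_change_threshold, config.alpha)
        sleep_rows.append(
            {
                "unit_id": uid,
                "cell_type": ds.cell_types[uid],
                "sleep_label": label,
                "sleep_change": resp.relative_change,
                "sleep_p": resp.p_value,
                "baseline_rate_hz": resp.baseline_rate_hz,
                "pulse_rate_hz": resp.pulse_rate_hz,
            }
        )
    sleep_df = pd.DataFrame(sleep_rows).set_index("unit_id", drop=False)

    # --- rate maps (pyramidal units, mobility-filtered) ----------------------
    pyr_ids = [u for u in ds.unit_ids if ds.cell_types[u] == "pyramidal"]
    session_ids = [roles[r] for r in expected]
    mobility = {
        sid: mobility_mask(ds.sessions[sid]["trajectory"], config.speed_min_cm_s)
        for sid in session_ids
    }
    unit_maps: dict[int, dict[str, dict]] = {}
    for uid in pyr_ids:
        unit_maps[uid] = {}
        for sid in session_ids:
            sess = ds.sessions[sid]
            traj = sess["trajectory"]
            spk = sess["spikes"].get(uid, np.empty(0))
            kw = dict(sigma_bins=config.sigma_bins, sample_mask=mobility[sid])
            unit_maps[uid][sid] = {
                "whole": compute_rate_map(spk, traj, ds.arena, **kw),
                "in": compute_rate_map(spk, traj, ds.arena, mask=in_mask, **kw),
                "out": compute_rate_map(spk, traj, ds.arena, mask=out_mask, **kw),
            }

    # --- place-cell gate and paradigm classification -------------------------
    light_role = "a2" if ds.paradigm == "familiar" else "b1"
    qualify_roles = ("a1", "a3") if ds.paradigm == "familiar" else ("b2", "b3")
    light_sid = roles[light_role]
    light_intervals = ds.sessions[light_sid]["light_intervals"]
    if light_intervals is None:
        raise ManifestError(f"session {light_sid} has no light intervals")
    light_mask = _light_sample_mask(ds.sessions[light_sid]["trajectory"], light_intervals)

    class_rows = []
    for uid in pyr_ids:
        qmaps = {r: unit_maps[uid][roles[r]]["whole"] for r in qualify_roles}
        place_flag, per_session = clf.is_place_cell(
            qmaps, config.sparsity_max, config.coherence_min, config.rate_min_hz
        )
        sleep_label = sleep_df.loc[uid, "sleep_label"]
        sleep_change = sleep_df.loc[uid, "sleep_change"]
        if ds.paradigm == "familiar":
            if place_flag:
                a1_rate = unit_maps[uid][roles["a1"]]["in"].mean_rate_hz
                sess = ds.sessions[light_sid]
                a2_map = compute_rate_map(
                    sess["spikes"].get(uid, np.empty(0)),
                    sess["trajectory"],
                    ds.arena,
                    sigma_bins=0.0,
                    sample_mask=light_mask,
                    mask=in_mask,
                )
                a2_rate = a2_map.mean_rate_hz
                label = clf.classify_familiar(
                    a1_rate, a2_rate, sleep_label, sleep_change,
                    config.exploration_change_threshold,
                )
            else:
                a1_rate = a2_rate = math.nan
                label = "remaining"
            extra = {"zone_rate_a1_hz": a1_rate, "zone_rate_a2_light_hz": a2_rate}
        else:
            label = clf.classify_novel(sleep_label, sleep_change, place_flag)
            extra = {}
        class_rows.append(
            {
                "unit_id": uid,
                "cell_type": "pyramidal",
                "sleep_label": sleep_label,
                "sleep_change": sleep_change,
                "sleep_p": sleep_df.loc[uid, "sleep_p"],
                "paradigm_label": label,
                "place_flag": bool(place_flag),
                **{f"place_{r}": bool(v) for r, v in zip(qualify_roles, per_session.values())},
                **extra,
                "truth_label": ds.ground_truth.phenotype.get(uid, ""),
            }
        )
    class_df = pd.DataFrame(class_rows).set_index("unit_id", drop=False)
    # interneurons appear in the classification table with sleep labels only
    int_rows = sleep_df[sleep_df["cell_type"] == "interneuron"].copy()
    if len(int_rows):
        int_rows["paradigm_label"] = ""
        int_rows["place_flag"] = False
        int_rows["truth_label"] = [
            ds.ground_truth.phenotype.get(u, "") for u in int_rows["unit_id"]
        ]
        class_df = pd.concat([class_df, int_rows], axis=0)

    # --- score battery --------------------------------------------------------
    if ds.paradigm == "familiar":
        pairs = [(roles["a1"], roles["a2"]), (roles["a2"], roles["a3"]), (roles["a1"], roles["a3"])]
    else:
        pairs = [(roles["b1"], roles["b2"]), (roles["b2"], roles["b3"])]
    pair_scores, bias_scores = remap.score_battery(
        unit_maps, pairs,
        min_overlap=config.min_overlap_bins,
        field_threshold_hz=config.field_threshold_hz,
    )

    if group_by == "truth":
        grp = {
            uid: {"remaining": "unaffected"}.get(p, p)
            for uid, p in ds.ground_truth.phenotype.items()
            if ds.cell_types.get(uid) == "pyramidal"
        }
    else:
        grp = class_df.loc[class_df["cell_type"] == "pyramidal", "paradigm_label"].to_dict()
    pair_scores["group"] = pair_scores["unit_id"].map(grp)
    bias_scores["group"] = bias_scores["unit_id"].map(grp)

    stats_report = _stats_battery(pair_scores, bias_scores, config)

    group_sizes = {
        g: int((class_df["paradigm_label"] == g).sum()) for g in (*GROUPS, "remaining")
    }
    medians = (
        pair_scores[pair_scores["group"].isin(GROUPS)]
        .groupby(["pair", "group"])[["pfs_whole", "pfs_in", "pfs_out", "c_in", "c_out"]]
        .median()
    )
    summary = {
        "paradigm": ds.paradigm,
        "n_units": len(ds.unit_ids),
        "n_pyramidal": len(pyr_ids),
        "group_sizes": group_sizes,
        "group_medians": {
            f"{pair}:{group}": {k: (None if pd.isna(v) else round(float(v), 6))
                                for k, v in row.items()}
            for (pair, group), row in medians.iterrows()
        },
    }
    return Results(class_df.reset_index(drop=True), pair_scores, bias_scores, stats_report, summary)


def _stats_battery(pair_scores: pd.DataFrame, bias_scores: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Distribution comparisons, group-median comparisons and sign tests."""
    frames = []
    scored = pair_scores[pair_scores["group"].isin(GROUPS)]
    for pair, sub in scored.groupby("pair"):
        groups_whole = {g: sub.loc[sub["group"] == g, "pfs_whole"].dropna() for g in GROUPS}
        try:
            ks = stats.ks_pairwise(groups_whole, min_n=config.min_group_n)
            ks.insert(0, "family", f"pfs_whole:{pair}")
            frames.append(ks)
        except InsufficientDataError as exc:
            logger.info("KS skipped for %s: %s", pair, exc)
        for col in ("pfs_in", "pfs_out"):
            groups = {g: sub.loc[sub["group"] == g, col].dropna() for g in GROUPS}
            try:
                kw = stats.kw_with_posthoc(groups, min_n=config.min_group_n, alpha=config.alpha)
                kw.insert(0, "family", f"{col}:{pair}")
                frames.append(kw)
            except InsufficientDataError as exc:
                logger.info("KW skipped for %s %s: %s", col, pair, exc)
        sign_rows = []
        for col in ("c_in", "c_out"):
            for g in GROUPS:
                vals = sub.loc[sub["group"] == g, col].dropna()
                if len(vals) < config.min_group_n:
                    continue
                res = stats.sign_test(vals)
                sign_rows.append(
                    {
                        "family": f"{col}:{pair}",
                        "test": "binomial",
                        "group1": g,
                        "group2": "",
                        "statistic": float(res.n_pos),
                        "p_raw": res.p_value,
                        "p_holm": res.p_value,
                        "holm_tag": "",
                        "n1": res.n_pos + res.n_neg,
                        "n2": 0,
                    }
                )
        if sign_rows:
            frames.append(pd.DataFrame(sign_rows))
    biased = bias_scores[bias_scores["group"].isin(GROUPS)]
    bias_rows = []
    for (session, g), sub in biased.groupby(["session", "group"]):
        vals = sub["bias"].dropna()
        if len(vals) < config.min_group_n:
            continue
        res = stats.sign_test(vals)
        bias_rows.append(
            {
                "family": f"bias:{session}",
                "test": "binomial",
                "group1": g,
                "group2": "",
                "statistic": float(res.n_pos),
                "p_raw": res.p_value,
                "p_holm": res.p_value,
                "holm_tag": "",
                "n1": res.n_pos + res.n_neg,
                "n2": 0,
            }
        )
    if bias_rows:
        frames.append(pd.DataFrame(bias_rows))
    if not frames:
        return pd.DataFrame(
            columns=["family", "test", "group1", "group2", "statistic",
                     "p_raw", "p_holm", "holm_tag", "n1", "n2"]
        )
    return pd.concat(frames, ignore_index=True)


def _run(dataset_dir: str | Path, out_dir: str | Path, config: RunConfig, paradigm: str) -> Path:
    ds = load_dataset(dataset_dir)
    if ds.paradigm != paradigm:
        raise ManifestError(f"dataset paradigm {ds.paradigm!r}, expected {paradigm!r}")
    res = analyze_dataset(ds, config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.classifications.to_csv(out / "classifications.tsv", sep="\t", index=False, float_format="%.6g")
    res.pair_scores.to_csv(out / "remap_scores.tsv", sep="\t", index=False, float_format="%.6g")
    res.bias_scores.to_csv(out / "field_bias.tsv", sep="\t", index=False, float_format="%.6g")
    res.stats_report.to_csv(out / "stats_report.tsv", sep="\t", index=False, float_format="%.6g")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(res.summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out / "config.json", "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def run_familiar(dataset_dir: str | Path, out_dir: str | Path, config: RunConfig = RunConfig()) -> Path:
    """Analyse a familiar-paradigm dataset directory (sessions a1-a3 + pulse test)."""
    return _run(dataset_dir, out_dir, config, "familiar")


def run_novel(dataset_dir: str | Path, out_dir: str | Path, config: RunConfig = RunConfig()) -> Path:
    """Analyse a novel-paradigm dataset directory (sessions b1-b3 + pulse test)."""
    return _run(dataset_dir, out_dir, config, "novel")


def validate_inputs(dataset_dir: str | Path) -> list[dict]:
    """Schema and consistency checks; returns a machine-readable issue list."""
    root = Path(dataset_dir)
    issues: list[dict] = []
    try:
        manifest = json.loads((root / "manifest.json").read_text(encoding="utf-8"))
    except FileNotFoundError:
        return [{"issue": "missing file", "path": str(root / "manifest.json")}]
    except json.JSONDecodeError as exc:
        return [{"issue": "unreadable manifest", "detail": str(exc)}]

    zone = manifest.get("zone", {})
    width = zone.get("width_deg")
    if width is not None and not (120.0 <= width <= 180.0):
        issues.append({"issue": "zone angle out of range", "width_deg": width})
    known_units = {int(u["unit_id"]) for u in manifest.get("units", [])}
    expected = _FAMILIAR_ROLES if manifest.get("paradigm") == "familiar" else _NOVEL_ROLES
    roles_seen = set()
    for entry in manifest.get("sessions", []):
        roles_seen.add(entry.get("role"))
        for key in ("positions", "spikes", "pulses", "light_intervals"):
            if key in entry and not (root / entry[key]).exists():
                issues.append({"issue": "missing file", "path": entry[key]})
        if "positions" in entry and (root / entry["positions"]).exists():
            pos = pd.read_csv(root / entry["positions"], sep="\t")
            t = pos["t_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                issues.append({"issue": "time order", "session": entry["id"]})
            declared = entry.get("duration_s")
            if declared is not None and abs(len(t) / entry.get("sampling_rate_hz", 50.0) - declared) > 1.0:
                issues.append({"issue": "duration mismatch", "session": entry["id"]})
        if "spikes" in entry and (root / entry["spikes"]).exists():
            spk = pd.read_csv(root / entry["spikes"], sep="\t")
            orphans = set(spk["unit_id"].astype(int)) - known_units
            if orphans:
                issues.append(
                    {"issue": "orphan unit", "session": entry["id"],
                     "unit_ids": sorted(orphans)}
                )
    for role in expected:
        if role not in roles_seen:
            issues.append({"issue": "missing session role", "role": role})
    if "pulse-test" not in roles_seen:
        issues.append({"issue": "missing session role", "role": "pulse-test"})
    return issues
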