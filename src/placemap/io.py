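"""On-disk dataset layout: tab-separated text tables plus a JSON manifest.

Per session: ``<id>_positions.tsv`` (t_s, x_cm, y_cm), ``<id>_spikes.tsv``
(unit_id, t_s) and, for illuminated sessions, ``<id>_light.tsv`` (on_s,
off_s). The pulse-test session writes ``pulse_spikes.tsv`` and ``pulses.tsv``
(onset_s, duration_s). ``manifest.json`` records the arena, zone, session
roles and file names; ``groundtruth.json`` holds the simulator's labels.
Times are written in seconds with 1e-4 precision; all files are UTF-8 with a
header line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import ArenaSpec, LightZone
from .errors import ManifestError
from .synth import Dataset, GroundTruth, Trajectory

__all__ = ["write_dataset", "load_dataset", "write_manifest", "read_manifest"]

_T_FMT = "%.4f"


def _write_tsv(path: Path, df: pd.DataFrame, float_format: str = _T_FMT) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write a dataset directory (returns its path)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "paradigm": ds.paradigm,
        "animal_id": ds.animal_id,
        "arena": ds.arena.to_dict(),
        "zone": ds.zone.to_dict(),
        "units": [
            {"unit_id": int(u), "cell_type": ds.cell_types[u]} for u in ds.unit_ids
        ],
        "sessions": [],
    }
    for sid, sess in ds.sessions.items():
        traj: Trajectory = sess["trajectory"]
        pos = pd.DataFrame({"t_s": traj.t, "x_cm": traj.x, "y_cm": traj.y})
        _write_tsv(out / f"{sid}_positions.tsv", pos)
        rows = []
        for uid in sorted(sess["spikes"]):
            for t in sess["spikes"][uid]:
                rows.append((uid, t))
        spk = pd.DataFrame(rows, columns=["unit_id", "t_s"])
        if len(spk):
            spk = spk.sort_values(["t_s", "unit_id"], kind="stable")
        _write_tsv(out / f"{sid}_spikes.tsv", spk)
        entry = {
            "id": sid,
            "role": sess["role"],
            "positions": f"{sid}_positions.tsv",
            "spikes": f"{sid}_spikes.tsv",
            "duration_s": round(traj.duration_s, 4),
            "sampling_rate_hz": traj.fs,
            "light": sess["light_intervals"] is not None,
        }
        if sess["light_intervals"] is not None:
            light = pd.DataFrame(sess["light_intervals"], columns=["on_s", "off_s"])
            _write_tsv(out / f"{sid}_light.tsv", light)
            entry["light_intervals"] = f"{sid}_light.tsv"
        manifest["sessions"].append(entry)

    rows = []
    for uid in sorted(ds.pulse_spikes):
        for t in ds.pulse_spikes[uid]:
            rows.append((uid, t))
    spk = pd.DataFrame(rows, columns=["unit_id", "t_s"])
    if len(spk):
        spk = spk.sort_values(["t_s", "unit_id"], kind="stable")
    _write_tsv(out / "pulse_spikes.tsv", spk)
    pulses = pd.DataFrame(
        {"onset_s": ds.pulse_onsets, "duration_s": ds.pulse_duration_s}
    )
    _write_tsv(out / "pulses.tsv", pulses)
    manifest["sessions"].append(
        {
            "id": "pulse",
            "role": "pulse-test",
            "spikes": "pulse_spikes.tsv",
            "pulses": "pulses.tsv",
            "pulse_duration_s": ds.pulse_duration_s,
            "light": True,
        }
    )
    write_manifest(out / "manifest.json", manifest)
    with open(out / "groundtruth.json", "w", encoding="utf-8") as fh:
        json.dump(ds.ground_truth.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return out


def write_manifest(path: str | Path, manifest: dict) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_manifest(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"missing manifest: {path}")
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def _read_spikes(path: Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    out: dict[int, np.ndarray] = {}
    for uid, grp in df.groupby("unit_id"):
        out[int(uid)] = np.sort(grp["t_s"].to_numpy(dtype=float))
    return out


def load_dataset(in_dir: str | Path) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset` (or any data
    following the same manifest schema)."""
    root = Path(in_dir)
    manifest = read_manifest(root / "manifest.json")
    arena = ArenaSpec.from_dict(manifest["arena"])
    zone = LightZone.from_dict(manifest["zone"])
    unit_ids = [int(u["unit_id"]) for u in manifest["units"]]
    cell_types = {int(u["unit_id"]): u["cell_type"] for u in manifest["units"]}

    sessions: dict[str, dict] = {}
    pulse_spikes: dict[int, np.ndarray] = {}
    pulse_onsets = np.empty(0)
    pulse_duration = 0.4
    for entry in manifest["sessions"]:
        if entry["role"] == "pulse-test":
            pulse_spikes = _read_spikes(root / entry["spikes"])
            pulses = pd.read_csv(root / entry["pulses"], sep="\t")
            pulse_onsets = pulses["onset_s"].to_numpy(dtype=float)
            pulse_duration = float(entry.get("pulse_duration_s", 0.4))
            continue
        pos = pd.read_csv(root / entry["positions"], sep="\t")
        traj = Trajectory(
            t=pos["t_s"].to_numpy(dtype=float),
            x=pos["x_cm"].to_numpy(dtype=float),
            y=pos["y_cm"].to_numpy(dtype=float),
            fs=float(entry.get("sampling_rate_hz", 50.0)),
        )
        spikes = _read_spikes(root / entry["spikes"])
        for uid in unit_ids:
            spikes.setdefault(uid, np.empty(0))
        light = None
        if entry.get("light") and "light_intervals" in entry:
            li = pd.read_csv(root / entry["light_intervals"], sep="\t")
            light = li[["on_s", "off_s"]].to_numpy(dtype=float)
        sessions[entry["id"]] = {
            "trajectory": traj,
            "spikes": spikes,
            "light_intervals": light,
            "role": entry["role"],
        }
    for uid in unit_ids:
        pulse_spikes.setdefault(uid, np.empty(0))

    gt = GroundTruth()
    gt_path = root / "groundtruth.json"
    if gt_path.exists():
        with open(gt_path, encoding="utf-8") as fh:
            d = json.load(fh)
        gt.phenotype = {int(k): v for k, v in d.get("phenotype", {}).items()}
        gt.cell_type = {int(k): v for k, v in d.get("cell_type", {}).items()}
        gt.remapped = {int(k): v for k, v in d.get("remapped", {}).items()}
        gt.centers_pre = {int(k): v for k, v in d.get("centers_pre", {}).items()}
        gt.centers_post = {int(k): v for k, v in d.get("centers_post", {}).items()}
        gt.expected_signs = d.get("expected_signs", {})

    return Dataset(
        paradigm=manifest["paradigm"],
        arena=arena,
        zone=zone,
        sessions=sessions,
        pulse_spikes=pulse_spikes,
        pulse_onsets=pulse_onsets,
        pulse_duration_s=pulse_duration,
        ground_truth=gt,
        unit_ids=unit_ids,
        cell_types=cell_types,
        animal_id=manifest.get("animal_id", "unknown"),
    )
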