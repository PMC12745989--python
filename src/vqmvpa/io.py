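"""Serialization: trial tables as CSV, beta/representation arrays as HDF5,
configs as JSON."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .design import DesignConfig, StimulusDesign
from .representation import RepresentationSet
from .simulate import BetaDataset, SimulationParams


def save_design(design: StimulusDesign, path: str | Path) -> None:
    design.trials.to_csv(path, index=False)


def load_design(path: str | Path, config: DesignConfig) -> StimulusDesign:
    trials = pd.read_csv(path)
    # canonical catalogue order: sorted image ids (deterministic on reload)
    images = (
        trials.drop_duplicates("image_id")[["image_id", "task", "category",
                                            "quality"]]
        .sort_values("image_id", kind="stable")
        .reset_index(drop=True)
    )
    return StimulusDesign(trials=trials, images=images, config=config)


def save_betas(betas: BetaDataset, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("betas")
        for (p, roi), arr in betas.betas.items():
            g.create_dataset(f"{p}/{roi}", data=arr)
        r = f.create_group("reliable_voxels")
        for (p, roi), idx in betas.reliable_voxels.items():
            r.create_dataset(f"{p}/{roi}", data=idx)


def load_betas(path: str | Path, design: StimulusDesign,
               params: SimulationParams) -> BetaDataset:
    betas, reliable = {}, {}
    with h5py.File(path, "r") as f:
        for p in f["betas"]:
            for roi in f["betas"][p]:
                betas[(p, roi)] = f["betas"][p][roi][()]
        for p in f.get("reliable_voxels", []):
            for roi in f["reliable_voxels"][p]:
                reliable[(p, roi)] = f["reliable_voxels"][p][roi][()]
    return BetaDataset(betas=betas, design=design, params_used=params,
                       reliable_voxels=reliable)


def save_representations(reps: RepresentationSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        pr = f.create_group("per_repetition")
        av = f.create_group("averaged")
        for (p, roi), arr in reps.per_repetition.items():
            pr.create_dataset(f"{p}/{roi}", data=arr)
        for (p, roi), arr in reps.averaged.items():
            av.create_dataset(f"{p}/{roi}", data=arr)
        idx = reps.image_index
        f.create_dataset(
            "image_index",
            data=np.array(
                [idx[c].astype(str).to_numpy() for c in idx.columns]
            ).T.astype("S"),
        )
        f.attrs["image_index_columns"] = list(idx.columns)
        f.attrs["hemisphere_order"] = "left_then_right"


def load_representations(path: str | Path) -> RepresentationSet:
    per_rep, avg = {}, {}
    with h5py.File(path, "r") as f:
        for p in f["per_repetition"]:
            for roi in f["per_repetition"][p]:
                per_rep[(p, roi)] = f["per_repetition"][p][roi][()]
        for p in f["averaged"]:
            for roi in f["averaged"][p]:
                avg[(p, roi)] = f["averaged"][p][roi][()]
        cols = list(f.attrs["image_index_columns"])
        raw = f["image_index"][()].astype(str)
        image_index = pd.DataFrame(raw, columns=cols)
    return RepresentationSet(per_repetition=per_rep, averaged=avg,
                             image_index=image_index)


def config_to_json(design_config: DesignConfig, params: SimulationParams,
                   path: str | Path) -> None:
    blob = {
        "design": dataclasses.asdict(design_config),
        "simulation": _params_dict(params),
    }
    Path(path).write_text(json.dumps(blob, indent=2, default=_jsonify))


def config_from_json(path: str | Path) -> tuple[DesignConfig, SimulationParams]:
    blob = json.loads(Path(path).read_text())
    d = blob.get("design", {})
    if "isi_menu_s" in d:
        d["isi_menu_s"] = tuple(d["isi_menu_s"])
    s = dict(blob.get("simulation", {}))
    if "roi_names" in s:
        s["roi_names"] = tuple(s["roi_names"])
    if "semantic_gain_by_quality_and_roi" in s:
        s["semantic_gain_by_quality_and_roi"] = {
            tuple(k.split("|")): v
            for k, v in s["semantic_gain_by_quality_and_roi"].items()
        }
    return DesignConfig(**d), SimulationParams(**s)


def _params_dict(params: SimulationParams) -> dict:
    d = dataclasses.asdict(params)
    d["semantic_gain_by_quality_and_roi"] = {
        f"{roi}|{q}": v
        for (roi, q), v in params.semantic_gain_by_quality_and_roi.items()
    }
    return d


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def _stringify(obj):
    """Recursively make an object JSON-serializable (keys become strings)."""
    if dataclasses.is_dataclass(obj):
        return _stringify(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _stringify(v) for k, v in sorted(obj.items(),
                                                         key=lambda kv:
                                                         str(kv[0]))}
    if isinstance(obj, (list, tuple)):
        return [_stringify(x) for x in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(*objs) -> str:
    """Stable short hash of configuration objects for provenance records."""
    blob = json.dumps([_stringify(o) for o in objs], sort_keys=True,
                      default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
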