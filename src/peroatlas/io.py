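"""Readers and writers for traces, truth sidecars, configs and masks."""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometry import CompartmentMask, LabeledSection
from .synthgen import GeneratorConfig, TruthRecord


def write_trace_csv(traces: pd.DataFrame, path) -> None:
    """Write animal_id, timestamp (ISO-8601), temp_c; ground-truth columns
    such as the artifact mask are deliberately not exported."""
    out = traces[["animal_id", "timestamp", "temp_c"]].copy()
    out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
    out["temp_c"] = out["temp_c"].round(4)
    out.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df.sort_values(["animal_id", "timestamp"]).reset_index(drop=True)


def write_truth_json(truths, path) -> None:
    payload = [dataclasses.asdict(t) for t in truths]
    Path(path).write_text(json.dumps(payload, indent=1, default=str))


def read_truth_json(path) -> list[TruthRecord]:
    raw = json.loads(Path(path).read_text())
    return [TruthRecord(**r) for r in raw]


def write_config_yaml(cfg: GeneratorConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["start_date"] = cfg.start_date.isoformat()
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def read_config_yaml(path) -> GeneratorConfig:
    d = yaml.safe_load(Path(path).read_text())
    if isinstance(d.get("start_date"), str):
        d["start_date"] = dt.date.fromisoformat(d["start_date"])
    for key in ("spurious_magnitude", "copulation_delay_days"):
        if key in d and isinstance(d[key], list):
            d[key] = tuple(d[key])
    return GeneratorConfig(**d)


def write_metadata_csv(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("pairing_date", "birth_date", "weaning_date"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col]).dt.date
    return df


def write_mask(mask, path, sidecar: bool = True) -> None:
    """Write a label mask as 16-bit PNG/TIFF plus a JSON sidecar holding the
    pixel size and label semantics."""
    import imageio.v3 as iio

    path = Path(path)
    iio.imwrite(path, mask.labels.astype(np.uint16))
    if sidecar:
        meta = {"pixel_size_um": mask.pixel_size_um}
        if isinstance(mask, LabeledSection):
            meta.update(kind="zones", site_id=mask.site_id,
                        section_id=mask.section_id)
        else:
            meta.update(kind="compartments", magnification=mask.magnification,
                        image_id=mask.image_id)
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))


def read_mask(path):
    import imageio.v3 as iio

    path = Path(path)
    labels = np.asarray(iio.imread(path)).astype(np.int32)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    if meta.get("kind") == "zones":
        return LabeledSection(labels, meta["pixel_size_um"],
                              meta.get("site_id", "site"),
                              meta.get("section_id", "s1"))
    return CompartmentMask(labels, meta["pixel_size_um"],
                           meta.get("magnification", "40x"),
                           meta.get("image_id", "img"))
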