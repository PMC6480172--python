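"""Plain-text persistence for records, datasets and annotation tracks.

Records travel as a CSV (one sample per row, header ``value``) plus a JSON
sidecar carrying the sampling frequency, the generator seed and the truth
intervals.  Segment datasets persist as a samples CSV (one segment per
row) plus a JSON manifest.  Everything round-trips losslessly enough for
float32 segment data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import SegmentDataset
from .simulate import SyntheticRecord

__all__ = [
    "write_record",
    "read_record",
    "write_segment_dataset",
    "read_segment_dataset",
]


def write_record(record: SyntheticRecord, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (samples) and ``<path>.json`` (sidecar)."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    json_path = path.with_suffix(".json")
    pd.DataFrame({"value": record.samples}).to_csv(csv_path, index=False)
    sidecar = {
        "fs": record.fs,
        "seed": record.seed,
        "record_id": record.record_id,
        "generator_version": record.generator_version,
        "truth_intervals": [
            {"start_s": s, "end_s": e, "quality": q, "position": p}
            for (s, e, q, p) in record.truth_intervals
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_record(path: str | Path) -> SyntheticRecord:
    """Read a record written by :func:`write_record`."""
    path = Path(path)
    samples = pd.read_csv(path.with_suffix(".csv"))["value"].to_numpy(dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    intervals = [
        (d["start_s"], d["end_s"], d["quality"], d["position"])
        for d in meta.get("truth_intervals", [])
    ]
    return SyntheticRecord(
        samples=samples,
        fs=float(meta["fs"]),
        heart_rate_series=np.empty(0),
        truth_intervals=intervals,
        seed=int(meta.get("seed", -1)),
        record_id=meta.get("record_id", path.stem),
        generator_version=meta.get("generator_version", "unknown"),
    )


def write_segment_dataset(ds: SegmentDataset, path: str | Path) -> tuple[Path, Path]:
    """Write ``<path>.csv`` (one segment per row) + ``<path>.manifest.json``."""
    path = Path(path)
    csv_path = path.with_suffix(".csv")
    man_path = path.with_name(path.stem + ".manifest.json")
    pd.DataFrame(ds.X).to_csv(csv_path, index=False, header=False, float_format="%.7g")
    manifest = {
        "fs": ds.fs,
        "seg_len_s": ds.seg_len_s,
        "overlap_frac": ds.overlap_frac,
        "quality": [q for q in ds.quality],
        "position": [p for p in ds.position],
        "record_ids": [r for r in ds.record_ids],
        "start_indices": ds.start_indices.tolist(),
        "class_counts": {f"{q}|{p}": int(c) for (q, p), c in ds.class_counts.items()},
        "n_discarded_straddling": ds.n_discarded_straddling,
        "n_discarded_zero_variance": ds.n_discarded_zero_variance,
    }
    man_path.write_text(json.dumps(manifest))
    return csv_path, man_path


def read_segment_dataset(path: str | Path) -> SegmentDataset:
    path = Path(path)
    X = pd.read_csv(path.with_suffix(".csv"), header=None).to_numpy(dtype=np.float32)
    meta = json.loads(path.with_name(path.stem + ".manifest.json").read_text())
    counts = {}
    for key, c in meta["class_counts"].items():
        q, p = key.split("|")
        counts[(None if q == "None" else q, None if p == "None" else p)] = c
    return SegmentDataset(
        X=X,
        quality=np.array(meta["quality"], dtype=object),
        position=np.array(meta["position"], dtype=object),
        record_ids=np.array(meta["record_ids"], dtype=object),
        start_indices=np.asarray(meta["start_indices"], dtype=int),
        fs=float(meta["fs"]),
        seg_len_s=float(meta["seg_len_s"]),
        overlap_frac=float(meta["overlap_frac"]),
        class_counts=counts,
        n_discarded_straddling=int(meta["n_discarded_straddling"]),
        n_discarded_zero_variance=int(meta["n_discarded_zero_variance"]),
    )
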