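"""Plain-text readers and writers for the pipeline's interchange formats.

Tracking goes to CSV (t_s, x_cm, y_cm); photometry to CSV
(t_s, fluor, led_state); sweeps to wide CSV with one column per step;
counts and sample metadata to TSV; ground truth and normalization
constants to JSON sidecars.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TrackingTrace
from .ephys import SweepSet
from .photometry import PhotometrySession
from .transcripts import CountTable


def write_tracking(trace: TrackingTrace, path) -> None:
    trace.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_tracking(path, frame_rate: float | None = None) -> TrackingTrace:
    df = pd.read_csv(path)
    if frame_rate is None:
        frame_rate = 1.0 / float(np.median(np.diff(df["t_s"])))
    return TrackingTrace.from_frame(df, frame_rate)


def write_photometry(session: PhotometrySession, path) -> None:
    pd.DataFrame({"t_s": session.t, "fluor": session.fluor,
                  "led_state": session.led_state}).to_csv(path, index=False)
    meta = {"raw_rate": session.raw_rate,
            "habituation_interval": list(session.habituation_interval),
            "test_interval": list(session.test_interval)}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_photometry(path) -> PhotometrySession:
    df = pd.read_csv(path, dtype={"led_state": str})
    meta = json.loads(Path(str(path) + ".json").read_text())
    return PhotometrySession(t=df["t_s"].to_numpy(),
                             fluor=df["fluor"].to_numpy(),
                             led_state=df["led_state"].to_numpy(),
                             raw_rate=meta["raw_rate"],
                             habituation_interval=tuple(meta["habituation_interval"]),
                             test_interval=tuple(meta["test_interval"]))


def write_sweeps(sweeps: SweepSet, path) -> None:
    cols = {"t_s": sweeps.t}
    for label, trace in zip(sweeps.sweep_labels, sweeps.traces):
        cols[f"sweep_{label:g}"] = trace
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"mode": sweeps.mode, "rate": sweeps.rate,
            "labels": [float(v) for v in sweeps.sweep_labels],
            "stim_onsets": None if sweeps.stim_onsets is None
            else [float(v) for v in sweeps.stim_onsets]}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_sweeps(path) -> SweepSet:
    df = pd.read_csv(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    labels = np.asarray(meta["labels"], float)
    traces = np.vstack([df[f"sweep_{v:g}"].to_numpy() for v in labels])
    onsets = meta["stim_onsets"]
    return SweepSet(mode=meta["mode"], t=df["t_s"].to_numpy(), traces=traces,
                    sweep_labels=labels, rate=meta["rate"],
                    stim_onsets=None if onsets is None else np.asarray(onsets))


def write_counts(table: CountTable, counts_path, samples_path) -> None:
    table.counts.to_csv(counts_path, sep="\t", index_label="gene")
    table.samples.to_csv(samples_path, sep="\t", index_label="sample_id")


def read_counts(counts_path, samples_path) -> CountTable:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample_id")
    return CountTable(counts=counts, samples=samples)


def write_truth(truth, path) -> None:
    """JSON sidecar for any dataclass or dict ground-truth record."""
    obj = dataclasses.asdict(truth) if dataclasses.is_dataclass(truth) else truth
    Path(path).write_text(json.dumps(_plain(obj), indent=2, sort_keys=True))


def read_gene_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    out = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.add(line)
    return out


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj
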