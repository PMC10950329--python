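"""File formats: TIFF videos/images, CSV tables, YAML configs, JSON reports.

Videos are multi-frame grayscale TIFFs with a JSON sidecar
(``<stem>.meta.json``) carrying the acquisition metadata (frame interval,
protocol, seed); images are multi-channel TIFFs; tabular outputs are tidy
CSVs with documented column names.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile
import yaml

from .kinetics import FluorescenceTrace, Indicator, NormalizedTrace
from .protocols import StimulationProtocol
from .simulate import GroundTruth, SimulationConfig, TimeLapseVideo

__all__ = [
    "write_video", "load_timelapse", "write_image", "load_image",
    "write_ground_truth", "load_ground_truth",
    "traces_to_frame", "write_traces_csv",
    "protocol_to_dict", "protocol_from_dict",
    "save_yaml", "load_yaml",
]

CONFIG_SCHEMA_VERSION = 1


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def protocol_to_dict(p: StimulationProtocol) -> dict[str, Any]:
    return {"frequency": p.frequency, "duration": p.duration,
            "stim_onset": p.stim_onset, "frame_interval": p.frame_interval,
            "total_duration": p.total_duration, "n_aps": p.n_aps}


def protocol_from_dict(d: dict[str, Any]) -> StimulationProtocol:
    return StimulationProtocol(**d)


def write_video(path: str | Path, video: TimeLapseVideo,
                metadata: dict[str, Any] | None = None) -> Path:
    """Write a 16-bit multi-frame TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    frames = video.frames
    if frames.dtype not in (np.uint8, np.uint16):
        frames = np.clip(np.round(frames), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, frames, photometric="minisblack")
    meta: dict[str, Any] = {"frame_interval": video.frame_interval,
                            "dtype": str(frames.dtype),
                            "schema_version": CONFIG_SCHEMA_VERSION}
    if video.protocol is not None:
        meta["protocol"] = protocol_to_dict(video.protocol)
    if metadata:
        meta.update(metadata)
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_timelapse(path: str | Path,
                   frame_interval: float | None = None,
                   protocol: StimulationProtocol | None = None,
                   ) -> TimeLapseVideo:
    """Load a multi-frame TIFF as a time-ordered stack.

    The frame interval comes from the sidecar metadata or from the
    ``frame_interval``/``protocol`` overrides; with neither available the
    file is rejected.  If a protocol is known (sidecar or argument) the
    frame count must match it.
    """
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict[str, Any] = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    if protocol is None and "protocol" in meta:
        protocol = protocol_from_dict(meta["protocol"])
    if frame_interval is None:
        if protocol is not None:
            frame_interval = protocol.frame_interval
        elif "frame_interval" in meta:
            frame_interval = float(meta["frame_interval"])
        else:
            raise ValueError(
                f"{path.name}: no frame-interval metadata and no override")
    if protocol is not None and frames.shape[0] != protocol.n_frames:
        raise ValueError(
            f"{path.name}: {frames.shape[0]} frames but protocol expects "
            f"{protocol.n_frames}")
    return TimeLapseVideo(frames=frames, frame_interval=frame_interval,
                          protocol=protocol, source_dtype=str(frames.dtype))


def write_image(path: str | Path, image: np.ndarray,
                metadata: dict[str, Any] | None = None) -> Path:
    """Write a multi-channel image as TIFF (float images stored as-is)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(image), photometric="minisblack")
    if metadata:
        _sidecar(path).write_text(json.dumps(metadata, indent=1))
    return path


def load_image(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path))


def write_ground_truth(path: str | Path, truth: GroundTruth) -> Path:
    path = Path(path)
    truth.boutons.to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(
        {"tau_endo": truth.tau_endo,
         "tau_bleach": (None if np.isinf(truth.tau_bleach)
                        else truth.tau_bleach),
         "seed": truth.seed}, indent=1))
    return path


def load_ground_truth(path: str | Path) -> GroundTruth:
    path = Path(path)
    boutons = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text())
    tb = meta.get("tau_bleach")
    return GroundTruth(boutons=boutons, tau_endo=float(meta["tau_endo"]),
                       tau_bleach=np.inf if tb is None else float(tb),
                       seed=int(meta["seed"]))


def traces_to_frame(traces: list[FluorescenceTrace],
                    normalized: list[NormalizedTrace] | None = None
                    ) -> pd.DataFrame:
    """Tidy per-ROI trace table: roi_id, frame, time_s, F (+ norm_df)."""
    rows = []
    norm_by_id = {n.roi_id: n for n in (normalized or [])}
    for tr in traces:
        f = tr.corrected()
        nd = norm_by_id.get(tr.roi_id)
        for k in range(len(tr.time)):
            rows.append({
                "roi_id": tr.roi_id, "frame": k, "time_s": tr.time[k],
                "F": f[k],
                "norm_df": (nd.norm_df[k] if nd is not None else np.nan)})
    return pd.DataFrame(rows)


def write_traces_csv(path: str | Path, traces, normalized=None) -> Path:
    path = Path(path)
    traces_to_frame(traces, normalized).to_csv(path, index=False)
    return path


def save_yaml(path: str | Path, obj: Any) -> Path:
    path = Path(path)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    path.write_text(yaml.safe_dump(obj, sort_keys=False))
    return path


def load_yaml(path: str | Path) -> Any:
    return yaml.safe_load(Path(path).read_text())
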