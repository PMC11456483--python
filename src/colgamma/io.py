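"""Configuration handling, trace writers and run manifests.

Traces are written as plain CSV (``time_ms`` column, then one ``r_Hz_*``
column per population and optionally ``v_mV_*`` columns) with a JSON
sidecar carrying the condition, onset, network fingerprint and sampling
step, so a trace file round-trips to a :class:`~colgamma.simulator.TraceSet`
without loss of metadata.  Every CLI invocation writes a manifest that
references all of its outputs.
"""

from __future__ import annotations

import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .simulator import TraceSet


def load_config(path) -> dict:
    """Load a YAML model configuration."""
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)


def _column_name(kind: str, label: str) -> str:
    return f"{kind}_{label.replace('/', '')}"


def write_trace(trace: TraceSet, stem, include_v: bool = False) -> dict:
    """Write ``<stem>.csv`` and ``<stem>.json``; returns the sidecar dict."""
    stem = Path(stem)
    data = {"time_ms": trace.time}
    for lab in trace.labels:
        data[_column_name("r_Hz", lab)] = trace.rate(lab)
    if include_v and trace.v is not None:
        for lab in trace.labels:
            data[_column_name("v_mV", lab)] = trace.voltage(lab)
    pd.DataFrame(data).to_csv(stem.with_suffix(".csv"), index=False)
    sidecar = {
        "schema": "colgamma.trace/1",
        "labels": trace.labels,
        "condition": trace.condition,
        "t_onset": trace.t_onset,
        "dt": trace.dt,
        "fingerprint": trace.fingerprint,
        "includes_voltage": bool(include_v and trace.v is not None),
    }
    with open(stem.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
    return sidecar


def read_trace(stem) -> TraceSet:
    """Read a trace written by :func:`write_trace`."""
    stem = Path(stem)
    with open(stem.with_suffix(".json")) as fh:
        meta = json.load(fh)
    df = pd.read_csv(stem.with_suffix(".csv"))
    labels = meta["labels"]
    r = np.column_stack([df[_column_name("r_Hz", lab)].to_numpy() for lab in labels])
    v = None
    if meta.get("includes_voltage"):
        v = np.column_stack([df[_column_name("v_mV", lab)].to_numpy() for lab in labels])
    return TraceSet(
        time=df["time_ms"].to_numpy(),
        r=r,
        v=v,
        labels=labels,
        condition=meta["condition"],
        t_onset=float(meta["t_onset"]),
        fingerprint=meta.get("fingerprint", ""),
        dt=float(meta.get("dt", 0.01)),
    )


def write_manifest(
    path,
    command: str,
    config: dict,
    outputs: list,
    fingerprint: str = "",
    seed: Optional[int] = None,
) -> dict:
    """Write a run manifest referencing every output of one invocation."""
    from . import __version__

    manifest = {
        "schema": "colgamma.manifest/1",
        "command": command,
        "code_version": __version__,
        "platform": platform.platform(),
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "spec_fingerprint": fingerprint,
        "seed": seed,   # recorded even for the deterministic mean field
        "config": config,
        "outputs": [str(p) for p in outputs],
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
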