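"""Tidy CSV readers/writers for traces, trajectories, and ground truth.

Formats
-------
Calcium traces: ``animal_id, neuron, group, t_s, donor, acceptor``.
Trajectories:   ``animal_id, group, t_s, x_mm, y_mm``.
Ground truth (calcium): one row per animal with the generator parameters.
The stimulus protocol travels separately as JSON/YAML (see
:meth:`nemoresponse.protocol.StimulusProtocol.to_dict`).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .behavior import Trajectory
from .calcium import CalciumTrace
from .errors import InvalidArgumentError
from .protocol import StimulusProtocol

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_trajectories_csv",
    "read_trajectories_csv",
    "write_protocol",
    "read_protocol",
]


def write_traces_csv(traces: list[CalciumTrace], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "neuron": t.neuron,
                "group": t.group,
                "t_s": t.t_s,
                "donor": t.donor,
                "acceptor": t.acceptor,
            }
        )
        for t in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_traces_csv(path: str | Path, protocol: StimulusProtocol) -> list[CalciumTrace]:
    df = pd.read_csv(path)
    required = {"animal_id", "t_s", "donor", "acceptor"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"trace CSV needs columns {sorted(required)}")
    out = []
    for aid, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(
            CalciumTrace(
                animal_id=str(aid),
                neuron=str(grp["neuron"].iloc[0]) if "neuron" in grp else "",
                group=str(grp["group"].iloc[0]) if "group" in grp else "",
                t_s=grp["t_s"].to_numpy(),
                donor=grp["donor"].to_numpy(),
                acceptor=grp["acceptor"].to_numpy(),
                protocol=protocol,
            )
        )
    return out


def write_trajectories_csv(trajs: list[Trajectory], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "animal_id": t.animal_id,
                "group": t.group,
                "t_s": t.t_s,
                "x_mm": t.x_mm,
                "y_mm": t.y_mm,
            }
        )
        for t in trajs
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectories_csv(path: str | Path, protocol: StimulusProtocol) -> list[Trajectory]:
    df = pd.read_csv(path)
    required = {"animal_id", "t_s", "x_mm", "y_mm"}
    if not required.issubset(df.columns):
        raise InvalidArgumentError(f"trajectory CSV needs columns {sorted(required)}")
    out = []
    for aid, grp in df.groupby("animal_id", sort=False):
        grp = grp.sort_values("t_s")
        out.append(
            Trajectory(
                animal_id=str(aid),
                group=str(grp["group"].iloc[0]) if "group" in grp else "",
                t_s=grp["t_s"].to_numpy(),
                x_mm=grp["x_mm"].to_numpy(),
                y_mm=grp["y_mm"].to_numpy(),
                protocol=protocol,
            )
        )
    return out


def write_protocol(protocol: StimulusProtocol, path: str | Path) -> None:
    path = Path(path)
    d = protocol.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d))
    else:
        path.write_text(json.dumps(d, indent=2))


def read_protocol(path: str | Path) -> StimulusProtocol:
    path = Path(path)
    text = path.read_text()
    d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return StimulusProtocol.from_dict(d)
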