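"""Uniformly sampled simulation traces and their TSV serialization.

A :class:`Trace` carries a time axis, named data columns (units encoded in
the column names), an event table (attach/detach jumps with the total
motor energies immediately before and after each flip) and a metadata
dict recording the master seed and resolved parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = ["t_s", "motor_id", "kind", "x_nm", "E_before_pNnm", "E_after_pNnm"]


def empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "t_s": np.array([], dtype=float),
            "motor_id": np.array([], dtype=np.int64),
            "kind": np.array([], dtype=object),
            "x_nm": np.array([], dtype=float),
            "E_before_pNnm": np.array([], dtype=float),
            "E_after_pNnm": np.array([], dtype=float),
        }
    )


@dataclass
class Trace:
    t: np.ndarray
    data: dict[str, np.ndarray]
    events: pd.DataFrame = field(default_factory=empty_events)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for k, v in self.data.items():
            if len(v) != len(self.t):
                raise ValueError(f"column {k!r} length != time axis length")

    def __len__(self) -> int:
        return len(self.t)

    def __getitem__(self, key: str) -> np.ndarray:
        return self.data[key]

    @property
    def dt_sample(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else np.nan

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, **self.data})

    def write_tsv(self, path: str | Path, events: bool = True) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k} = {v}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")
        if events and len(self.events):
            self.events.to_csv(
                path.with_suffix(".events.tsv"), sep="\t", index=False,
                float_format="%.10g",
            )

    @classmethod
    def read_tsv(cls, path: str | Path) -> "Trace":
        path = Path(path)
        meta: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh, sep="\t")
        ev_path = path.with_suffix(".events.tsv")
        events = pd.read_csv(ev_path, sep="\t") if ev_path.exists() else empty_events()
        t = df.pop("t_s").to_numpy()
        return cls(t=t, data={c: df[c].to_numpy() for c in df.columns},
                   events=events, meta=meta)


def events_frame(t, motor, kind_code, x, e_before, e_after) -> pd.DataFrame:
    """Assemble an event table from raw kernel arrays (kind: 1=attach, -1=detach)."""
    kind = np.where(np.asarray(kind_code) > 0, "attach", "detach")
    return pd.DataFrame(
        {
            "t_s": np.asarray(t, dtype=float),
            "motor_id": np.asarray(motor, dtype=np.int64),
            "kind": kind,
            "x_nm": np.asarray(x, dtype=float),
            "E_before_pNnm": np.asarray(e_before, dtype=float),
            "E_after_pNnm": np.asarray(e_after, dtype=float),
        }
    )
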