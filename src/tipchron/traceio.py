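"""BEAST-style tab-separated MCMC trace logs.

A trace file starts with ``#`` comment lines (run metadata such as the seed
and a config digest), then a header whose first column is ``state``, then
one row per sampled state.  Values round-trip at 12 significant digits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError


class Trace:
    """Sampled MCMC states: a strictly increasing ``state`` index plus named
    real-valued parameter columns."""

    def __init__(self, df: pd.DataFrame, metadata: dict | None = None):
        if "state" not in df.columns:
            raise FormatError("trace must have a 'state' column")
        states = df["state"].to_numpy()
        if len(states) > 1 and np.any(np.diff(states) <= 0):
            raise FormatError("trace 'state' column must be strictly increasing")
        self.df = df.reset_index(drop=True)
        self.metadata = dict(metadata or {})

    @property
    def columns(self) -> list[str]:
        return [c for c in self.df.columns if c != "state"]

    def __len__(self) -> int:
        return len(self.df)

    def __getitem__(self, column: str) -> np.ndarray:
        return self.df[column].to_numpy()

    def burned_in(self, fraction: float) -> "Trace":
        """Drop the first ``fraction`` of samples."""
        if not (0 <= fraction < 1):
            raise FormatError("burn-in fraction must be in [0, 1)")
        start = int(np.ceil(fraction * len(self.df)))
        return Trace(self.df.iloc[start:].reset_index(drop=True), self.metadata)


def write_trace(trace: Trace, path) -> None:
    with open(path, "w") as fh:
        for key, value in trace.metadata.items():
            fh.write(f"# {key}={value}\n")
        cols = ["state"] + trace.columns
        fh.write("\t".join(cols) + "\n")
        for _, row in trace.df[cols].iterrows():
            fields = [f"{int(row['state'])}"] + [f"{row[c]:.12g}" for c in trace.columns]
            fh.write("\t".join(fields) + "\n")


def read_trace(path) -> Trace:
    metadata = {}
    header: list[str] | None = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    metadata[key.strip()] = value.strip()
                continue
            if not line:
                continue
            if header is None:
                header = line.split("\t")
                if not header or header[0] != "state":
                    raise FormatError("trace header must start with a 'state' column")
                continue
            rows.append([float(x) for x in line.split("\t")])
    if header is None:
        raise FormatError("trace file has no header")
    df = pd.DataFrame(rows, columns=header) if rows else pd.DataFrame(columns=header)
    df["state"] = df["state"].astype(np.int64) if len(df) else df["state"]
    return Trace(df, metadata)
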