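"""Ancient-DNA consensus calling from per-site base counts.

The rule: positions covered by fewer than ``min_cov`` reads are masked to
``N``; a base supported by at least ``major_frac`` of the reads is called
plainly; otherwise the set of bases each supported by at least
``1 - major_frac`` of the reads is collapsed to its IUPAC ambiguity code.
Defaults (coverage 3, majority 75%) follow common aDNA mitogenome practice.
Indels are not represented: the rule addresses substitutions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FormatError, ParameterError

BASES = "ACGT"

#: sorted base tuple -> IUPAC code (the 15 non-empty subsets of {A,C,G,T})
IUPAC_FROM_SET = {
    ("A",): "A", ("C",): "C", ("G",): "G", ("T",): "T",
    ("A", "G"): "R", ("C", "T"): "Y", ("C", "G"): "S", ("A", "T"): "W",
    ("G", "T"): "K", ("A", "C"): "M",
    ("C", "G", "T"): "B", ("A", "G", "T"): "D", ("A", "C", "T"): "H",
    ("A", "C", "G"): "V", ("A", "C", "G", "T"): "N",
}


@dataclass
class Pileup:
    """Per-position counts of observed A, C, G, T reads (shape L x 4)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise FormatError("pileup counts must be an (L, 4) array")
        if np.any(self.counts < 0):
            raise FormatError("pileup counts must be non-negative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def coverage(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def call_consensus(pileup: Pileup, min_cov: int = 3, major_frac: float = 0.75) -> str:
    """Call one consensus base per pileup position.

    Per position: coverage below ``min_cov`` gives ``N``; a top base with
    fraction >= ``major_frac`` is called directly; otherwise all bases with
    fraction >= ``1 - major_frac`` form the IUPAC ambiguity call (``N`` if,
    defensively, none qualifies).
    """
    if min_cov < 1:
        raise ParameterError("min_cov must be >= 1")
    if not (0.5 < major_frac <= 1.0):
        raise ParameterError("major_frac must be in (0.5, 1]")

    counts = pileup.counts
    cov = pileup.coverage
    out = []
    minor_frac = 1.0 - major_frac
    for pos in range(len(pileup)):
        n = cov[pos]
        if n < min_cov:
            out.append("N")
            continue
        row = counts[pos]
        top = row.max()
        if top >= major_frac * n:
            out.append(BASES[int(row.argmax())])
            continue
        members = tuple(BASES[i] for i in range(4) if row[i] >= minor_frac * n)
        out.append(IUPAC_FROM_SET.get(members, "N"))
    return "".join(out)


def read_pileup(path) -> Pileup:
    """Read a tab-separated pileup table with columns pos, A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    for col in ("pos", "A", "C", "G", "T"):
        if col not in df.columns:
            raise FormatError(f"pileup table missing column '{col}'")
    df = df.sort_values("pos")
    expected = np.arange(len(df))
    if not np.array_equal(df["pos"].to_numpy(), expected):
        raise FormatError("pileup positions must be 0..L-1 without gaps")
    return Pileup(df[["A", "C", "G", "T"]].to_numpy())


def write_pileup(pileup: Pileup, path) -> None:
    df = pd.DataFrame(pileup.counts, columns=list(BASES))
    df.insert(0, "pos", np.arange(len(pileup)))
    df.to_csv(path, sep="\t", index=False)
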