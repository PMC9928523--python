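"""Alignments and per-sample date metadata.

An :class:`Alignment` is an equal-length nucleotide matrix over the IUPAC
alphabet (plus ``N`` and ``-``, both treated as missing data downstream).
A :class:`SampleTable` carries, per sample, the sampling site and its dating
status: ``radiocarbon`` (uncalibrated 14C age +/- error, years BP),
``undated`` (ancient, age unknown) or ``modern`` (age 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO

from .errors import FormatError

IUPAC_CHARS = set("ACGTRYSWKMBDHVN-")
DATE_TYPES = ("radiocarbon", "undated", "modern")

#: IUPAC code -> set of plain bases it denotes
AMBIGUITY = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "-": "ACGT",
}


@dataclass
class Alignment:
    taxa: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise FormatError("taxa and sequences must have equal counts")
        if len(set(self.taxa)) != len(self.taxa):
            dupes = {t for t in self.taxa if self.taxa.count(t) > 1}
            raise FormatError(f"duplicate taxon name(s): {sorted(dupes)}")
        if not self.sequences:
            raise FormatError("empty alignment")
        length = len(self.sequences[0])
        for taxon, seq in zip(self.taxa, self.sequences):
            if len(seq) != length:
                raise FormatError(
                    f"ragged alignment: sequence for '{taxon}' has length "
                    f"{len(seq)}, expected {length}"
                )
            bad = set(seq) - IUPAC_CHARS
            if bad:
                raise FormatError(f"illegal character(s) {sorted(bad)} in sequence '{taxon}'")

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def sequence(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]

    def subset(self, taxa: list[str]) -> "Alignment":
        missing = [t for t in taxa if t not in self.taxa]
        if missing:
            raise FormatError(f"taxa not in alignment: {missing}")
        return Alignment(list(taxa), [self.sequence(t) for t in taxa])

    def __repr__(self) -> str:
        return f"<Alignment {self.n_taxa} taxa x {self.length} sites>"


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment; lowercase is uppercased and U mapped to T."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    taxa = [r.id for r in records]
    seqs = [_normalize(str(r.seq)) for r in records]
    return Alignment(taxa, seqs)


def write_alignment(aln: Alignment, path) -> None:
    with open(path, "w") as fh:
        for taxon, seq in zip(aln.taxa, aln.sequences):
            fh.write(f">{taxon}\n{seq}\n")


@dataclass
class SampleRecord:
    id: str
    site: str
    date_type: str
    c14_age: float | None = None
    c14_error: float | None = None

    def __post_init__(self) -> None:
        if self.date_type not in DATE_TYPES:
            raise FormatError(
                f"unknown date_type '{self.date_type}' for sample '{self.id}' "
                f"(expected one of {DATE_TYPES})"
            )
        has_age = self.c14_age is not None
        has_err = self.c14_error is not None
        if self.date_type == "radiocarbon":
            if not (has_age and has_err):
                raise FormatError(f"radiocarbon sample '{self.id}' needs both c14_age and c14_error")
            if self.c14_error <= 0:
                raise FormatError(f"c14_error must be > 0 for sample '{self.id}'")
        elif has_age or has_err:
            raise FormatError(f"non-radiocarbon sample '{self.id}' must not carry c14 fields")


class SampleTable:
    """Typed per-sample metadata, cross-checkable against an alignment."""

    REQUIRED = ["id", "site", "date_type", "c14_age", "c14_error"]

    def __init__(self, records: list[SampleRecord]):
        self.records = list(records)
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise FormatError("duplicate sample ids")
        self._by_id = {r.id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, sample_id: str) -> SampleRecord:
        return self._by_id[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self._by_id

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def of_type(self, date_type: str) -> list[SampleRecord]:
        return [r for r in self.records if r.date_type == date_type]

    def check_against(self, aln: Alignment) -> None:
        missing = sorted(set(self.ids) - set(aln.taxa))
        if missing:
            raise FormatError(f"sample ids absent from alignment: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "id": r.id,
                    "site": r.site,
                    "date_type": r.date_type,
                    "c14_age": r.c14_age,
                    "c14_error": r.c14_error,
                }
                for r in self.records
            ]
        )


def read_sample_table(path) -> SampleTable:
    """Read the tab-separated sample metadata table.

    The header must contain ``id site date_type c14_age c14_error``; extra
    columns are preserved in the raw frame but ignored.  ``c14_age`` and
    ``c14_error`` may be blank for undated/modern rows.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "site": str, "date_type": str})
    missing = [c for c in SampleTable.REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing column(s): {missing}")
    records = []
    for _, row in df.iterrows():
        age = row["c14_age"]
        err = row["c14_error"]
        records.append(
            SampleRecord(
                id=str(row["id"]),
                site=str(row["site"]),
                date_type=str(row["date_type"]),
                c14_age=None if pd.isna(age) else float(age),
                c14_error=None if pd.isna(err) else float(err),
            )
        )
    return SampleTable(records)


def write_sample_table(table: SampleTable, path) -> None:
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="")
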