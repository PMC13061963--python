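"""Core read containers and FASTQ input/output.

A :class:`Read` is a sequence with per-base Phred qualities plus processing
flags (terminal trimming, concatemer) and an open ``meta`` dict used by the
synthetic generator to carry ground truth (true class, true motif, artifact
flags). A :class:`ReadPool` is an ordered collection of reads.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")

__all__ = [
    "Read",
    "ReadPool",
    "AdapterSet",
    "FastqParseError",
    "load_fastq",
    "write_fastq",
]


class FastqParseError(ValueError):
    """Raised when a FASTQ record cannot be parsed; names the record index."""


@dataclass
class Read:
    id: str
    sequence: str
    qualities: np.ndarray  # Phred scores, one per base
    flags: set = field(default_factory=set)  # subset of {"trimmed_5p","trimmed_3p","concatemer"}
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = str(self.sequence).upper()
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int) -> "Read":
        """Return a sub-read over [start, stop), sharing id, flags and meta."""
        return Read(
            self.id,
            self.sequence[start:stop],
            self.qualities[start:stop].copy(),
            flags=set(self.flags),
            meta=dict(self.meta),
        )


class ReadPool:
    """Ordered collection of reads."""

    def __init__(self, reads: Iterable[Read] = ()) -> None:
        self.reads: list[Read] = list(reads)

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self) -> Iterator[Read]:
        return iter(self.reads)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return ReadPool(self.reads[i])
        return self.reads[i]

    def lengths(self) -> np.ndarray:
        return np.array([len(r) for r in self.reads], dtype=np.int64)

    def subset(self, predicate) -> "ReadPool":
        return ReadPool(r for r in self.reads if predicate(r))

    def ground_truth_frame(self) -> pd.DataFrame:
        """Sidecar table of per-read ground truth and flags (TSV-friendly)."""
        rows = []
        for r in self.reads:
            rows.append(
                {
                    "read_id": r.id,
                    "length": len(r),
                    "class": r.meta.get("true_class", ""),
                    "true_motif": r.meta.get("true_motif", ""),
                    "is_concatemer_truth": bool(r.meta.get("is_concatemer_truth", False)),
                    "has_adapters_truth": bool(r.meta.get("has_adapters_truth", False)),
                    "flags": ",".join(sorted(r.flags)),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class AdapterSet:
    """Named adapter/barcode sequences searched during trimming and QC."""

    adapters: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.adapters:
            raise ValueError("AdapterSet must contain at least one adapter")
        if any(not a for a in self.adapters):
            raise ValueError("adapters must be non-empty")
        object.__setattr__(self, "adapters", tuple(a.upper() for a in self.adapters))

    def __iter__(self) -> Iterator[str]:
        return iter(self.adapters)


def load_fastq(path: str | Path | io.TextIOBase) -> ReadPool:
    """Load a Phred+33 FASTQ file into a :class:`ReadPool`.

    Malformed records raise :class:`FastqParseError` naming the record index.
    """
    handle = open(path) if isinstance(path, (str, Path)) else path
    reads: list[Read] = []
    try:
        for i, rec in enumerate(SeqIO.parse(handle, "fastq")):
            reads.append(
                Read(rec.id, str(rec.seq), np.array(rec.letter_annotations["phred_quality"]))
            )
    except ValueError as exc:
        raise FastqParseError(f"malformed FASTQ record at index {len(reads)}: {exc}") from exc
    finally:
        if isinstance(path, (str, Path)):
            handle.close()
    return ReadPool(reads)


def write_fastq(pool: ReadPool | Sequence[Read], path: str | Path) -> None:
    """Write reads as standard 4-line Phred+33 FASTQ records."""
    records = []
    for r in pool:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in r.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")
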