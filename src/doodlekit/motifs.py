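"""Tandem-repeat motif detection, fraction tables, fingerprints and genome scans.

A read "contains" a motif when the motif occurs in an uninterrupted
back-to-back run of at least a length-dependent number of exact copies:
7 consecutive copies for 1-3 nt motifs, 6 for 4 nt motifs, and 4 for
6-8 nt motifs. Matching is exact — partial trailing copies and copies
broken by a single substitution do not count — which makes the classifier
stringent on noisy reads but free of alignment heuristics.

Motif fractions over a pool are estimated from a seeded random sample of
reads longer than a minimum length (600 reads > 65 nt by default), one
classification per sampled read. Pool-level fraction vectors act as
condition "fingerprints"; comparing two conditions reports per-motif
percentage change and fold change.

The genome scan counts non-overlapping, leftmost-greedy perfect occurrences
of a doubled motif on the forward strand and reports the genome proportion
(n x m) / g, with m the length of the searched repeated string and g the
genome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from .reads import ReadPool

__all__ = [
    "DEFAULT_THRESHOLDS",
    "DEFAULT_PANEL_MOTIFS",
    "MotifPanel",
    "RepeatCall",
    "GenomeScanResult",
    "Fingerprint",
    "canonical_rotation",
    "max_tandem_copies",
    "classify_read",
    "motif_fraction_table",
    "fingerprint_from_table",
    "fingerprint_change",
    "motif_probability",
    "genome_repeat_scan",
]

# Minimum consecutive copies by motif length: 7 for 1-3 nt, 6 for 4 nt,
# 4 for 6-8 nt; longer palindromic motifs (A^4T^4, A^5T^5) follow the
# long-motif rule.
DEFAULT_THRESHOLDS: dict[int, int] = {1: 7, 2: 7, 3: 7, 4: 6, 6: 4, 7: 4, 8: 4, 9: 4, 10: 4}

# Motif columns observed across polymerases and conditions.
DEFAULT_PANEL_MOTIFS: tuple[str, ...] = (
    "A",
    "T",
    "AT",
    "GT",
    "CG",
    "AATT",
    "GGT",
    "CTATAG",
    "TCATGA",
    "CTTAAG",
    "CAATTG",
    "GTATAC",
    "GTATATAC",
    "CATATATG",
    "CATATG",
    "AAAATTTT",
    "AAAAATTTTT",
)


def canonical_rotation(motif: str) -> str:
    """Lexicographically smallest rotation (so GT and TG share one name)."""
    if not motif:
        raise ValueError("motif must be non-empty")
    doubled = motif + motif
    return min(doubled[i : i + len(motif)] for i in range(len(motif)))


@dataclass(frozen=True)
class MotifPanel:
    motifs: tuple[str, ...] = DEFAULT_PANEL_MOTIFS
    thresholds: Mapping[int, int] = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))
    canonicalize_rotations: bool = False

    def __post_init__(self) -> None:
        if not self.motifs:
            raise ValueError("panel must contain at least one motif")
        for m in self.motifs:
            if not m or set(m) - set("ACGT"):
                raise ValueError(f"invalid panel motif {m!r}")
        if any(t < 2 for t in self.thresholds.values()):
            raise ValueError("copy thresholds must be >= 2")
        object.__setattr__(self, "motifs", tuple(m.upper() for m in self.motifs))

    def threshold(self, motif: str) -> int:
        try:
            return self.thresholds[len(motif)]
        except KeyError:
            raise KeyError(f"no copy threshold configured for motif length {len(motif)}")


@dataclass(frozen=True)
class RepeatCall:
    motif: str
    max_copies: int
    start: int  # 0-based offset of the maximal run (0 when max_copies == 0)
    passes_threshold: bool


@dataclass(frozen=True)
class GenomeScanResult:
    n: int  # occurrences of the repeated string
    m: int  # length of the searched repeated string (nt)
    g: int  # genome length (nt)

    @property
    def proportion(self) -> float:
        return self.n * self.m / self.g


@dataclass(frozen=True)
class Fingerprint:
    """Per-motif read fractions for one pool/condition."""

    fractions: Mapping[str, float]
    n_reads_assessed: int


def max_tandem_copies(sequence: str, motif: str, threshold: Optional[int] = None) -> RepeatCall:
    """Maximum number of back-to-back exact copies of ``motif`` in ``sequence``.

    Right-to-left dynamic program: copies starting at i is 1 + copies at i+|m|
    when the motif matches at i. Sequences shorter than the motif yield 0.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    motif = motif.upper()
    sequence = sequence.upper()
    n, m = len(sequence), len(motif)
    if n < m:
        passes = threshold is not None and 0 >= threshold
        return RepeatCall(motif, 0, 0, passes)
    copies = np.zeros(n + m, dtype=np.int64)  # copies[i] for start i; tail zeros
    best, best_start = 0, 0
    for i in range(n - m, -1, -1):
        if sequence[i : i + m] == motif:
            copies[i] = 1 + copies[i + m]
            if copies[i] >= best:  # >= keeps the leftmost maximal run
                best, best_start = int(copies[i]), i
    passes = threshold is not None and best >= threshold
    return RepeatCall(motif, best, best_start, passes)


def _copies_for_panel_motif(sequence: str, motif: str, panel: MotifPanel) -> int:
    if panel.canonicalize_rotations:
        rots = {motif[i:] + motif[:i] for i in range(len(motif))}
        return max(max_tandem_copies(sequence, r).max_copies for r in rots)
    return max_tandem_copies(sequence, motif).max_copies


def classify_read(sequence: str, panel: MotifPanel) -> set[str]:
    """Panel motifs whose tandem-copy threshold is met anywhere in the read.

    A read may carry several motifs; short reads trivially fail rather than
    erroring.
    """
    found: set[str] = set()
    for motif in panel.motifs:
        if _copies_for_panel_motif(sequence, motif, panel) >= panel.threshold(motif):
            found.add(motif)
    return found


def motif_fraction_table(
    pool: ReadPool,
    panel: MotifPanel | None = None,
    n_sample: int = 600,
    min_length: int = 65,
    seed: int | None = None,
) -> pd.DataFrame:
    """Fraction of sampled reads containing each panel motif.

    Samples ``min(n_sample, available)`` reads strictly longer than
    ``min_length`` uniformly without replacement, classifies each, and
    reports per-motif fractions. Absent motifs are exactly 0.
    """
    panel = panel or MotifPanel()
    eligible = [r for r in pool if len(r) > min_length]
    if not eligible:
        raise ValueError(f"no reads longer than {min_length} nt to sample")
    rng = np.random.default_rng(seed)
    k = min(n_sample, len(eligible))
    idx = rng.choice(len(eligible), size=k, replace=False)
    counts = {m: 0 for m in panel.motifs}
    for i in idx:
        for m in classify_read(eligible[i].sequence, panel):
            counts[m] += 1
    rows = [{"motif": m, "fraction": counts[m] / k, "n_reads": counts[m]} for m in panel.motifs]
    table = pd.DataFrame(rows).set_index("motif")
    table.attrs["n_reads_assessed"] = k
    return table


def fingerprint_from_table(table: pd.DataFrame) -> Fingerprint:
    return Fingerprint(
        dict(table["fraction"]), int(table.attrs.get("n_reads_assessed", table["n_reads"].sum()))
    )


def fingerprint_change(fp_a: Fingerprint, fp_b: Fingerprint) -> pd.DataFrame:
    """Per-motif change from condition a to b.

    Columns: fraction_a, fraction_b, percent_change = 100 (b - a)/a,
    fold_change = b/a, and infinite_increase for a == 0 < b.
    """
    if set(fp_a.fractions) != set(fp_b.fractions):
        raise ValueError("fingerprints cover different motif sets")
    rows = []
    for motif in fp_a.fractions:
        a, b = fp_a.fractions[motif], fp_b.fractions[motif]
        inf_up = a == 0 and b > 0
        rows.append(
            {
                "motif": motif,
                "fraction_a": a,
                "fraction_b": b,
                "percent_change": np.nan if a == 0 else 100.0 * (b - a) / a,
                "fold_change": np.nan if a == 0 else b / a,
                "infinite_increase": inf_up,
            }
        )
    return pd.DataFrame(rows).set_index("motif")


def motif_probability(length: int) -> float:
    """Probability of one specific sequence of ``length`` nt at one position,
    under i.i.d. uniform base usage: (1/4)**length."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return 0.25**length


def genome_repeat_scan(
    genome_sequence: str,
    motif: str,
    min_copies: int = 2,
    overlapping: bool = False,
) -> GenomeScanResult:
    """Count perfect occurrences of ``motif`` repeated ``min_copies`` times.

    Forward strand only; default counting is non-overlapping leftmost-greedy
    (after a hit the scan resumes past it). ``overlapping=True`` advances one
    base at a time instead.
    """
    if not genome_sequence:
        raise ValueError("genome must be non-empty")
    if not motif:
        raise ValueError("motif must be non-empty")
    target = motif.upper() * min_copies
    genome = genome_sequence.upper()
    m = len(target)
    n = 0
    pos = genome.find(target)
    while pos != -1:
        n += 1
        pos = genome.find(target, pos + (1 if overlapping else m))
    return GenomeScanResult(n, m, len(genome))


def scan_motif_panel(
    genome_sequence: str, motifs: Iterable[str], min_copies: int = 2
) -> pd.DataFrame:
    """Genome scan over several motifs; one row per motif."""
    rows = []
    for motif in motifs:
        res = genome_repeat_scan(genome_sequence, motif, min_copies)
        rows.append(
            {"motif": motif, "n": res.n, "m": res.m, "g": res.g, "proportion": res.proportion}
        )
    return pd.DataFrame(rows).set_index("motif")
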