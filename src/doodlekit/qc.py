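"""Read QC: terminal adapter trimming, concatemer flagging, length/quality filters.

The filtering rules follow the long-read pipeline used for untemplated
synthesis pools: trim adapter/barcode content from the read ends, discard
concatemer reads (an adapter found *inside* the read indicates two ligated
fragments basecalled as one), then keep reads with median Phred quality >= 13
and length strictly greater than 65 nt (shorter sequences are likely library
preparation fragments such as free adapters and barcodes).

Adapter matching is an exhaustive ungapped offset scan: every placement of
the adapter against the search region is scored by exact base identity over
the overlap. A hit requires identity >= ``min_identity`` over an overlap of
at least ``min_match_len`` nt. ``N`` never counts as a match.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from .reads import AdapterSet, Read, ReadPool

__all__ = [
    "FilterParams",
    "FilterReport",
    "AdapterHit",
    "median_q",
    "best_adapter_hit",
    "trim_terminal_adapters",
    "is_concatemer",
    "flag_concatemers",
    "apply_filters",
    "extract_between_flanks",
    "qc_pipeline",
]


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for trimming and filtering.

    min_length_exclusive: reads must be strictly longer (nt).
    min_median_q: inclusive median Phred threshold.
    end_window: how far from each end terminal adapters are searched (nt).
    min_identity: fraction of identical bases over the aligned overlap.
    min_match_len: minimum overlap length for a hit to count (nt).
    """

    min_length_exclusive: int = 65
    min_median_q: float = 13.0
    end_window: int = 150
    min_identity: float = 0.8
    min_match_len: int = 12

    def __post_init__(self) -> None:
        if self.min_length_exclusive < 0 or self.min_median_q < 0:
            raise ValueError("thresholds must be >= 0")
        if not (0 < self.min_identity <= 1):
            raise ValueError("min_identity must be in (0, 1]")
        if self.min_match_len < 1 or self.end_window < 1:
            raise ValueError("end_window and min_match_len must be >= 1")


@dataclass
class FilterReport:
    input_reads: int = 0
    trimmed_5p: int = 0
    trimmed_3p: int = 0
    concatemers: int = 0
    fail_length: int = 0
    fail_quality: int = 0
    retained: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class AdapterHit:
    """An adapter placement on a read: [start, end) in read coordinates."""

    adapter: str
    start: int
    end: int
    matches: int
    overlap: int

    @property
    def identity(self) -> float:
        return self.matches / self.overlap

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


def median_q(read: Read) -> float:
    """Median per-base Phred score; even-length median is the central-pair mean."""
    if len(read) == 0:
        raise ValueError("median_q undefined for an empty read")
    return float(np.median(read.qualities))


def _scan_hits(sequence: str, adapter: str, params: FilterParams) -> list[AdapterHit]:
    """All qualifying ungapped placements of ``adapter`` on ``sequence``.

    Offsets range over partial overlaps at both ends; N matches nothing.
    """
    n, m = len(sequence), len(adapter)
    if n == 0:
        return []
    seq = np.frombuffer(sequence.encode(), dtype=np.uint8)
    adp = np.frombuffer(adapter.encode(), dtype=np.uint8)
    n_code = ord("N")
    hits: list[AdapterHit] = []
    # full-overlap placements, vectorized over all offsets at once
    if n >= m and m >= params.min_match_len:
        windows = np.lib.stride_tricks.sliding_window_view(seq, m)
        eq = (windows == adp) & (windows != n_code) & (adp != n_code)
        match_counts = eq.sum(axis=1)
        for offset in np.nonzero(match_counts / m >= params.min_identity)[0]:
            hits.append(AdapterHit(adapter, int(offset), int(offset) + m, int(match_counts[offset]), m))
    # partial overlaps hanging off either read end
    partial = [off for off in range(-m + 1, 0)] + [off for off in range(max(0, n - m + 1), n)]
    for offset in partial:
        s0, s1 = max(0, offset), min(n, offset + m)
        overlap = s1 - s0
        if overlap < params.min_match_len or overlap == m:
            continue
        a0 = s0 - offset
        s_seg = seq[s0:s1]
        a_seg = adp[a0 : a0 + overlap]
        matches = int(np.sum((s_seg == a_seg) & (s_seg != n_code) & (a_seg != n_code)))
        if matches / overlap >= params.min_identity:
            hits.append(AdapterHit(adapter, s0, s1, matches, overlap))
    return hits


def best_adapter_hit(
    sequence: str, adapters: AdapterSet, params: FilterParams
) -> Optional[AdapterHit]:
    """Highest-scoring qualifying hit of any adapter (most matched bases wins)."""
    best: Optional[AdapterHit] = None
    for adapter in adapters:
        for hit in _scan_hits(sequence, adapter, params):
            if best is None or (hit.matches, hit.identity) > (best.matches, best.identity):
                best = hit
    return best


def trim_terminal_adapters(read: Read, adapters: AdapterSet, params: FilterParams) -> Read:
    """Cut adapter content found within ``end_window`` of either read end.

    The read is cut at the adapter's inner boundary (everything outward of the
    hit is removed with it). Idempotent: a second pass finds nothing new.
    """
    out = read
    w = params.end_window
    # 5' end
    hit = best_adapter_hit(out.sequence[: min(w, len(out))], adapters, params)
    if hit is not None:
        out = out.slice(hit.end, len(out))
        out.flags.add("trimmed_5p")
    # 3' end
    n = len(out)
    tail_start = max(0, n - w)
    hit = best_adapter_hit(out.sequence[tail_start:], adapters, params)
    if hit is not None:
        out = out.slice(0, tail_start + hit.start)
        out.flags.add("trimmed_3p")
    return out


def is_concatemer(read: Read, adapters: AdapterSet, params: FilterParams) -> bool:
    """True iff an adapter hit sits *inside* the read, outside both end windows.

    A hit straddling the window boundary is attributed by its midpoint.
    Assumes the read has already been terminally trimmed.
    """
    n = len(read)
    w = params.end_window
    lo, hi = w, n - w
    if hi <= lo:
        return False  # read too short to have an interior
    for adapter in adapters:
        for hit in _scan_hits(read.sequence, adapter, params):
            if lo < hit.midpoint < hi:
                return True
    return False


def flag_concatemers(pool: ReadPool, adapters: AdapterSet, params: FilterParams) -> ReadPool:
    """Set the ``concatemer`` flag on every read with an internal adapter."""
    for r in pool:
        if is_concatemer(r, adapters, params):
            r.flags.add("concatemer")
    return pool


def apply_filters(pool: ReadPool, params: FilterParams) -> tuple[ReadPool, FilterReport]:
    """Length (>65 nt, exclusive), median-Q (>=13, inclusive) and concatemer filters.

    Reads failing several rules are counted under each rule in the report but
    removed once. Concatemer status is taken from the read's flag (set by
    :func:`flag_concatemers` or carried from upstream QC).
    """
    report = FilterReport(input_reads=len(pool))
    kept: list[Read] = []
    for r in pool:
        ok = True
        if len(r) <= params.min_length_exclusive:
            report.fail_length += 1
            ok = False
        if len(r) == 0 or median_q(r) < params.min_median_q:
            report.fail_quality += 1
            ok = False
        if "concatemer" in r.flags:
            report.concatemers += 1
            ok = False
        if ok:
            kept.append(r)
    report.retained = len(kept)
    return ReadPool(kept), report


def extract_between_flanks(
    read: Read, flank5: str, flank3: str, params: FilterParams
) -> Optional[str]:
    """Subsequence enclosed by the best 5' then 3' flank matches, in order.

    The leftmost qualifying ``flank5`` hit is paired with the nearest
    non-overlapping ``flank3`` hit that follows it. Returns ``None`` when
    either flank is absent.
    """
    if not flank5 or not flank3:
        raise ValueError("flanks must be non-empty")
    # Full-length flank matches only: demand the whole flank aligns.
    p5 = FilterParams(
        min_identity=params.min_identity,
        min_match_len=len(flank5),
        end_window=params.end_window,
    )
    p3 = FilterParams(
        min_identity=params.min_identity,
        min_match_len=len(flank3),
        end_window=params.end_window,
    )
    hits5 = _scan_hits(read.sequence, flank5, p5)
    if not hits5:
        return None
    h5 = min(hits5, key=lambda h: (h.start, -h.matches))
    hits3 = [h for h in _scan_hits(read.sequence, flank3, p3) if h.start >= h5.end]
    if not hits3:
        return None
    h3 = min(hits3, key=lambda h: (h.start, -h.matches))
    return read.sequence[h5.end : h3.start]


def qc_pipeline(
    pool: ReadPool, adapters: AdapterSet, params: FilterParams | None = None
) -> tuple[ReadPool, FilterReport]:
    """Trim -> flag concatemers -> filter, returning the clean pool and report."""
    params = params or FilterParams()
    trimmed = ReadPool(trim_terminal_adapters(r, adapters, params) for r in pool)
    flag_concatemers(trimmed, adapters, params)
    filtered, report = apply_filters(trimmed, params)
    report.trimmed_5p = sum("trimmed_5p" in r.flags for r in trimmed)
    report.trimmed_3p = sum("trimmed_3p" in r.flags for r in trimmed)
    return filtered, report
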