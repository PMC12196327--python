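"""Adapter trimming and read-level quality filters.

Reads are trimmed at the leftmost position where a prefix of the 3′
adapter aligns to the read with a bounded mismatch fraction, then
filtered: mean Phred < 20, any ambiguous base (N), or length < 15 nt
removes a read.  Removal reasons are tallied with a fixed precedence
(quality, then ambiguous, then length) so reports are deterministic for
reads violating several filters.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator

from .io_formats import Read


@dataclass(slots=True)
class PreprocessReport:
    n_input: int = 0
    n_trimmed: int = 0
    n_removed_quality: int = 0
    n_removed_ambiguous: int = 0
    n_removed_short: int = 0
    n_kept: int = 0

    def __post_init__(self) -> None:
        removed = self.n_removed_quality + self.n_removed_ambiguous + self.n_removed_short
        if self.n_input and self.n_kept != self.n_input - removed:
            raise ValueError("inconsistent preprocess report")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_trimmed": self.n_trimmed,
            "n_removed_quality": self.n_removed_quality,
            "n_removed_ambiguous": self.n_removed_ambiguous,
            "n_removed_short": self.n_removed_short,
            "n_kept": self.n_kept,
        }


def find_adapter_start(
    seq: str, adapter: str, min_overlap: int = 3, max_err_rate: float = 0.1
) -> int | None:
    """Leftmost position where a prefix of *adapter* aligns to the read
    suffix with mismatch fraction ≤ *max_err_rate* and overlap ≥
    *min_overlap*; None if the adapter is not found."""
    L = len(seq)
    for p in range(0, L - min_overlap + 1):
        m = min(len(adapter), L - p)
        budget = int(max_err_rate * m)
        mm = 0
        for a, b in zip(seq[p : p + m], adapter[:m]):
            if a != b:
                mm += 1
                if mm > budget:
                    break
        else:
            return p
    return None


def trim_adapter(
    read: Read, adapter: str, min_overlap: int = 3, max_err_rate: float = 0.1
) -> Read:
    """Truncate the read (and quality) before the adapter start; reads
    without an adapter occurrence pass through unchanged."""
    if not adapter:
        raise ValueError("adapter must be non-empty")
    p = find_adapter_start(read.seq, adapter, min_overlap, max_err_rate)
    if p is None or p == len(read.seq):
        return read
    if p == 0:
        # adapter-only read: keep a 0-length read out of the stream by
        # returning a 1 nt stub that the length filter will remove
        return replace(read, seq=read.seq[:1], qual=read.qual[:1])
    return replace(read, seq=read.seq[:p], qual=read.qual[:p])


def trim_reads(
    reads: Iterable[Read], adapter: str, min_overlap: int = 3, max_err_rate: float = 0.1
) -> Iterator[tuple[Read, bool]]:
    """Trim a stream, caching by sequence (libraries are duplicated).
    Yields (trimmed_read, was_trimmed)."""
    cache: dict[str, int | None] = {}
    for read in reads:
        if read.seq in cache:
            p = cache[read.seq]
        else:
            p = find_adapter_start(read.seq, adapter, min_overlap, max_err_rate)
            cache[read.seq] = p
        if p is None or p == len(read.seq):
            yield read, False
        else:
            q = max(p, 1)
            yield replace(read, seq=read.seq[:q], qual=read.qual[:q]), True


def filter_reads(
    reads: Iterable[Read],
    min_len: int = 15,
    min_mean_q: float = 20.0,
    n_trimmed: int = 0,
) -> tuple[list[Read], PreprocessReport]:
    """Apply the three read filters; order of surviving reads preserved.

    A read is removed if its mean Phred quality is strictly below
    *min_mean_q*, if it contains an N, or if it is shorter than
    *min_len* — tallied in that precedence.
    """
    kept: list[Read] = []
    n_input = n_q = n_n = n_s = 0
    mean_cache: dict[str, float] = {}
    for read in reads:
        n_input += 1
        mq = mean_cache.get(read.qual)
        if mq is None:
            mq = read.mean_quality()
            mean_cache[read.qual] = mq
        if mq < min_mean_q:
            n_q += 1
        elif "N" in read.seq:
            n_n += 1
        elif len(read.seq) < min_len:
            n_s += 1
        else:
            kept.append(read)
    report = PreprocessReport(
        n_input=n_input,
        n_trimmed=n_trimmed,
        n_removed_quality=n_q,
        n_removed_ambiguous=n_n,
        n_removed_short=n_s,
        n_kept=len(kept),
    )
    return kept, report


def preprocess_reads(
    reads: Iterable[Read],
    adapter: str,
    min_overlap: int = 3,
    max_err_rate: float = 0.1,
    min_len: int = 15,
    min_mean_q: float = 20.0,
) -> tuple[list[Read], PreprocessReport]:
    """Trim then filter: the full pre-processing stage."""
    trimmed: list[Read] = []
    n_trimmed = 0
    for read, was in trim_reads(reads, adapter, min_overlap, max_err_rate):
        trimmed.append(read)
        n_trimmed += was
    return filter_reads(trimmed, min_len=min_len, min_mean_q=min_mean_q, n_trimmed=n_trimmed)
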