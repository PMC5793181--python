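"""Raw-read preprocessing: 3' adapter trimming, length filtering, tag collapsing.

The collapsed unit of quantification is the :class:`ReadTag` — one distinct
trimmed sequence with its per-sample copy number. Reads shorter than 16 nt
after trimming are discarded. Reads containing N survive trimming and
collapsing unchanged; N is treated as matching no base (a mismatch) both
here and in downstream alignment. Quality scores play no role after
trimming: quantification is driven entirely by sequence and copy number.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

MIN_TAG_LENGTH = 16


@dataclass(frozen=True)
class ReadTag:
    """A unique trimmed read sequence with its copy number in one sample."""

    sequence: str
    copies: int
    sample_id: str = ""

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass
class PreprocessStats:
    sample_id: str
    n_raw: int
    n_adapter_trimmed: int
    n_too_short_discarded: int
    n_usable: int
    n_unique_tags: int

    def validate(self) -> None:
        assert self.n_usable == self.n_raw - self.n_too_short_discarded
        assert self.n_unique_tags <= self.n_usable


def _mismatches(a: str, b: str, allowed: int) -> int:
    """Mismatch count between equal-length strings, early exit past `allowed`.

    N matches nothing, including another N.
    """
    m = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            m += 1
            if m > allowed:
                return m
    return m


def trim_adapter(
    read_sequence: str,
    adapter_sequence: str,
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
) -> str:
    """Remove the 3' adapter from a read.

    Scans candidate adapter start positions left to right; the leftmost
    position where the read suffix matches a prefix of the adapter with a
    mismatch fraction <= ``max_error_rate`` over the overlap wins, and the
    read is truncated there. Overlaps shorter than ``min_overlap`` (partial
    adapter falling off the 3' end) are not considered. No acceptable match
    leaves the read unchanged.
    """
    if not adapter_sequence:
        raise ValueError("adapter_sequence must be non-empty")
    if min_overlap < 3:
        raise ValueError("min_overlap must be >= 3")
    n, m = len(read_sequence), len(adapter_sequence)
    for start in range(0, n - min_overlap + 1):
        overlap = min(m, n - start)
        allowed = int(max_error_rate * overlap)
        if _mismatches(read_sequence[start : start + overlap], adapter_sequence[:overlap], allowed) <= allowed:
            return read_sequence[:start]
    return read_sequence


def filter_by_length(
    reads: Sequence[str], min_length: int = MIN_TAG_LENGTH
) -> tuple[list[str], int]:
    """Retain reads of length >= ``min_length``; return (kept, n_discarded)."""
    kept = [r for r in reads if len(r) >= min_length]
    return kept, len(reads) - len(kept)


def collapse_tags(reads: Iterable[str], sample_id: str = "") -> list[ReadTag]:
    """Collapse reads into unique tags with copy numbers.

    Output is sorted by descending copies then sequence, so collapsing is
    deterministic and independent of input order.
    """
    counts = Counter(reads)
    return [
        ReadTag(sequence=seq, copies=c, sample_id=sample_id)
        for seq, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def qc_summary(
    trimmed_reads: Sequence[str],
    sample_id: str = "",
    raw_reads: Sequence[str] | None = None,
    min_length: int = MIN_TAG_LENGTH,
) -> tuple[PreprocessStats, pd.Series, pd.DataFrame]:
    """Summarize a sample after trimming.

    Returns ``(stats, length_histogram, base_composition)`` where the
    histogram covers usable (post-filter) reads and the composition table
    gives per-position base fractions over usable reads.
    """
    n_raw = len(trimmed_reads)
    usable, n_short = filter_by_length(trimmed_reads, min_length)
    n_trimmed = 0
    if raw_reads is not None:
        n_trimmed = sum(
            1 for raw, t in zip(raw_reads, trimmed_reads) if len(t) < len(raw)
        )
    tags = collapse_tags(usable, sample_id)
    stats = PreprocessStats(
        sample_id=sample_id,
        n_raw=n_raw,
        n_adapter_trimmed=n_trimmed,
        n_too_short_discarded=n_short,
        n_usable=len(usable),
        n_unique_tags=len(tags),
    )
    stats.validate()

    hist = pd.Series(Counter(len(r) for r in usable), dtype=int).sort_index()
    hist.name = "n_reads"

    max_len = max((len(r) for r in usable), default=0)
    comp_counts = {b: [0] * max_len for b in "ACGTN"}
    for r in usable:
        for i, b in enumerate(r):
            comp_counts.setdefault(b, [0] * max_len)[i] += 1
    comp = pd.DataFrame(comp_counts)
    totals = comp.sum(axis=1)
    comp = comp.div(totals.replace(0, 1), axis=0)
    comp.index.name = "position"
    return stats, hist, comp


def preprocess_sample(
    raw_reads: Iterable[str],
    adapter_sequence: str,
    sample_id: str = "",
    min_overlap: int = 5,
    max_error_rate: float = 0.1,
    min_length: int = MIN_TAG_LENGTH,
    _trim_cache: dict[str, str] | None = None,
) -> tuple[list[ReadTag], PreprocessStats]:
    """Trim, length-filter and collapse one sample's reads.

    Identical raw sequences trim identically, so trimming runs once per
    distinct raw sequence (optionally sharing ``_trim_cache`` across
    samples) and copy numbers are carried through the funnel.
    """
    raw_counts = Counter(raw_reads)
    cache = _trim_cache if _trim_cache is not None else {}
    trimmed_counts: Counter[str] = Counter()
    n_raw = 0
    n_trimmed = 0
    for seq, c in raw_counts.items():
        n_raw += c
        t = cache.get(seq)
        if t is None:
            t = trim_adapter(seq, adapter_sequence, min_overlap, max_error_rate)
            cache[seq] = t
        if len(t) < len(seq):
            n_trimmed += c
        trimmed_counts[t] += c

    n_short = sum(c for seq, c in trimmed_counts.items() if len(seq) < min_length)
    usable_counts = {
        seq: c for seq, c in trimmed_counts.items() if len(seq) >= min_length
    }
    tags = [
        ReadTag(sequence=seq, copies=c, sample_id=sample_id)
        for seq, c in sorted(usable_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    stats = PreprocessStats(
        sample_id=sample_id,
        n_raw=n_raw,
        n_adapter_trimmed=n_trimmed,
        n_too_short_discarded=n_short,
        n_usable=n_raw - n_short,
        n_unique_tags=len(tags),
    )
    stats.validate()
    return tags, stats


def tags_to_fasta(tags: Sequence[ReadTag], path) -> None:
    """Write collapsed tags as FASTA with headers ``tag{i}_x{copies}``."""
    with open(path, "w") as handle:
        for i, tag in enumerate(tags, start=1):
            handle.write(f">tag{i}_x{tag.copies}\n{tag.sequence}\n")
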