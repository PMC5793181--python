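"""Independent oracles shared across the test suite.

Everything here is deliberately written against the contract, not the
implementation: exhaustive scans, brute-force recounts, closed forms.
"""

from __future__ import annotations

import numpy as np

from srnascape.simulate import reverse_complement


def _encode(s: str) -> np.ndarray:
    return np.frombuffer(s.encode(), dtype=np.uint8)


def brute_force_align(
    genome: dict[str, str],
    tag: str,
    max_mismatch: int = 1,
    max_nta: int = 3,
    min_aligned: int = 16,
) -> list[tuple]:
    """Exhaustive scan over every position, strand and NTA trim length.

    Returns sorted ``(chrom, position, strand, mismatches, nta, aligned_len)``
    tuples for the best tier: fewest mismatches over the aligned (NTA-
    excluded) portion first, then smallest trim, mirroring the aligner's
    contract by enumeration. Assumes an ACGT-only genome.
    """
    hits = []
    for k in range(max_nta + 1):
        core = tag[: len(tag) - k]
        L = len(core)
        if L < min_aligned:
            break
        ce = _encode(core)
        for chrom, seq in genome.items():
            for strand, s in (("+", seq), ("-", reverse_complement(seq))):
                se = _encode(s)
                if len(se) < L:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(se, L)
                mm = (win != ce).sum(axis=1)
                for p in np.nonzero(mm <= max_mismatch)[0]:
                    gpos = int(p) if strand == "+" else len(s) - (int(p) + L)
                    hits.append((chrom, gpos, strand, int(mm[p]), k, L))
    if not hits:
        return []
    best = min((h[3], h[4]) for h in hits)
    return sorted(h for h in hits if (h[3], h[4]) == best)


def brute_force_trim(
    read: str, adapter: str, min_overlap: int, max_error_rate: float
) -> str:
    """Leftmost acceptable adapter placement by explicit enumeration."""
    best = None
    for start in range(len(read) - min_overlap + 1):
        overlap = min(len(adapter), len(read) - start)
        if overlap < min_overlap:
            continue
        seg = read[start : start + overlap]
        mism = sum(
            1 for a, b in zip(seg, adapter[:overlap]) if a != b or a == "N"
        )
        if mism <= int(max_error_rate * overlap):
            best = start
            break
    return read if best is None else read[:best]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
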