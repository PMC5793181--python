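"""One-mismatch, NTA-aware alignment of collapsed tags to a genome.

The mapping contract mirrors short-read small-RNA practice: a tag aligns
full-length with at most one substitution (no gaps), on either strand.
Because miRNAs frequently carry 1-3 non-templated bases (NTA) on the 3' end,
the aligner retries with the last k = 0..max_nta bases removed, and keeps
the hit tier with the smallest k, then the fewest mismatches at that k.
Ties within the best tier are all reported. The aligned portion must remain
at least 16 nt.

The search is seed-and-verify against a precomputed 8-mer position index:
with at most one substitution, one half of the query is exact (pigeonhole),
so that half's leading 8-mer occurs exactly in the genome; every indexed
occurrence of either half's leading 8-mer is verified over the full query.
N in a tag matches no base (it always counts as a mismatch), and a half
containing N is never the exact half, so seeding on the clean half still
finds every valid placement. An exhaustive position-by-position scan serves
as the independent oracle in the test suite, never here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .simulate import reverse_complement

MIN_ALIGNED_LENGTH = 16
SEED_LENGTH = 8


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    position: int  # 0-based leftmost on the + strand of the reference
    strand: str  # '+' or '-'
    mismatches: int
    nta_length: int
    aligned_length: int


def _seed_index(seq: str) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - SEED_LENGTH + 1):
        index.setdefault(seq[i : i + SEED_LENGTH], []).append(i)
    return index


class GenomeIndex:
    """Forward and reverse-complement sequences with 8-mer seed tables."""

    def __init__(self, genome: dict[str, str]):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self._rc = {c: reverse_complement(s) for c, s in self.genome.items()}
        self._seeds = {
            (c, "+"): _seed_index(s) for c, s in self.genome.items()
        }
        self._seeds.update(
            {(c, "-"): _seed_index(s) for c, s in self._rc.items()}
        )

    def __len__(self):
        return sum(len(s) for s in self.genome.values())


def _count_mismatches(a: str, b: str, allowed: int) -> int:
    m = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            m += 1
            if m > allowed:
                return m
    return m


def _scan_sequence(
    seq: str, seeds: dict[str, list[int]], core: str, max_mismatch: int
) -> list[tuple[int, int]]:
    """All ``(position, n_mismatch)`` placements of ``core`` in ``seq``."""
    L = len(core)
    half = L // 2
    n = len(seq)
    candidates: set[int] = set()
    s1 = core[:SEED_LENGTH]
    if "N" not in s1:
        candidates.update(seeds.get(s1, ()))
    s2 = core[half : half + SEED_LENGTH]
    if "N" not in s2:
        candidates.update(p - half for p in seeds.get(s2, ()))
    hits = []
    for p in candidates:
        if p < 0 or p + L > n:
            continue
        mm = _count_mismatches(seq[p : p + L], core, max_mismatch)
        if mm <= max_mismatch:
            hits.append((p, mm))
    return hits


def align_tag(
    tag_sequence: str,
    index: GenomeIndex,
    max_mismatch: int = 1,
    max_nta: int = 3,
    min_aligned: int = MIN_ALIGNED_LENGTH,
) -> list[AlignmentHit]:
    """Align one tag, returning all hits of the best (mismatch, trim) tier.

    For k = 0..max_nta the tag minus its last k bases is aligned full-length
    on both strands. Because NTA bases are excluded from mismatch counting,
    the best tier minimizes mismatches over the aligned portion first and
    the trimmed length second: a tag with two genuinely non-templated 3'
    bases is reported as (0 mismatches, k=2), not (1 mismatch, k=1). The
    search still walks k upward and stops as soon as a perfect alignment is
    found, since a later (larger-k) hit can never beat it. Results are
    sorted by (chrom, position, strand) for determinism.
    """
    if len(tag_sequence) < min_aligned:
        raise ValueError(f"tag shorter than {min_aligned} nt: {len(tag_sequence)}")
    if max_mismatch > 1:
        raise ValueError("seeded search supports at most one mismatch")
    tag = tag_sequence.upper()
    found: list[AlignmentHit] = []
    for k in range(0, max_nta + 1):
        core_len = len(tag) - k
        if core_len < min_aligned:
            break
        core = tag[:core_len]
        for chrom, seq in index.genome.items():
            for pos, mm in _scan_sequence(
                seq, index._seeds[(chrom, "+")], core, max_mismatch
            ):
                found.append(AlignmentHit(chrom, pos, "+", mm, k, core_len))
            rc = index._rc[chrom]
            n = len(rc)
            for pos, mm in _scan_sequence(
                rc, index._seeds[(chrom, "-")], core, max_mismatch
            ):
                found.append(
                    AlignmentHit(chrom, n - (pos + core_len), "-", mm, k, core_len)
                )
        if any(h.mismatches == 0 for h in found):
            break
    if not found:
        return []
    best = min((h.mismatches, h.nta_length) for h in found)
    tier = [h for h in found if (h.mismatches, h.nta_length) == best]
    tier.sort(key=lambda h: (h.chrom, h.position, h.strand))
    return tier
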