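"""Feature assignment, isomiR calling, and per-category quantification.

Aligned tags are matched to annotated sRNA loci on the same strand when the
feature covers at least ``overlap_fraction`` of the aligned span. When a tag
touches loci of several categories, only the highest-priority category is
kept (miRNA > tRNA > snoRNA > snRNA > yRNA > 7SK > 7SL) so category totals
are disjoint and reproducible; ties within the winning category split the
tag's weight equally. miRNA-assigned tags are classified as canonical
(5' offset 0) or isomiR (+1 / +2 nt downstream of the annotated 5' start,
measured on the feature's biological 5' end for minus-strand loci); isomiRs
are quantified as separate features of species "isomiR".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

if TYPE_CHECKING:  # pragma: no cover
    from .align import AlignmentHit
    from .preprocess import ReadTag

#: The seven annotation categories, in assignment priority order.
CATEGORY_PRIORITY = ("miRNA", "tRNA", "snoRNA", "snRNA", "yRNA", "7SK", "7SL")
CATEGORIES = CATEGORY_PRIORITY

#: Quantified species: isomiRs are reported separately from canonical miRNA.
SPECIES = ("miRNA", "isomiR", "tRNA", "snRNA", "snoRNA", "yRNA", "7SK", "7SL")

UNANNOTATED = "unannotated"

ISOMIR_CLASSES = {0: "canonical", 1: "isomiR_plus1", 2: "isomiR_plus2"}


@dataclass(frozen=True)
class FeatureRecord:
    """One annotated sRNA locus (0-based half-open coordinates)."""

    feature_id: str
    category: str
    chrom: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if (self.anticodon is not None) != (self.category == "tRNA"):
            raise ValueError("anticodon present iff category is tRNA")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class Assignment:
    """One tag-to-feature attribution with its weight share."""

    feature_id: str  # or "unannotated"
    category: str  # category name or "unannotated"
    offset_5p: int
    isomir_class: str  # canonical / isomiR_plus1 / isomiR_plus2 / not_applicable
    weight: float
    aligned_length: int = 0
    nta_length: int = 0


class FeatureIndex:
    """Strand-aware interval index over features, per chromosome."""

    def __init__(self, features: Iterable[FeatureRecord]):
        self.features = list(features)
        self.by_id = {f.feature_id: f for f in self.features}
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def overlapping(self, chrom: str, start: int, end: int) -> list[FeatureRecord]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(start, end)]


def _offset_5p(hit: "AlignmentHit", feature: FeatureRecord) -> int:
    """Tag 5' position relative to the feature's biological 5' end."""
    if feature.strand == "+":
        return hit.position - feature.start
    return feature.end - (hit.position + hit.aligned_length)


def call_isomir(assignment: Assignment) -> str:
    """Classify a miRNA assignment's 5' offset.

    Offset 0 is the canonical 5' end; +1 and +2 are the recognized isomiR
    classes; any other offset is labeled ``not_applicable`` (the tag still
    counts as evidence for the locus unless strict mode discards it).
    """
    if assignment.category != "miRNA":
        raise ValueError("isomiR calling applies to miRNA assignments only")
    return ISOMIR_CLASSES.get(assignment.offset_5p, "not_applicable")


def assign_tag(
    hits: Sequence["AlignmentHit"],
    feature_index: FeatureIndex,
    overlap_fraction: float = 0.8,
) -> list[Assignment]:
    """Assign one tag's alignment hits to features.

    Candidate (hit, feature) pairs require same strand and an overlap of at
    least ``overlap_fraction`` of the aligned span. Only candidates of the
    highest-priority category survive; weight is split equally among the
    surviving distinct features. No candidate at all yields a single
    ``unannotated`` assignment of weight 1.
    """
    candidates: dict[str, tuple["AlignmentHit", FeatureRecord]] = {}
    for hit in hits:
        span_start, span_end = hit.position, hit.position + hit.aligned_length
        for f in feature_index.overlapping(hit.chrom, span_start, span_end):
            if f.strand != hit.strand:
                continue
            ov = min(span_end, f.end) - max(span_start, f.start)
            if ov < overlap_fraction * hit.aligned_length:
                continue
            # keep the first hit seen per feature; hits are a best tier, so
            # any of them is an equally valid placement
            candidates.setdefault(f.feature_id, (hit, f))
    if not candidates:
        return [
            Assignment(
                feature_id=UNANNOTATED,
                category=UNANNOTATED,
                offset_5p=0,
                isomir_class="not_applicable",
                weight=1.0,
                aligned_length=hits[0].aligned_length if hits else 0,
                nta_length=hits[0].nta_length if hits else 0,
            )
        ]
    best_cat = min(
        (f.category for _h, f in candidates.values()),
        key=CATEGORY_PRIORITY.index,
    )
    survivors = [
        (h, f) for h, f in candidates.values() if f.category == best_cat
    ]
    survivors.sort(key=lambda hf: hf[1].feature_id)
    w = 1.0 / len(survivors)
    out = []
    for hit, f in survivors:
        off = _offset_5p(hit, f)
        a = Assignment(
            feature_id=f.feature_id,
            category=f.category,
            offset_5p=off,
            isomir_class="not_applicable",
            weight=w,
            aligned_length=hit.aligned_length,
            nta_length=hit.nta_length,
        )
        if f.category == "miRNA":
            a = Assignment(
                feature_id=a.feature_id,
                category=a.category,
                offset_5p=a.offset_5p,
                isomir_class=call_isomir(a),
                weight=a.weight,
                aligned_length=a.aligned_length,
                nta_length=a.nta_length,
            )
        out.append(a)
    return out


@dataclass
class QuantResult:
    """Per-species count matrices plus per-sample accounting.

    ``matrices`` maps each species in :data:`SPECIES` to a features x
    samples matrix of copy-weighted counts. isomiR features are named
    ``{mirna_id}|+1`` / ``{mirna_id}|+2``. ``unannotated`` and ``unmapped``
    give per-sample copy totals; ``excluded_offsets`` counts miRNA-locus
    copies at unrecognized 5' offsets dropped under strict mode.
    """

    matrices: dict[str, pd.DataFrame]
    unannotated: pd.Series
    unmapped: pd.Series
    excluded_offsets: pd.Series
    audit: pd.DataFrame = field(default_factory=pd.DataFrame)

    def mapped_total(self) -> pd.Series:
        total = sum(m.sum(axis=0) for m in self.matrices.values())
        return total + self.unannotated + self.excluded_offsets

    def species_totals(self) -> pd.DataFrame:
        return pd.DataFrame({sp: m.sum(axis=0) for sp, m in self.matrices.items()}).T


def quantify(
    assignments_by_sequence: dict[str, list[Assignment]],
    tags: Iterable["ReadTag"],
    sample_ids: Sequence[str],
    strict_5p_offsets: bool = False,
) -> QuantResult:
    """Accumulate copy-weighted assignment weights into count matrices.

    ``assignments_by_sequence`` maps each distinct tag sequence to its
    assignments (empty list = no alignment hit). Tags whose sequence is
    missing from the map raise. With ``strict_5p_offsets`` miRNA-locus tags
    at offsets other than 0/+1/+2 are excluded from the miRNA matrix (and
    tallied) instead of counting as canonical-locus evidence.
    """
    sample_pos = {s: j for j, s in enumerate(sample_ids)}
    acc: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in SPECIES}
    unannotated = np.zeros(len(sample_ids))
    unmapped = np.zeros(len(sample_ids))
    excluded = np.zeros(len(sample_ids))

    def add(species: str, fid: str, j: int, value: float):
        row = acc[species].get(fid)
        if row is None:
            row = acc[species][fid] = np.zeros(len(sample_ids))
        row[j] += value

    for tag in tags:
        if tag.sample_id not in sample_pos:
            raise ValueError(f"sample {tag.sample_id!r} not in sample_ids")
        j = sample_pos[tag.sample_id]
        assignments = assignments_by_sequence[tag.sequence]
        if not assignments:
            unmapped[j] += tag.copies
            continue
        for a in assignments:
            value = tag.copies * a.weight
            if a.feature_id == UNANNOTATED:
                unannotated[j] += value
            elif a.category == "miRNA":
                if a.isomir_class in ("isomiR_plus1", "isomiR_plus2"):
                    suffix = "+1" if a.isomir_class == "isomiR_plus1" else "+2"
                    add("isomiR", f"{a.feature_id}|{suffix}", j, value)
                elif a.isomir_class == "canonical" or not strict_5p_offsets:
                    add("miRNA", a.feature_id, j, value)
                else:
                    excluded[j] += value
            else:
                add(a.category, a.feature_id, j, value)

    matrices = {}
    for sp in SPECIES:
        rows = acc[sp]
        if rows:
            matrices[sp] = pd.DataFrame(
                {fid: rows[fid] for fid in sorted(rows)}, index=list(sample_ids)
            ).T
        else:
            matrices[sp] = pd.DataFrame(
                np.zeros((0, len(sample_ids))), columns=list(sample_ids)
            )
    return QuantResult(
        matrices=matrices,
        unannotated=pd.Series(unannotated, index=list(sample_ids)),
        unmapped=pd.Series(unmapped, index=list(sample_ids)),
        excluded_offsets=pd.Series(excluded, index=list(sample_ids)),
    )


def detection_curve(
    matrix: pd.DataFrame, thresholds: Sequence[int] = (1, 5, 10, 15, 20)
) -> pd.DataFrame:
    """Per-sample number of features detected at each read-count threshold.

    Rows are thresholds, columns samples; values are counts of features with
    count >= threshold, necessarily non-increasing down the rows.
    """
    thresholds = list(thresholds)
    if any(t <= 0 for t in thresholds) or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ):
        raise ValueError("thresholds must be strictly increasing positive integers")
    data = {t: (matrix >= t).sum(axis=0) for t in thresholds}
    out = pd.DataFrame(data).T
    out.index.name = "threshold"
    return out


def detection_curve_by_subtype(
    curve: pd.DataFrame, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Mean detection curve per subtype (columns) from a per-sample curve."""
    subtype = metadata.set_index("sample_id")["subtype"]
    return curve.T.groupby(subtype).mean().T


def median_expression_profile(matrix: pd.DataFrame) -> pd.Series:
    """Features ranked by median count across samples, descending.

    Even sample counts use the mean of the central pair; ties in the median
    are broken lexicographically by feature id.
    """
    if matrix.shape[1] < 1:
        raise ValueError("at least one sample required")
    med = matrix.median(axis=1)
    order = sorted(med.index, key=lambda fid: (-med[fid], fid))
    out = med.loc[order]
    out.name = "median_count"
    return out
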