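"""tRNA fragment analysis: anticodon-family abundance and positional coverage.

tRNA-derived reads are quantified at the anticodon-family level (all loci
sharing an amino acid + anticodon label, e.g. ``Val_CAC``), both as counts
and as per-sample fractions of all tRNA reads. Positional coverage pools
per-locus read depth 5'->3' into 100 percentile bins per family so loci of
different lengths are comparable, and summarizes 5'-half enrichment as the
fraction of (unbinned) depth falling in the first half of the parent tRNA —
the pattern in which sequenced fragments overwhelmingly favor the 5' half.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .annotate import FeatureRecord

N_COVERAGE_BINS = 100


def aggregate_anticodon(
    trna_matrix: pd.DataFrame, features: list[FeatureRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate a tRNA count matrix to anticodon families.

    Returns ``(counts, fractions)``, both family x sample; fractions are of
    each sample's total tRNA count and sum to 1 wherever the total is > 0.
    """
    by_id = {f.feature_id: f for f in features}
    families = {}
    for fid in trna_matrix.index:
        f = by_id.get(fid)
        if f is None or f.category != "tRNA":
            raise ValueError(f"{fid!r} is not an annotated tRNA feature")
        if not f.anticodon:
            raise ValueError(f"tRNA feature {fid!r} lacks an anticodon label")
        families[fid] = f.anticodon
    fam = pd.Series(families)
    counts = trna_matrix.groupby(fam).sum().sort_index()
    totals = counts.sum(axis=0)
    fractions = counts.div(totals.where(totals > 0, 1.0), axis=1)
    return counts, fractions


@dataclass
class CoverageProfile:
    """Pooled positional depth for one anticodon family."""

    family: str
    binned: np.ndarray  # length N_COVERAGE_BINS, percentile bins 5'->3'
    total_depth: float
    five_prime_half_fraction: float
    n_excluded: int = 0


@dataclass
class CoverageRead:
    """One tRNA-assigned tag expanded to coverage terms."""

    feature_id: str
    offset_5p: int
    aligned_length: int
    depth: float  # copies x weight

    sample_id: str = ""


def positional_coverage(
    reads: list[CoverageRead], features: list[FeatureRecord]
) -> dict[str, CoverageProfile]:
    """Pool tRNA read depth into per-family percentile coverage profiles.

    Each read adds ``depth`` to feature positions
    ``[offset_5p, offset_5p + aligned_length)`` clipped to ``[0, L)``.
    Reads whose offset falls outside ``[-2, L)`` are skipped and tallied in
    the family's ``n_excluded``. The 5'-half fraction is computed from
    unbinned depth at positions ``< L/2``.
    """
    by_id = {f.feature_id: f for f in features}
    depth_by_locus: dict[str, np.ndarray] = {}
    excluded: dict[str, int] = {}
    for r in reads:
        f = by_id[r.feature_id]
        if f.category != "tRNA":
            raise ValueError(f"{r.feature_id!r} is not a tRNA feature")
        L = f.length
        if not (-2 <= r.offset_5p < L):
            excluded[f.anticodon] = excluded.get(f.anticodon, 0) + 1
            continue
        arr = depth_by_locus.get(r.feature_id)
        if arr is None:
            arr = depth_by_locus[r.feature_id] = np.zeros(L)
        lo = max(0, r.offset_5p)
        hi = min(L, r.offset_5p + r.aligned_length)
        if hi > lo:
            arr[lo:hi] += r.depth

    profiles: dict[str, CoverageProfile] = {}
    fam_loci: dict[str, list[str]] = {}
    for f in features:
        if f.category == "tRNA":
            fam_loci.setdefault(f.anticodon, []).append(f.feature_id)
    for fam in sorted(fam_loci):
        binned = np.zeros(N_COVERAGE_BINS)
        total = 0.0
        first_half = 0.0
        for fid in fam_loci[fam]:
            arr = depth_by_locus.get(fid)
            if arr is None:
                continue
            L = len(arr)
            pos = np.arange(L)
            bins = np.minimum((pos * N_COVERAGE_BINS) // L, N_COVERAGE_BINS - 1)
            np.add.at(binned, bins, arr)
            total += arr.sum()
            first_half += arr[pos < L / 2].sum()
        profiles[fam] = CoverageProfile(
            family=fam,
            binned=binned,
            total_depth=total,
            five_prime_half_fraction=(first_half / total) if total > 0 else 0.0,
            n_excluded=excluded.get(fam, 0),
        )
    return profiles


def pooled_five_prime_half_fraction(profiles: dict[str, CoverageProfile]) -> float:
    """Depth-weighted 5'-half fraction over all families."""
    total = sum(p.total_depth for p in profiles.values())
    if total == 0:
        return 0.0
    return (
        sum(p.five_prime_half_fraction * p.total_depth for p in profiles.values())
        / total
    )


def anticodon_differential(
    fractions: pd.DataFrame,
    metadata: pd.DataFrame,
    group: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-vs-rest comparison of anticodon-family fractions.

    Rank-based: per family, a two-sided Wilcoxon rank-sum test of the
    ``group`` samples' fractions against all others, with the effect
    reported as the difference of group mean fractions and BH FDR across
    families. Fractions rather than raw counts are compared so the result
    is library-size free.
    """
    subtype = metadata.set_index("sample_id")["subtype"]
    cols = [c for c in fractions.columns if c in subtype.index]
    in_group = [c for c in cols if subtype[c] == group]
    out_group = [c for c in cols if subtype[c] != group]
    if len(in_group) < 2 or len(out_group) < 2:
        raise ValueError(
            f"insufficient replication for {group!r} vs others: "
            f"{len(in_group)} vs {len(out_group)} samples"
        )
    a = fractions[in_group].to_numpy(dtype=float)
    b = fractions[out_group].to_numpy(dtype=float)
    from .differential import rank_sum_p

    p = rank_sum_p(a, b)
    effect = a.mean(axis=1) - b.mean(axis=1)
    fdr = multipletests(p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "family": fractions.index,
            "comparison": f"{group} vs others",
            "effect": effect,
            "p_value": p,
            "fdr": fdr,
            "significant": fdr < alpha,
        }
    ).set_index("family")
    return out.sort_values(["p_value", "family"])
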