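"""Subtype differential expression via rank aggregation.

Counts are normalized to CPM and log2(CPM+1)-transformed. For each feature,
three criteria are computed on the two groups being compared: a two-sided
Wilcoxon rank-sum p-value, a two-sided Welch t-test p-value, and the log2
fold change of group mean CPM (with pseudocount 1). Features are ranked by
each criterion and the aggregate rank is the sum of the three — a rank
aggregation over complementary evidence, in the spirit of consensus
differential-expression callers that sum per-method ranks. FDR is
Benjamini-Hochberg over the rank-sum p-values; a feature is significant
when FDR < alpha and |log2FC| >= lfc_min.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

SUBTYPES = ("BL1", "BL2", "M", "LAR")
OTHERS = "others"


def normalize_cpm(
    matrix: pd.DataFrame, library_sizes: pd.Series | None = None
) -> pd.DataFrame:
    """Counts-per-million normalization.

    ``library_sizes`` defaults to the matrix's own column totals; when the
    matrix is one species' slice of a larger quantification, pass the
    per-sample totals over all species so sparse species stay comparable.
    """
    lib = matrix.sum(axis=0) if library_sizes is None else library_sizes[matrix.columns]
    zero = lib[lib <= 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return matrix * 1e6 / lib


def log2_cpm(
    matrix: pd.DataFrame,
    pseudocount: float = 1.0,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    return np.log2(normalize_cpm(matrix, library_sizes) + pseudocount)


def rank_sum_p(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Wilcoxon rank-sum p-values.

    Rows without ties use the exact null distribution (scipy's vectorized
    "auto" mode would silently switch every row to the normal approximation
    as soon as any single row carries ties); rows with ties use the
    tie-corrected normal approximation. Fully constant rows, where the
    statistic is undefined, get p = 1.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    pooled_sorted = np.sort(np.concatenate([a, b], axis=1), axis=1)
    has_ties = (pooled_sorted[:, 1:] == pooled_sorted[:, :-1]).any(axis=1)
    p = np.ones(a.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        if (~has_ties).any():
            res = stats.mannwhitneyu(
                a[~has_ties], b[~has_ties], axis=1,
                alternative="two-sided", method="exact",
            )
            p[~has_ties] = res.pvalue
        if has_ties.any():
            res = stats.mannwhitneyu(
                a[has_ties], b[has_ties], axis=1,
                alternative="two-sided", method="asymptotic",
            )
            p[has_ties] = np.where(np.isnan(res.pvalue), 1.0, res.pvalue)
    return np.minimum(p, 1.0)


def _groups(metadata: pd.DataFrame, group_a: str, group_b: str, columns) -> tuple[list, list]:
    subtype = metadata.set_index("sample_id")["subtype"]
    cols = [c for c in columns if c in subtype.index]
    a = [c for c in cols if subtype[c] == group_a]
    if group_b == OTHERS:
        b = [c for c in cols if subtype[c] != group_a]
    else:
        b = [c for c in cols if subtype[c] == group_b]
    return a, b


def de_test(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str = OTHERS,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    species: str | None = None,
    library_sizes: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential expression of ``group_a`` vs ``group_b`` (or "others").

    ``matrix`` holds raw counts (features x samples); normalization happens
    inside. Results are sorted by aggregate rank, ties broken by feature id.
    """
    cols_a, cols_b = _groups(metadata, group_a, group_b, matrix.columns)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError(
            f"insufficient replication for {group_a!r} vs {group_b!r}: "
            f"{len(cols_a)} vs {len(cols_b)} samples"
        )
    cpm = normalize_cpm(matrix, library_sizes)
    log_a = np.log2(cpm[cols_a].to_numpy(dtype=float) + 1.0)
    log_b = np.log2(cpm[cols_b].to_numpy(dtype=float) + 1.0)

    p_rs = rank_sum_p(log_a, log_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        tt = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
        p_t = np.where(np.isnan(tt.pvalue), 1.0, tt.pvalue)

    lfc = np.log2(cpm[cols_a].mean(axis=1).to_numpy() + 1.0) - np.log2(
        cpm[cols_b].mean(axis=1).to_numpy() + 1.0
    )

    rank_rs = stats.rankdata(p_rs, method="min")
    rank_t = stats.rankdata(p_t, method="min")
    rank_lfc = stats.rankdata(-np.abs(lfc), method="min")
    aggregate = (rank_rs + rank_t + rank_lfc).astype(int)

    fdr = multipletests(p_rs, method="fdr_bh")[1]
    label = f"{group_a} vs {group_b}"
    out = pd.DataFrame(
        {
            "feature_id": matrix.index,
            "category": species if species is not None else "",
            "comparison": label,
            "log2_fold_change": lfc,
            "p_value": p_rs,
            "p_value_welch": p_t,
            "fdr": fdr,
            "aggregate_rank": aggregate,
            "significant": (fdr < alpha) & (np.abs(lfc) >= lfc_min),
        }
    )
    return out.sort_values(["aggregate_rank", "feature_id"]).reset_index(drop=True)


def de_test_all_species(
    matrices: dict[str, pd.DataFrame],
    metadata: pd.DataFrame,
    group_a: str,
    group_b: str = OTHERS,
    min_total: float = 1.0,
    **kwargs,
) -> pd.DataFrame:
    """Run :func:`de_test` per species matrix and concatenate.

    CPM is computed against per-sample totals pooled over all species, so a
    sparse species (or one absent from a sample) never divides by zero and
    species matrices stay on one comparable scale. Features whose total
    count over all samples is below ``min_total`` are dropped before
    testing (they carry no rank information).
    """
    library_sizes = sum(m.sum(axis=0) for m in matrices.values())
    parts = []
    for sp, m in matrices.items():
        m = m[m.sum(axis=1) >= min_total]
        if m.shape[0] == 0:
            continue
        parts.append(
            de_test(
                m, metadata, group_a, group_b,
                species=sp, library_sizes=library_sizes, **kwargs,
            )
        )
    if not parts:
        return pd.DataFrame(
            columns=[
                "feature_id", "category", "comparison", "log2_fold_change",
                "p_value", "p_value_welch", "fdr", "aggregate_rank", "significant",
            ]
        )
    return pd.concat(parts, ignore_index=True)


def pairwise_summary(results: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Significant-feature counts per species for all six subtype pairs.

    ``results`` maps comparison labels (e.g. ``"M vs LAR"``) to DE tables
    with ``category`` and ``significant`` columns. Returns a 6 x 8 count
    table (plus Total row/column) over the eight quantified species.
    """
    from .annotate import SPECIES

    expected = {
        f"{a} vs {b}" for a, b in combinations(SUBTYPES, 2)
    } | {f"{b} vs {a}" for a, b in combinations(SUBTYPES, 2)}
    labels = list(results)
    missing = 6 - len({tuple(sorted(l.split(" vs "))) for l in labels})
    if missing or any(l not in expected for l in labels):
        raise ValueError("results must cover all 6 unordered subtype pairs")
    rows = {}
    for label, df in results.items():
        sig = df.loc[df["significant"].astype(bool)]
        rows[label] = {
            sp: int((sig["category"] == sp).sum()) for sp in SPECIES
        }
    table = pd.DataFrame(rows).T[list(SPECIES)]
    table["Total"] = table.sum(axis=1)
    table.loc["Total"] = table.sum(axis=0)
    table.index.name = "comparison"
    return table


def exclusive_sets(
    one_vs_rest: dict[str, pd.DataFrame],
) -> tuple[dict[str, set[str]], pd.DataFrame]:
    """Features significant in exactly one subtype's one-vs-rest comparison.

    A feature is exclusive to subtype S iff it is significant in "S vs
    others" and in no other subtype's one-vs-rest test; the resulting sets
    are pairwise disjoint by construction. Also returns a subtype x species
    count table of the exclusive features.
    """
    from .annotate import SPECIES

    if set(one_vs_rest) != set(SUBTYPES):
        raise ValueError("one-vs-rest results required for all four subtypes")
    sig = {
        st: set(df.loc[df["significant"].astype(bool), "feature_id"])
        for st, df in one_vs_rest.items()
    }
    sets = {}
    for st in SUBTYPES:
        others = set().union(*(sig[o] for o in SUBTYPES if o != st))
        sets[st] = sig[st] - others
    counts = {}
    for st in SUBTYPES:
        df = one_vs_rest[st]
        excl = df[df["feature_id"].isin(sets[st])]
        counts[f"{st} vs others"] = {
            sp: int((excl["category"] == sp).sum()) for sp in SPECIES
        }
    table = pd.DataFrame(counts).T[list(SPECIES)]
    table["Total"] = table.sum(axis=1)
    table.index.name = "comparison"
    return sets, table
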