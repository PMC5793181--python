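"""sRNA-mRNA Spearman correlation networks and directional-bias profiling.

All correlations are Spearman's rank correlation (robust to outliers and to
monotone scale differences between platforms). Expression enters as
log2(CPM+1); the rank transform makes the log immaterial to rho but CPM
removes depth-driven tie structure. For small n the p-value is computed by
permutation of the rank vector; otherwise by the usual t approximation with
n-2 degrees of freedom.
"""

from __future__ import annotations

from itertools import permutations
from math import factorial

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .differential import log2_cpm

PERMUTATION_CAP = 10_000


def _rho_of_ranks(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx * rx).sum() * (ry * ry).sum())
    if denom == 0:
        raise ValueError("constant vector: Spearman correlation undefined")
    return float((rx * ry).sum() / denom)


def _t_approx_p(rho: float, n: int) -> float:
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def spearman(x, y, seed: int = 0) -> tuple[float, float]:
    """Spearman rho with mid-ranks for ties, plus a two-sided p-value.

    For n >= 10 the p-value uses the t approximation with n-2 df. For
    n < 10 it is a permutation p over all n! orderings of one rank vector,
    falling back to 10,000 sampled permutations when n! exceeds that cap.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 observations")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = _rho_of_ranks(rx, ry)
    if n >= 10:
        return rho, _t_approx_p(rho, n)
    tol = 1e-12
    if factorial(n) <= PERMUTATION_CAP:
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(_rho_of_ranks(rx, np.array(perm))) >= abs(rho) - tol:
                count += 1
        return rho, count / total
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(PERMUTATION_CAP):
        if abs(_rho_of_ranks(rx, rng.permutation(ry))) >= abs(rho) - tol:
            count += 1
    return rho, count / PERMUTATION_CAP


def correlate_matrices(
    srna_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    min_samples: int = 8,
    categories: dict[str, str] | None = None,
    normalize: str = "cpm",
) -> pd.DataFrame:
    """All-pairs Spearman correlation between two count matrices.

    Matrices are features x samples; only shared sample columns are used
    (at least ``min_samples`` required). With ``normalize="cpm"`` (the
    default for count data) values enter as log2(CPM+1); ``"none"`` uses
    values as given, for matrices that are already depth-normalized. Rows
    that are all zero or constant are dropped (they have no rank
    information) and counted in the returned frame's
    ``attrs['n_dropped']``. BH q-values are computed across all pairs
    within each sRNA category (one category, "sRNA", when ``categories``
    is not given).
    """
    if normalize not in ("cpm", "none"):
        raise ValueError("normalize must be 'cpm' or 'none'")
    shared = [c for c in srna_matrix.columns if c in set(mrna_matrix.columns)]
    n = len(shared)
    if n < min_samples:
        raise ValueError(
            f"only {n} shared samples; at least {min_samples} required"
        )
    dropped = 0

    def prep(mat: pd.DataFrame) -> pd.DataFrame:
        nonlocal dropped
        m = mat[shared]
        nonzero = m.sum(axis=1) > 0
        dropped += int((~nonzero).sum())
        m = m[nonzero]
        if normalize == "cpm":
            m = np.log2(m * 1e6 / m.sum(axis=0).where(lambda s: s > 0, 1.0) + 1.0)
        const = m.nunique(axis=1) <= 1
        dropped += int(const.sum())
        return m[~const]

    s = prep(srna_matrix)
    g = prep(mrna_matrix)
    rs = stats.rankdata(s.to_numpy(), axis=1)
    rg = stats.rankdata(g.to_numpy(), axis=1)
    rs = rs - rs.mean(axis=1, keepdims=True)
    rg = rg - rg.mean(axis=1, keepdims=True)
    rs /= np.linalg.norm(rs, axis=1, keepdims=True)
    rg /= np.linalg.norm(rg, axis=1, keepdims=True)
    rho = np.clip(rs @ rg.T, -1.0, 1.0)

    if n >= 10:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho * rho, 0.0))
        p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
        p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    else:
        p = np.empty_like(rho)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                p[i, j] = spearman(rs[i], rg[j])[1]

    srna_ids = np.repeat(s.index.to_numpy(), len(g))
    mrna_ids = np.tile(g.index.to_numpy(), len(s))
    flat_rho = rho.ravel()
    out = pd.DataFrame(
        {
            "srna_id": srna_ids,
            "mrna_id": mrna_ids,
            "rho": flat_rho,
            "p_value": p.ravel(),
            "n_samples": n,
            "sign": np.where(flat_rho > 0, "positive", np.where(flat_rho < 0, "negative", "zero")),
            "category": [
                (categories or {}).get(sid, "sRNA") for sid in srna_ids
            ],
        }
    )
    out["q_value"] = np.nan
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "q_value"] = multipletests(
            out.loc[idx, "p_value"], method="fdr_bh"
        )[1]
    out.attrs["n_dropped"] = dropped
    return out


def direction_bias(records: pd.DataFrame, bin_width: float = 0.1) -> pd.DataFrame:
    """Positive/negative correlation counts by |rho| bin.

    Bins are [0, w), [w, 2w), ..., with the last bin closed at 1.0.
    Zero-rho records carry no direction and are excluded from both counts.
    ``fraction_positive`` is NaN for empty bins.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    nbins = int(round(1.0 / bin_width))
    nz = records[records["rho"] != 0]
    # 1e-9 guards float quotients like 0.6/0.1 = 5.999...
    bins = np.minimum(
        np.floor(np.abs(nz["rho"].to_numpy()) / bin_width + 1e-9).astype(int),
        nbins - 1,
    )
    pos = nz["rho"].to_numpy() > 0
    n_pos = np.bincount(bins[pos], minlength=nbins)
    n_neg = np.bincount(bins[~pos], minlength=nbins)
    denom = n_pos + n_neg
    with np.errstate(invalid="ignore"):
        frac = np.where(denom > 0, n_pos / np.maximum(denom, 1), np.nan)
    return pd.DataFrame(
        {
            "bin_low": np.arange(nbins) * bin_width,
            "bin_high": np.minimum((np.arange(nbins) + 1) * bin_width, 1.0),
            "n_positive": n_pos,
            "n_negative": n_neg,
            "fraction_positive": frac,
        }
    )


def _passing(records: pd.DataFrame, rho_min: float, q_max: float) -> pd.DataFrame:
    return records[
        (records["rho"].abs() >= rho_min) & (records["q_value"] <= q_max)
    ]


def gene_class_counts(
    records: pd.DataFrame,
    gene_classes: pd.DataFrame,
    rho_min: float = 0.5,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Per listed gene: distinct sRNAs correlated negatively / positively.

    Only correlations with |rho| >= rho_min and q <= q_max count. Genes in
    the class list but absent from the records get zero counts and
    ``in_records = False``.
    """
    passing = _passing(records, rho_min, q_max)
    seen = set(records["mrna_id"])
    rows = []
    for gene_id, cls in gene_classes[["gene_id", "class"]].itertuples(index=False):
        sub = passing[passing["mrna_id"] == gene_id]
        rows.append(
            {
                "gene_id": gene_id,
                "class": cls,
                "n_negative_mirnas": sub.loc[sub["rho"] < 0, "srna_id"].nunique(),
                "n_positive_mirnas": sub.loc[sub["rho"] > 0, "srna_id"].nunique(),
                "in_records": gene_id in seen,
            }
        )
    return pd.DataFrame(rows)


def subtype_target_table(
    one_vs_rest: dict[str, pd.DataFrame],
    records: pd.DataFrame,
    gene_classes: pd.DataFrame,
    rho_min: float = 0.5,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Subtype-aware miRNA / target-gene relations.

    For each subtype S, miRNAs significantly up in "S vs others" are paired
    with class-listed genes they correlate negatively with (relation
    ``decreased_target_of_increased_miRNA``); miRNAs significantly down are
    paired the same way (``increased_target_of_decreased_miRNA``). Both
    directions are emitted with full provenance so either reading of a
    per-subtype target table can be reconstructed.
    """
    passing = _passing(records, rho_min, q_max)
    neg = passing[passing["rho"] < 0]
    classes = gene_classes.set_index("gene_id")["class"]
    rows = []
    for subtype in sorted(one_vs_rest):
        df = one_vs_rest[subtype]
        sig = df[df["significant"]]
        up = set(sig.loc[sig["log2_fold_change"] > 0, "feature_id"])
        down = set(sig.loc[sig["log2_fold_change"] < 0, "feature_id"])
        lfc = df.set_index("feature_id")["log2_fold_change"]
        for mirnas, relation in (
            (up, "decreased_target_of_increased_miRNA"),
            (down, "increased_target_of_decreased_miRNA"),
        ):
            sub = neg[neg["srna_id"].isin(mirnas) & neg["mrna_id"].isin(classes.index)]
            for r in sub.itertuples(index=False):
                rows.append(
                    {
                        "subtype": subtype,
                        "gene_class": classes[r.mrna_id],
                        "gene_id": r.mrna_id,
                        "mirna_id": r.srna_id,
                        "relation": relation,
                        "rho": r.rho,
                        "q_value": r.q_value,
                        "mirna_log2fc": lfc.get(r.srna_id, np.nan),
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=[
            "subtype", "gene_class", "gene_id", "mirna_id",
            "relation", "rho", "q_value", "mirna_log2fc",
        ],
    )
    return out.sort_values(
        ["subtype", "gene_class", "gene_id", "mirna_id"]
    ).reset_index(drop=True)


def export_network(
    records: pd.DataFrame,
    gene_classes: pd.DataFrame,
    edges_path,
    nodes_path,
    rho_min: float = 0.5,
    q_max: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a threshold-passing correlation network as edge/node tables.

    Edge rows are sorted by |rho| descending then ids, so re-exporting the
    same records is byte-identical. Node classes come from the gene-class
    list where available.
    """
    passing = _passing(records, rho_min, q_max).copy()
    passing = passing.sort_values(
        by=["rho", "srna_id", "mrna_id"],
        key=lambda s: -s.abs() if s.name == "rho" else s,
    )
    edges = passing[["srna_id", "mrna_id", "rho", "sign", "q_value"]].rename(
        columns={"srna_id": "source", "mrna_id": "target"}
    )
    classes = gene_classes.set_index("gene_id")["class"] if len(gene_classes) else pd.Series(dtype=object)
    nodes = pd.concat(
        [
            pd.DataFrame({"id": sorted(set(edges["source"])), "type": "miRNA"}),
            pd.DataFrame({"id": sorted(set(edges["target"])), "type": "gene"}),
        ],
        ignore_index=True,
    )
    if len(nodes):
        nodes["class"] = [classes.get(i, "") for i in nodes["id"]]
    else:
        nodes = pd.DataFrame(columns=["id", "type", "class"])
    edges.to_csv(edges_path, sep="\t", index=False)
    nodes.to_csv(nodes_path, sep="\t", index=False)
    return edges, nodes
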