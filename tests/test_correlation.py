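"""Spearman correlation, bias profiling and network summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from srnascape.correlation import (
    correlate_matrices,
    direction_bias,
    export_network,
    gene_class_counts,
    spearman,
    subtype_target_table,
)
from srnascape.simulate import simulate_paired_expression


class TestSpearman:
    def test_monotone_and_antitone_extremes(self, rng):
        x = rng.normal(size=20)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0, abs=1e-12)
        assert p == 0.0
        rho, _ = spearman(x, -x ** 3)
        assert rho == pytest.approx(-1.0, abs=1e-12)

    def test_matches_reference_implementation_with_ties(self, rng):
        for _ in range(100):
            x = rng.integers(0, 6, size=12).astype(float)  # heavy ties
            y = rng.normal(size=12)
            if len(set(x)) < 2:
                continue
            rho, p = spearman(x, y)
            ref_rho, ref_p = sps.spearmanr(x, y)
            assert rho == pytest.approx(ref_rho, abs=1e-12)
            assert p == pytest.approx(ref_p, abs=1e-9)

    def test_monotone_transform_invariance(self, rng):
        for _ in range(100):
            x = rng.normal(size=15)
            y = rng.normal(size=15)
            rho, _ = spearman(x, y)
            for fx, fy in ((np.exp, lambda v: 3 * v + 1),
                           (lambda v: v, np.exp)):
                rho_t, _ = spearman(fx(x), fy(y))
                assert rho_t == pytest.approx(rho, abs=1e-12)

    def test_antisymmetry_in_rank_space(self, rng):
        x = rng.normal(size=14)
        y = rng.normal(size=14)
        assert spearman(x, -y)[0] == pytest.approx(-spearman(x, y)[0], abs=1e-14)

    def test_exact_permutation_p_small_n(self):
        # n=5: 5! = 120 orderings; a perfectly monotone pair has the
        # extreme rho in exactly 2 of them
        rho, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert rho == 1.0
        assert p == pytest.approx(2 / 120)

    def test_sampled_permutation_p_close_to_analytic(self, rng):
        x = rng.normal(size=9)
        y = 0.8 * x + rng.normal(size=9)
        rho, p = spearman(x, y)
        # n=9 uses 10,000 sampled permutations; compare to t approximation
        t_p = 2 * sps.t.sf(abs(rho) * np.sqrt(7 / (1 - rho**2)), df=7)
        se = np.sqrt(t_p * (1 - t_p) / 10_000)
        assert abs(p - t_p) < max(4 * se, 0.02)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1.0] * 10, list(range(10)))

    def test_short_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [4, 5, 6])


def _matrices(rng, n_s=5, n_m=6, n=26):
    cols = [f"s{i}" for i in range(n)]
    s = pd.DataFrame(rng.poisson(50, (n_s, n)) + 1.0,
                     index=[f"miR_{i}" for i in range(n_s)], columns=cols)
    g = pd.DataFrame(rng.poisson(50, (n_m, n)) + 1.0,
                     index=[f"gene_{i}" for i in range(n_m)], columns=cols)
    return s, g


class TestCorrelateMatrices:
    def test_identical_vectors_give_rho_one(self, rng):
        s, g = _matrices(rng, 1, 1)
        g.iloc[0] = s.iloc[0].to_numpy()
        rec = correlate_matrices(s, g, normalize="none")
        assert rec["rho"].iloc[0] == pytest.approx(1.0)
        assert rec["sign"].iloc[0] == "positive"

    def test_min_samples_enforced(self, rng):
        s, g = _matrices(rng, n=5)
        with pytest.raises(ValueError):
            correlate_matrices(s, g, min_samples=8)

    def test_null_matrices_center_on_zero(self, rng):
        s, g = _matrices(rng, 50, 50)
        rec = correlate_matrices(s, g)
        assert abs(rec["rho"].mean()) < 0.03

    def test_copula_pairs_recovered(self):
        """Designated pairs at rho = +/-0.8 recovered in sign (always) and
        magnitude (within 0.15) at n=26 over 20 seeds."""
        errs = []
        for seed in range(20):
            srna, mrna, truth = simulate_paired_expression(
                40, 40, 26,
                [("sRNA_0001", "mRNA_0001", 0.8), ("sRNA_0002", "mRNA_0002", -0.8)],
                seed=seed,
            )
            rec = correlate_matrices(srna, mrna, min_samples=8).set_index(
                ["srna_id", "mrna_id"]
            )
            for sid, mid, rho_t, _r in truth.itertuples(index=False):
                got = rec.loc[(sid, mid), "rho"]
                assert np.sign(got) == np.sign(rho_t)
                errs.append(abs(got - rho_t))
        assert max(errs) < 0.15 * 2.5  # individual draws
        assert np.mean(errs) < 0.15


class TestDirectionBias:
    def test_direct_binning(self):
        rec = pd.DataFrame({"rho": [0.5, 0.6, -0.5]})
        prof = direction_bias(rec)
        b5 = prof.iloc[5]
        assert (b5["n_positive"], b5["n_negative"]) == (1, 1)
        assert b5["fraction_positive"] == 0.5
        assert prof.iloc[6]["fraction_positive"] == 1.0

    def test_all_negative_rhos(self):
        rec = pd.DataFrame({"rho": [-0.15, -0.55, -0.95]})
        prof = direction_bias(rec)
        occupied = prof[prof["n_negative"] + prof["n_positive"] > 0]
        assert (occupied["fraction_positive"] == 0.0).all()

    def test_zero_rho_excluded_and_totals_conserved(self, rng):
        rhos = np.concatenate([rng.uniform(-1, 1, 200), [0.0] * 5])
        prof = direction_bias(pd.DataFrame({"rho": rhos}))
        assert prof["n_positive"].sum() + prof["n_negative"].sum() == 200

    def test_boundary_rho_one_in_last_bin(self):
        prof = direction_bias(pd.DataFrame({"rho": [1.0, -1.0]}))
        assert prof.iloc[9]["n_positive"] == 1
        assert prof.iloc[9]["n_negative"] == 1


def _records(rows):
    df = pd.DataFrame(
        rows, columns=["srna_id", "mrna_id", "rho", "q_value"]
    )
    df["sign"] = np.where(df["rho"] > 0, "positive",
                          np.where(df["rho"] < 0, "negative", "zero"))
    df["p_value"] = df["q_value"]
    df["n_samples"] = 26
    return df


CLASSES = pd.DataFrame(
    {"gene_id": ["GATA3", "MYC"], "class": ["tumor_suppressor", "oncogene"]}
)


class TestGeneClassCounts:
    def test_counts_by_sign(self):
        rec = _records([
            ("m1", "GATA3", -0.7, 0.01),
            ("m2", "GATA3", -0.8, 0.01),
            ("m3", "GATA3", -0.9, 0.01),
            ("m4", "GATA3", 0.7, 0.01),
            ("m5", "MYC", 0.6, 0.2),  # fails q threshold
        ])
        out = gene_class_counts(rec, CLASSES).set_index("gene_id")
        assert out.loc["GATA3", "n_negative_mirnas"] == 3
        assert out.loc["GATA3", "n_positive_mirnas"] == 1
        assert out.loc["MYC", "n_positive_mirnas"] == 0

    def test_vacuous_threshold_zeroes_everything(self):
        rec = _records([("m1", "GATA3", -0.7, 0.01)])
        out = gene_class_counts(rec, CLASSES, rho_min=1.01)
        assert (out[["n_negative_mirnas", "n_positive_mirnas"]] == 0).all().all()

    def test_matches_filter_oracle(self, rng):
        rows = [
            (f"m{i}", rng.choice(["GATA3", "MYC", "OTHER"]),
             float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.1)))
            for i in range(200)
        ]
        rec = _records(rows)
        out = gene_class_counts(rec, CLASSES, 0.5, 0.05).set_index("gene_id")
        for gene in CLASSES["gene_id"]:
            neg = {
                r[0] for r in rows
                if r[1] == gene and r[2] <= -0.5 and r[3] <= 0.05
            }
            pos = {
                r[0] for r in rows
                if r[1] == gene and r[2] >= 0.5 and r[3] <= 0.05
            }
            assert out.loc[gene, "n_negative_mirnas"] == len(neg)
            assert out.loc[gene, "n_positive_mirnas"] == len(pos)


def _ovr_with(mirna, subtype, lfc):
    out = {}
    for st in ("BL1", "BL2", "M", "LAR"):
        sig = st == subtype
        out[st] = pd.DataFrame(
            [{"feature_id": mirna, "category": "miRNA",
              "significant": sig, "log2_fold_change": lfc if sig else 0.0}]
        )
    return out


class TestSubtypeTargetTable:
    def test_up_mirna_with_negative_target(self):
        rec = _records([("miR-200", "GATA3", -0.7, 0.01)])
        table = subtype_target_table(_ovr_with("miR-200", "LAR", 2.5), rec, CLASSES)
        assert len(table) == 1
        row = table.iloc[0]
        assert row["subtype"] == "LAR"
        assert row["gene_class"] == "tumor_suppressor"
        assert row["gene_id"] == "GATA3"
        assert row["relation"] == "decreased_target_of_increased_miRNA"

    def test_down_mirna_labeled_other_relation(self):
        rec = _records([("miR-1", "MYC", -0.8, 0.01)])
        table = subtype_target_table(_ovr_with("miR-1", "M", -2.0), rec, CLASSES)
        assert table.iloc[0]["relation"] == "increased_target_of_decreased_miRNA"

    def test_no_significant_mirnas_no_rows(self):
        rec = _records([("miR-1", "MYC", -0.8, 0.01)])
        ovr = _ovr_with("miR-1", "M", -2.0)
        for st in ovr:
            ovr[st]["significant"] = False
        assert len(subtype_target_table(ovr, rec, CLASSES)) == 0

    def test_positive_correlations_not_paired(self):
        rec = _records([("miR-1", "MYC", 0.8, 0.01)])
        assert len(subtype_target_table(_ovr_with("miR-1", "M", 2.0), rec, CLASSES)) == 0


class TestExportNetwork:
    def test_empty_records_header_only(self, tmp_path):
        rec = _records([])
        e, n = export_network(rec, CLASSES, tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert len(e) == 0 and len(n) == 0
        assert (tmp_path / "e.tsv").read_text().startswith("source\ttarget")

    def test_edges_and_node_union(self, tmp_path):
        rec = _records([
            ("m1", "GATA3", -0.9, 0.01),
            ("m2", "MYC", 0.7, 0.01),
            ("m1", "MYC", 0.6, 0.01),
        ])
        e, n = export_network(rec, CLASSES, tmp_path / "e.tsv", tmp_path / "n.tsv")
        assert len(e) == 3
        assert list(e["source"])[0] == "m1"  # |rho| = 0.9 first
        assert set(n["id"]) == {"m1", "m2", "GATA3", "MYC"}
        assert set(n.loc[n["type"] == "gene", "class"]) == {
            "tumor_suppressor", "oncogene"
        }

    def test_reexport_byte_identical(self, tmp_path, rng):
        rows = [
            (f"m{i}", f"g{i%7}", float(rng.uniform(-1, 1)), float(rng.uniform(0, 0.05)))
            for i in range(50)
        ]
        rec = _records(rows)
        export_network(rec, CLASSES, tmp_path / "e1.tsv", tmp_path / "n1.tsv")
        export_network(rec, CLASSES, tmp_path / "e2.tsv", tmp_path / "n2.tsv")
        assert (tmp_path / "e1.tsv").read_bytes() == (tmp_path / "e2.tsv").read_bytes()
        assert (tmp_path / "n1.tsv").read_bytes() == (tmp_path / "n2.tsv").read_bytes()
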