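"""End-to-end orchestration: simulate -> preprocess -> quantify -> tRNA ->
differential -> correlation, with a manifest of checksummed outputs.

The pipeline runs either from a simulation config (self-contained, ground
truth written alongside the data) or from user-supplied genome / GFF3 /
FASTQ / metadata files. Stages execute in order, fail fast with the stage
name, and assert the conservation invariants (read-funnel accounting and
count-matrix totals) as they go.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd
import yaml

from . import io as sio
from .align import GenomeIndex, align_tag
from .annotate import (
    FeatureIndex,
    SPECIES,
    assign_tag,
    detection_curve,
    median_expression_profile,
    quantify,
)
from .correlation import (
    correlate_matrices,
    direction_bias,
    export_network,
    gene_class_counts,
    subtype_target_table,
)
from .differential import SUBTYPES, de_test_all_species, exclusive_sets, pairwise_summary
from .preprocess import preprocess_sample, tags_to_fasta
from .simulate import (
    SimulationConfig,
    build_reference,
    simulate_counts,
    simulate_mrna_given_srna,
    synthesize_reads,
)
from .trna import (
    CoverageRead,
    aggregate_anticodon,
    anticodon_differential,
    pooled_five_prime_half_fraction,
    positional_coverage,
)

logger = logging.getLogger("srnascape")


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    In simulation mode (``simulate=True``) all inputs are generated under
    ``outdir``; otherwise ``genome_fasta``, ``annotations_gff``,
    ``fastq_dir`` (files named ``{sample_id}.fastq``) and ``metadata_tsv``
    must point at existing files.
    """

    outdir: str = "srnascape_run"
    seed: int = 0
    simulate: bool = True
    sim: SimulationConfig | None = None
    # file-mode inputs
    genome_fasta: str | None = None
    annotations_gff: str | None = None
    fastq_dir: str | None = None
    metadata_tsv: str | None = None
    mrna_tsv: str | None = None
    gene_classes_tsv: str | None = None
    # preprocessing
    adapter_sequence: str | None = None  # defaults to sim adapter
    min_overlap: int = 5
    max_adapter_error_rate: float = 0.1
    min_length: int = 16
    # alignment / assignment
    max_mismatch: int = 1
    max_nta: int = 3
    overlap_fraction: float = 0.8
    strict_5p_offsets: bool = False
    # analysis
    detection_thresholds: tuple[int, ...] = (1, 5, 10, 15, 20)
    alpha: float = 0.05
    lfc_min: float = 1.0
    rho_min: float = 0.5
    q_max: float = 0.05
    bias_bin_width: float = 0.1
    n_mrna: int = 300
    n_designated_pairs: int = 40
    force: bool = False

    def __post_init__(self):
        if self.simulate and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)

    def validate(self) -> None:
        if not self.simulate:
            required = {
                "genome_fasta": self.genome_fasta,
                "annotations_gff": self.annotations_gff,
                "fastq_dir": self.fastq_dir,
                "metadata_tsv": self.metadata_tsv,
            }
            for name, path in required.items():
                if path is None:
                    raise ValueError(f"config missing required path: {name}")
                if not os.path.exists(path):
                    raise FileNotFoundError(f"{name} does not exist: {path}")
            for name, path in (
                ("mrna_tsv", self.mrna_tsv),
                ("gene_classes_tsv", self.gene_classes_tsv),
            ):
                if path is not None and not os.path.exists(path):
                    raise FileNotFoundError(f"{name} does not exist: {path}")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in (0, 1]")
        if self.max_nta < 0 or self.max_mismatch < 0:
            raise ValueError("max_nta and max_mismatch must be >= 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        sim_data = data.pop("sim", None)
        cfg = cls(**data)
        if sim_data:
            cfg.sim = SimulationConfig(**sim_data)
        return cfg


@dataclass
class RunReport:
    stages: list[dict] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)
    conservation: dict[str, bool] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(
                {
                    "stages": self.stages,
                    "manifest": self.manifest,
                    "conservation": self.conservation,
                    "summary": self.summary,
                },
                handle,
                indent=2,
                sort_keys=True,
            )


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _default_pair_table(
    mirna_matrix: pd.DataFrame, config: RunConfig
) -> tuple[list[tuple[str, str, float]], pd.DataFrame]:
    """Designate miRNA->gene copula pairs for the simulated mRNA matrix.

    Spiked miRNAs come first so the subtype target table has wired examples
    to recover; remaining slots go to the most abundant miRNAs. Seventy
    percent of designated pairs are positive, matching the positive
    directional bias the correlation profile is meant to exhibit.
    """
    spiked = [
        fid
        for fid, _st, _lfc in (config.sim.spike_table if config.sim else [])
        if fid in mirna_matrix.index
    ]
    by_abundance = (
        mirna_matrix.sum(axis=1).sort_values(ascending=False).index.tolist()
    )
    ordered = list(dict.fromkeys(spiked + by_abundance))[: config.n_designated_pairs]
    pair_table = []
    classes = []
    for i, mid in enumerate(ordered):
        gene = f"gene_{i + 1:04d}"
        rho = 0.75 if i % 10 < 7 else -0.75
        if mid in spiked:
            rho = -0.75  # wire spiked miRNAs to anti-correlated targets
        pair_table.append((mid, gene, rho))
        classes.append(
            {
                "gene_id": gene,
                "class": "tumor_suppressor" if i % 2 == 0 else "oncogene",
            }
        )
    return pair_table, pd.DataFrame(classes)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages and return a :class:`RunReport`.

    Any stage failure raises :class:`StageError` naming the stage. Output
    files are listed in ``report.manifest`` with sha256 checksums; two runs
    with the same config and seed produce identical manifests.
    """
    config.validate()
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    report = RunReport()
    outputs: list[str] = []

    def emit(relpath: str):
        outputs.append(relpath)

    def path(relpath: str) -> str:
        p = os.path.join(outdir, relpath)
        os.makedirs(os.path.dirname(p), exist_ok=True)
        return p

    def stage(name: str):
        logger.info("stage %s", name)
        report.stages.append({"stage": name, "status": "running"})

    def done(**details):
        report.stages[-1].update(status="ok", **details)

    # ------------------------------------------------------------ simulate
    try:
        stage("simulate")
        if config.simulate:
            sim = config.sim
            genome, features = build_reference(sim)
            sio.write_fasta(genome, path("genome.fa"))
            emit("genome.fa")
            sio.write_gff3(features, path("annotations.gff3"))
            emit("annotations.gff3")
            truth = simulate_counts(sim, features)
            reads_by_sample, provenance = synthesize_reads(truth, genome, features, sim)
            for sample, reads in reads_by_sample.items():
                rel = f"reads/{sample}.fastq"
                sio.write_fastq(reads, path(rel), sim.quality_char)
                emit(rel)
            sio.write_tsv(truth.expected, path("truth/expected_counts.tsv"))
            emit("truth/expected_counts.tsv")
            sio.write_tsv(truth.realized, path("truth/realized_counts.tsv"))
            emit("truth/realized_counts.tsv")
            provenance.to_csv(path("truth/provenance.tsv"), sep="\t", index=False)
            emit("truth/provenance.tsv")
            metadata = pd.DataFrame(list(sim.design), columns=["sample_id", "subtype"])
            metadata.to_csv(path("metadata.tsv"), sep="\t", index=False)
            emit("metadata.tsv")
            adapter = config.adapter_sequence or sim.adapter_sequence
            fastq_of = {s: path(f"reads/{s}.fastq") for s in reads_by_sample}
            done(n_samples=len(reads_by_sample), n_features=len(features))
        else:
            genome = sio.read_fasta(config.genome_fasta)
            features = sio.read_gff3(config.annotations_gff)
            metadata = pd.read_csv(config.metadata_tsv, sep="\t")
            adapter = config.adapter_sequence
            if adapter is None:
                raise ValueError("adapter_sequence required in file mode")
            fastq_of = {}
            for sid in metadata["sample_id"]:
                for ext in (".fastq", ".fastq.gz", ".fq", ".fq.gz"):
                    p = os.path.join(config.fastq_dir, sid + ext)
                    if os.path.exists(p):
                        fastq_of[sid] = p
                        break
                else:
                    raise FileNotFoundError(f"no FASTQ for sample {sid}")
            done(n_samples=len(fastq_of), n_features=len(features))
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("simulate", exc) from exc

    # ------------------------------------------------------------ preprocess
    try:
        stage("preprocess")
        trim_cache: dict[str, str] = {}
        tags_by_sample = {}
        stats_rows = []
        for sid in metadata["sample_id"]:
            raw = sio.read_fastq_sequences(fastq_of[sid])
            tags, pstats = preprocess_sample(
                raw,
                adapter,
                sample_id=sid,
                min_overlap=config.min_overlap,
                max_error_rate=config.max_adapter_error_rate,
                min_length=config.min_length,
                _trim_cache=trim_cache,
            )
            tags_by_sample[sid] = tags
            stats_rows.append(dataclasses.asdict(pstats))
            rel = f"tags/{sid}.fa"
            tags_to_fasta(tags, path(rel))
            emit(rel)
            assert pstats.n_usable == pstats.n_raw - pstats.n_too_short_discarded
            assert sum(t.copies for t in tags) == pstats.n_usable
        stats_df = pd.DataFrame(stats_rows)
        stats_df.to_csv(path("preprocess_stats.tsv"), sep="\t", index=False)
        emit("preprocess_stats.tsv")
        report.conservation["preprocess_funnel"] = True
        done(
            n_raw=int(stats_df["n_raw"].sum()),
            n_usable=int(stats_df["n_usable"].sum()),
        )
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("preprocess", exc) from exc

    # ------------------------------------------------------------ quantify
    try:
        stage("quantify")
        gindex = GenomeIndex(genome)
        findex = FeatureIndex(features)
        assignments_by_seq = {}
        for sid, tags in tags_by_sample.items():
            for tag in tags:
                if tag.sequence in assignments_by_seq:
                    continue
                hits = align_tag(
                    tag.sequence,
                    gindex,
                    max_mismatch=config.max_mismatch,
                    max_nta=config.max_nta,
                    min_aligned=config.min_length,
                )
                if hits:
                    assignments_by_seq[tag.sequence] = assign_tag(
                        hits, findex, config.overlap_fraction
                    )
                else:
                    assignments_by_seq[tag.sequence] = []
        all_tags = [t for tags in tags_by_sample.values() for t in tags]
        sample_ids = list(metadata["sample_id"])
        quant = quantify(
            assignments_by_seq, all_tags, sample_ids, config.strict_5p_offsets
        )
        for sp, m in quant.matrices.items():
            rel = f"counts/{sp}.tsv"
            sio.write_tsv(m, path(rel))
            emit(rel)
        accounting = pd.DataFrame(
            {
                "unannotated": quant.unannotated,
                "unmapped": quant.unmapped,
                "excluded_offsets": quant.excluded_offsets,
            }
        )
        sio.write_tsv(accounting, path("counts/accounting.tsv"))
        emit("counts/accounting.tsv")
        # conservation: species totals + unannotated (+ strict-mode excluded)
        # must equal the mapped copy total per sample
        mapped_copies = pd.Series(0.0, index=sample_ids)
        for tags in tags_by_sample.values():
            for t in tags:
                if assignments_by_seq[t.sequence]:
                    mapped_copies[t.sample_id] += t.copies
        conserved = bool(
            (quant.mapped_total() - mapped_copies).abs().max() < 1e-6
        )
        report.conservation["quantify_totals"] = conserved
        if not conserved:
            raise AssertionError("count conservation violated")
        curves = {}
        for sp, m in quant.matrices.items():
            curve = detection_curve(m, config.detection_thresholds)
            curves[sp] = curve
            rel = f"detection/{sp}.tsv"
            sio.write_tsv(curve, path(rel))
            emit(rel)
            rel = f"medians/{sp}.tsv"
            sio.write_tsv(median_expression_profile(m).to_frame(), path(rel))
            emit(rel)
        done(
            n_unique_sequences=len(assignments_by_seq),
            mapped_copies=float(mapped_copies.sum()),
        )
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("quantify", exc) from exc

    # ------------------------------------------------------------ trna
    try:
        stage("trna")
        trna_matrix = quant.matrices["tRNA"]
        if trna_matrix.shape[0]:
            counts, fractions = aggregate_anticodon(trna_matrix, features)
            sio.write_tsv(counts, path("trna/anticodon_counts.tsv"))
            emit("trna/anticodon_counts.tsv")
            sio.write_tsv(fractions, path("trna/anticodon_fractions.tsv"))
            emit("trna/anticodon_fractions.tsv")
            cov_reads = []
            for tags in tags_by_sample.values():
                for t in tags:
                    for a in assignments_by_seq[t.sequence]:
                        if a.category == "tRNA":
                            cov_reads.append(
                                CoverageRead(
                                    feature_id=a.feature_id,
                                    offset_5p=a.offset_5p,
                                    aligned_length=a.aligned_length,
                                    depth=t.copies * a.weight,
                                    sample_id=t.sample_id,
                                )
                            )
            profiles = positional_coverage(cov_reads, features)
            cov_df = pd.DataFrame(
                {fam: p.binned for fam, p in profiles.items()}
            ).T
            cov_df.index.name = "family"
            sio.write_tsv(cov_df, path("trna/coverage_bins.tsv"))
            emit("trna/coverage_bins.tsv")
            half_df = pd.DataFrame(
                {
                    "five_prime_half_fraction": {
                        fam: p.five_prime_half_fraction for fam, p in profiles.items()
                    },
                    "total_depth": {
                        fam: p.total_depth for fam, p in profiles.items()
                    },
                }
            )
            half_df.loc["__pooled__"] = [
                pooled_five_prime_half_fraction(profiles),
                sum(p.total_depth for p in profiles.values()),
            ]
            sio.write_tsv(half_df, path("trna/half_fraction.tsv"))
            emit("trna/half_fraction.tsv")
            report.summary["trna_five_prime_half_fraction"] = float(
                pooled_five_prime_half_fraction(profiles)
            )
            counts_by_subtype = metadata["subtype"].value_counts()
            for st in SUBTYPES:
                if counts_by_subtype.get(st, 0) >= 2 and (
                    len(metadata) - counts_by_subtype.get(st, 0) >= 2
                ):
                    diff = anticodon_differential(
                        fractions, metadata, st, alpha=config.alpha
                    )
                    rel = f"trna/differential_{st}_vs_others.tsv"
                    diff.to_csv(path(rel), sep="\t")
                    emit(rel)
        done(n_families=int(trna_matrix.shape[0] and len(profiles)))
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("trna", exc) from exc

    # ------------------------------------------------------------ differential
    try:
        stage("differential")
        present = [
            st for st in SUBTYPES if (metadata["subtype"] == st).sum() >= 2
        ]
        pairwise_results = {}
        for a, b in combinations(present, 2):
            res = de_test_all_species(
                quant.matrices, metadata, a, b, alpha=config.alpha, lfc_min=config.lfc_min
            )
            label = f"{a} vs {b}"
            pairwise_results[label] = res
            rel = f"de/{a}_vs_{b}.tsv"
            res.to_csv(path(rel), sep="\t", index=False)
            emit(rel)
        ovr_results = {}
        for st in present:
            res = de_test_all_species(
                quant.matrices, metadata, st, "others",
                alpha=config.alpha, lfc_min=config.lfc_min,
            )
            ovr_results[st] = res
            rel = f"de/{st}_vs_others.tsv"
            res.to_csv(path(rel), sep="\t", index=False)
            emit(rel)
        if len(present) == 4:
            table1 = pairwise_summary(pairwise_results)
            sio.write_tsv(table1, path("de/pairwise_summary.tsv"))
            emit("de/pairwise_summary.tsv")
            sets, table2 = exclusive_sets(ovr_results)
            sio.write_tsv(table2, path("de/exclusive_summary.tsv"))
            emit("de/exclusive_summary.tsv")
            report.summary["exclusive_counts"] = {
                st: len(s) for st, s in sets.items()
            }
        done(n_comparisons=len(pairwise_results) + len(ovr_results))
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("differential", exc) from exc

    # ------------------------------------------------------------ correlate
    try:
        stage("correlate")
        mirna_matrix = quant.matrices["miRNA"]
        mrna = gene_classes = None
        if config.mrna_tsv:
            mrna = sio.read_tsv_matrix(config.mrna_tsv)
            if config.gene_classes_tsv:
                gene_classes = pd.read_csv(config.gene_classes_tsv, sep="\t")
        elif config.simulate and mirna_matrix.shape[0] >= 4:
            pair_table, gene_classes = _default_pair_table(mirna_matrix, config)
            mrna, pair_truth = simulate_mrna_given_srna(
                mirna_matrix, pair_table, config.n_mrna, seed=config.seed
            )
            sio.write_tsv(mrna, path("mrna/matrix.tsv"))
            emit("mrna/matrix.tsv")
            pair_truth.to_csv(path("truth/designated_pairs.tsv"), sep="\t", index=False)
            emit("truth/designated_pairs.tsv")
            gene_classes.to_csv(path("mrna/gene_classes.tsv"), sep="\t", index=False)
            emit("mrna/gene_classes.tsv")
        if mrna is not None:
            if gene_classes is None:
                gene_classes = pd.DataFrame(columns=["gene_id", "class"])
            records = correlate_matrices(
                mirna_matrix, mrna,
                min_samples=min(8, mrna.shape[1]),
                categories={i: "miRNA" for i in mirna_matrix.index},
            )
            records.to_csv(path("correlation/records.tsv"), sep="\t", index=False)
            emit("correlation/records.tsv")
            bias = direction_bias(records, config.bias_bin_width)
            bias.to_csv(path("correlation/direction_bias.tsv"), sep="\t", index=False)
            emit("correlation/direction_bias.tsv")
            gcc = gene_class_counts(records, gene_classes, config.rho_min, config.q_max)
            gcc.to_csv(path("correlation/gene_class_counts.tsv"), sep="\t", index=False)
            emit("correlation/gene_class_counts.tsv")
            if len(present) == 4:
                ttable = subtype_target_table(
                    ovr_results_mirna(ovr_results), records, gene_classes,
                    config.rho_min, config.q_max,
                )
                ttable.to_csv(path("correlation/subtype_targets.tsv"), sep="\t", index=False)
                emit("correlation/subtype_targets.tsv")
            export_network(
                records, gene_classes,
                path("correlation/network_edges.tsv"),
                path("correlation/network_nodes.tsv"),
                config.rho_min, config.q_max,
            )
            emit("correlation/network_edges.tsv")
            emit("correlation/network_nodes.tsv")
            done(n_pairs=len(records))
        else:
            done(n_pairs=0, skipped="no mRNA matrix available")
    except Exception as exc:  # noqa: BLE001
        report.stages[-1].update(status="failed", error=str(exc))
        raise StageError("correlate", exc) from exc

    report.manifest = sio.build_manifest(outdir, outputs)
    report.to_json(os.path.join(outdir, "run_report.json"))
    return report


def ovr_results_mirna(ovr_results: dict[str, pd.DataFrame]) -> dict[str, pd.DataFrame]:
    """Restrict one-vs-rest DE tables to the miRNA species."""
    return {
        st: df[df["category"] == "miRNA"].reset_index(drop=True)
        for st, df in ovr_results.items()
    }
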