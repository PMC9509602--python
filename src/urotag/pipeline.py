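"""End-to-end orchestration: simulate/load -> db -> qc -> profile -> statistics.

A single validated config drives every stage; all randomness flows from its
one seed through named per-stage substreams, so reruns with an identical
config are byte-identical.  Each stage writes its outputs under its own
subdirectory of the output root and a ``report.json`` summarises the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diffabund, ecology, io, markers, profiler, readqc, synthdata
from .tagdb import build_tagdb

__all__ = ["PipelineConfig", "ConfigError", "load_config", "run_pipeline"]

logger = logging.getLogger(__name__)

_SIMULATE_DEFAULTS: dict[str, Any] = {
    "n_phyla": 10,
    "n_genera": 60,
    "n_species": 300,
    "n_subjects": 30,
    "sigma_lognormal": 1.5,
    "subject_sd": 0.5,
    "sample_sd": 0.0,
    "effects": {},
    "n_reads_per_sample": 50_000,
    "error_rate": 0.001,
    "n_rate": 0.0005,
    "length_mean": 100_000,
    "gc_range": (0.3, 0.7),
    "planted_sites": (20, 200),
}

_PARAM_DEFAULTS: dict[str, Any] = {
    "g_score_threshold": 10.0,
    "max_n_fraction": 0.08,
    "max_lowq_fraction": 0.20,
    "low_quality_q": 20,
    "alpha": 0.05,
    "lda_threshold": 2.0,
    "n_boot": 30,
    "n_perm": 999,
    "folds": 10,
    "repeats": 10,
    "top_n": 30,
    "n_trees": 500,
    "cv_n_trees": 100,
}

_INPUT_KEYS = {"genomes", "taxonomy", "reads_dir", "design"}


class ConfigError(ValueError):
    """Invalid or unknown configuration content, reported before any stage runs."""


@dataclass
class PipelineConfig:
    seed: int
    simulate: dict[str, Any] | None = None
    inputs: dict[str, str] | None = None
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("exactly one of 'simulate' or 'inputs' must be given")
        if self.simulate is not None:
            unknown = set(self.simulate) - set(_SIMULATE_DEFAULTS)
            if unknown:
                raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
            self.simulate = {**_SIMULATE_DEFAULTS, **self.simulate}
        if self.inputs is not None:
            unknown = set(self.inputs) - _INPUT_KEYS
            if unknown:
                raise ConfigError(f"unknown input keys: {sorted(unknown)}")
            missing = _INPUT_KEYS - set(self.inputs)
            if missing:
                raise ConfigError(f"missing input keys: {sorted(missing)}")
        unknown = set(self.params) - set(_PARAM_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown parameter keys: {sorted(unknown)}")
        self.params = {**_PARAM_DEFAULTS, **self.params}
        for key in ("g_score_threshold", "max_n_fraction", "max_lowq_fraction",
                    "lda_threshold", "alpha"):
            if self.params[key] <= 0:
                raise ConfigError(f"parameter {key} must be positive")


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - {"seed", "simulate", "inputs", "params"}
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must set a seed")
    return PipelineConfig(
        seed=int(raw["seed"]),
        simulate=raw.get("simulate"),
        inputs=raw.get("inputs"),
        params=raw.get("params", {}),
    )


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % 2**31)


def _load_inputs(inputs: Mapping[str, str]):
    taxonomy = io.read_taxonomy(inputs["taxonomy"])
    genomes = io.read_fasta(inputs["genomes"])
    samples = pd.read_csv(inputs["design"], sep="\t", dtype=str)
    design = synthdata.PairedDesign(samples, pd.DataFrame(), {})
    reads = {
        s: io.read_fastq(Path(inputs["reads_dir"]) / f"{s}.fastq")
        for s in samples["sample_id"]
    }
    return taxonomy, genomes, design, reads


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict[str, Any]:
    """Execute all stages in order and return the summary report dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    report: dict[str, Any] = {"seed": config.seed, "params": dict(sorted(p.items()))}

    # --- stage 1: data ---------------------------------------------------
    if config.simulate is not None:
        sim_dir = outdir / "simulation"
        sim = dict(config.simulate)
        sim["gc_range"] = tuple(sim["gc_range"])
        sim["planted_sites"] = tuple(sim["planted_sites"])
        design = synthdata.simulate_study(sim_dir, seed=_stage_seed(config.seed, 0), **sim)
        taxonomy = io.read_taxonomy(sim_dir / "taxonomy.tsv")
        genomes = io.read_fasta(sim_dir / "genomes.fasta")
        raw_reads = {
            s: io.read_fastq(sim_dir / "reads" / f"{s}.fastq")
            for s in design.sample_ids()
        }
    else:
        taxonomy, genomes, design, raw_reads = _load_inputs(config.inputs)
    logger.info("pipeline: %d samples, %d species genomes", len(raw_reads), len(genomes))

    # --- stage 2: primary tag database -----------------------------------
    db_dir = outdir / "tagdb"
    primary = build_tagdb(genomes, taxonomy)
    primary.write(db_dir)
    report["tagdb"] = {
        "n_tags": len(primary),
        "n_species_with_markers": len(primary.tag_counts),
        "n_species_flagged": len(primary.no_marker_species),
    }

    # --- stage 3: QC ------------------------------------------------------
    qc_dir = outdir / "qc"
    qc_dir.mkdir(exist_ok=True)
    clean_reads: dict[str, list] = {}
    qc_rows = []
    for sample_id in sorted(raw_reads):
        clean, rep = readqc.run_qc(
            raw_reads[sample_id],
            max_n_fraction=p["max_n_fraction"],
            max_lowq_fraction=p["max_lowq_fraction"],
            low_quality_q=p["low_quality_q"],
        )
        clean_reads[sample_id] = clean
        io.write_fastq(clean, qc_dir / f"{sample_id}.clean.fastq")
        qc_rows.append(
            {
                "sample_id": sample_id,
                "n_raw": rep.n_raw,
                "n_enzyme": rep.n_enzyme,
                "n_clean": rep.n_clean,
                "fraction_enzyme": rep.fraction_enzyme,
                "fraction_clean": rep.fraction_clean,
            }
        )
    qc_table = pd.DataFrame(qc_rows)
    qc_table.to_csv(qc_dir / "qc_report.tsv", sep="\t", index=False)
    report["qc"] = {
        "n_raw_total": int(qc_table["n_raw"].sum()),
        "n_clean_total": int(qc_table["n_clean"].sum()),
    }

    # --- stage 4: two-pass profiling --------------------------------------
    prof_dir = outdir / "profiles"
    prof_dir.mkdir(exist_ok=True)
    profiles, count_cols, pass1_meta = [], {}, {}
    for sample_id in sorted(clean_reads):
        profile, pass1, pass2 = profiler.profile_sample(
            clean_reads[sample_id], primary, genomes,
            sample_id=sample_id, g_threshold=p["g_score_threshold"],
            with_counts=True,
        )
        profiles.append(profile)
        count_cols[sample_id] = pd.Series(pass2.S, dtype=float)
        pass1_meta[sample_id] = pass1.to_frame().to_dict(orient="index")
    species_matrix = profiler.profiles_to_matrix(profiles)
    read_counts = pd.DataFrame(count_cols).fillna(0.0).sort_index()
    rank_matrices = {
        rank: profiler.aggregate_ranks(species_matrix, taxonomy, rank)
        for rank in ("phylum", "genus", "species")
    }
    for rank, mat in rank_matrices.items():
        io.write_profile_matrix(mat, prof_dir / f"{rank}.tsv")
    io.write_profile_matrix(read_counts, prof_dir / "species_read_counts.tsv")
    (prof_dir / "pass1_counts.json").write_text(
        json.dumps(pass1_meta, indent=1, sort_keys=True)
    )
    report["profiling"] = {
        "n_species_detected": int((species_matrix > 0).any(axis=1).sum())
    }

    # --- stage 5: ecology -------------------------------------------------
    eco_dir = outdir / "ecology"
    eco_dir.mkdir(exist_ok=True)
    labels = design.labels().loc[species_matrix.columns]
    subjects = design.samples.set_index("sample_id")["subject_id"].loc[
        species_matrix.columns
    ]
    alpha_table = ecology.alpha_diversity_table(read_counts, species_matrix)
    alpha_table.to_csv(eco_dir / "alpha_diversity.tsv", sep="\t")
    alpha_tests = {}
    pivot = design.samples.pivot(index="subject_id", columns="side", values="sample_id")
    for index in ("chao1", "shannon", "simpson"):
        try:
            _, pval = diffabund.paired_wilcoxon(
                alpha_table.loc[pivot["stone"], index],
                alpha_table.loc[pivot["non_stone"], index],
            )
        except diffabund.UndefinedTestError:
            pval = float("nan")
        alpha_tests[index] = pval
    beta = {}
    seed_perm = _stage_seed(config.seed, 5)
    for metric in ("bray_curtis", "jaccard_binary", "euclidean"):
        dm = ecology.distance_matrix(species_matrix, metric)
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            eco_dir / f"distance_{metric}.tsv", sep="\t"
        )
        ord_res = ecology.pcoa(dm)
        ord_res.coordinates.to_csv(eco_dir / f"pcoa_{metric}.tsv", sep="\t")
        f_stat, pval = ecology.permanova(
            dm, labels, n_perm=p["n_perm"], seed=seed_perm
        )
        beta[metric] = {"pseudo_F": f_stat, "p": pval}
    detected = {
        side: set(
            species_matrix.index[
                (species_matrix[design.sample_ids(side)] > 0).any(axis=1)
            ]
        )
        for side in ("stone", "non_stone")
    }
    venn = ecology.venn_summary(detected["stone"], detected["non_stone"])
    report["ecology"] = {
        "alpha_paired_wilcoxon_p": alpha_tests,
        "permanova": beta,
        "venn": {
            "shared": venn.n_shared,
            "stone_only": venn.n_only_a,
            "non_stone_only": venn.n_only_b,
            "pct_shared": venn.pct_shared,
            "pct_stone_only": venn.pct_only_a,
            "pct_non_stone_only": venn.pct_only_b,
        },
    }

    # --- stage 6: differential abundance ----------------------------------
    diff_dir = outdir / "diff"
    diff_dir.mkdir(exist_ok=True)
    table = diffabund.differential_table(rank_matrices, design, alpha=p["alpha"])
    table.to_csv(diff_dir / "differential_table.tsv", sep="\t", index=False)
    combined = pd.concat(
        [m.set_axis([f"{rank}|{t}" for t in m.index]) for rank, m in rank_matrices.items()]
    )
    lda = diffabund.lda_effect_size(
        combined, labels, alpha=p["alpha"], lda_threshold=p["lda_threshold"],
        n_boot=p["n_boot"], seed=_stage_seed(config.seed, 6),
    )
    lda.to_csv(diff_dir / "lda_effect_size.tsv", sep="\t", index=False)
    for rank in ("genus", "species"):
        corr = diffabund.spearman_matrix(rank_matrices[rank], top_n=p["top_n"])
        corr.rho.to_csv(diff_dir / f"spearman_rho_{rank}.tsv", sep="\t")
        corr.p.to_csv(diff_dir / f"spearman_p_{rank}.tsv", sep="\t")
    report["diffabund"] = {
        "n_significant_taxa": int(table["significant"].sum()),
        "n_lda_discriminative": int(len(lda)),
    }

    # --- stage 7: marker model --------------------------------------------
    mark_dir = outdir / "markers"
    mark_dir.mkdir(exist_ok=True)
    model = markers.fit_marker_model(
        species_matrix, labels, n_trees=p["n_trees"], folds=p["folds"],
        repeats=p["repeats"], top_n=p["top_n"], cv_n_trees=p["cv_n_trees"],
        seed=_stage_seed(config.seed, 7),
    )
    model.cv_curve.to_csv(mark_dir / "cv_curve.tsv", sep="\t", index=False)
    pd.Series(model.optimal_set, name="species_id").to_csv(
        mark_dir / "optimal_set.tsv", sep="\t", index=False
    )
    model.pod.rename_axis("sample_id").to_csv(mark_dir / "pod.tsv", sep="\t")
    model.roc.to_csv(mark_dir / "roc.tsv", sep="\t", index=False)
    try:
        _, pod_p = diffabund.paired_wilcoxon(
            model.pod.loc[pivot["stone"]], model.pod.loc[pivot["non_stone"]]
        )
    except diffabund.UndefinedTestError:
        pod_p = float("nan")
    report["markers"] = {
        "k_star": model.k_star,
        "auc": model.auc,
        "pod_paired_wilcoxon_p": pod_p,
        "n_pod_fallback": len(model.pod_fallback_samples),
    }

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
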