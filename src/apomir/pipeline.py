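"""End-to-end orchestration: simulate -> normalize -> diffexp -> associate ->
seedmatch -> survival -> report, with provenance records and fixed seeds.

A run is configured by a YAML file (see :class:`RunConfig`) and writes one
TSV per stage plus a JSON provenance sidecar (input checksums, config,
seed) into the output directory. Reruns with the same config are
bit-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import ScreenConfig, run_association_screen
from .cohort import make_cohort_report
from .diffexp import DEResult, bh_adjust, classify_dysregulated, run_de
from .io import (
    ExpressionMatrix,
    MatrixKind,
    PathwayGeneList,
    ValidationError,
    read_expression_matrix,
    read_fasta,
    read_pathway_gene_list,
    read_sample_meta,
    write_expression_matrix,
    write_fasta,
    write_sample_meta,
)
from .normalize import mirna_quantile_scale, paired_differential, rpmpcg_normalize
from .seedmatch import classify_interactions, scan_many
from .simulate import (
    SimulationConfig,
    simulate_mirna_with_associations,
    simulate_paired_counts,
    simulate_survival,
)
from .survival import run_survival

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths, stage toggles, and stage parameters for one pipeline run."""

    out_dir: str
    # inputs; all optional when simulate=True
    counts_path: str | None = None
    mirna_path: str | None = None
    meta_path: str | None = None
    pathway_path: str | None = None
    mirna_fasta_path: str | None = None
    utr_fasta_path: str | None = None
    # stage toggles
    simulate: bool = True
    diffexp: bool = True
    associate: bool = True
    seedmatch: bool = True
    survival: bool = True
    # parameters
    rng_seed: int = 0
    fc_lower: float = 0.67
    fc_upper: float = 1.50
    alpha: float = 0.05
    n_boot: int = 10_000
    n_perm: int = 10_000
    de_test: str = "lrt"
    survival_cohorts: tuple[str, ...] = ("all", "colon", "rectal")
    sim: dict = field(default_factory=dict)  # SimulationConfig overrides

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if isinstance(cfg.survival_cohorts, list):
            cfg.survival_cohorts = tuple(cfg.survival_cohorts)
        return cfg

    def validate(self) -> None:
        if not self.simulate:
            needed = {
                "counts_path": self.diffexp,
                "mirna_path": self.associate or self.survival,
                "meta_path": True,
                "pathway_path": self.diffexp,
            }
            for name, required in needed.items():
                p = getattr(self, name)
                if required and (p is None or not Path(p).exists()):
                    raise ValidationError(f"required input missing: {name} = {p}")
        if self.seedmatch:
            for name in ("mirna_fasta_path", "utr_fasta_path"):
                p = getattr(self, name)
                if not self.simulate and (p is None or not Path(p).exists()):
                    raise ValidationError(f"seedmatch enabled but {name} = {p}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _provenance(out: Path, stage: str, config: RunConfig, inputs: list[Path]) -> None:
    record = {
        "stage": stage,
        "version": __version__,
        "seed": config.rng_seed,
        "config": {
            k: v for k, v in asdict(config).items() if not isinstance(v, dict)
        },
        "inputs": {str(p): _sha256(p) for p in inputs if p.exists()},
    }
    (out / f"{stage}.provenance.json").write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")


def _de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "tumor_mean": round(r.tumor_mean, 2),
                "normal_mean": round(r.normal_mean, 2),
                "fold_change": round(r.fold_change, 2),
                "log_fc_estimate": r.log_fc_estimate,
                "raw_p": f"{r.raw_p:.3g}",
                "adjusted_p": f"{r.adjusted_p:.3g}",
                "subgroup": r.subgroup,
            }
            for r in results
        ]
    )


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, msg: str) -> None:
        log_lines.append(f"{stage}: {msg}")

    # --- inputs (simulated or read) -------------------------------------
    if config.simulate:
        sim_cfg = SimulationConfig(**{"rng_seed": config.rng_seed, **config.sim})
        counts, meta, truth = simulate_paired_counts(sim_cfg)
        pathway = PathwayGeneList(tuple(counts.feature_ids))
        norm = rpmpcg_normalize(counts, pathway)
        gene_diff0 = paired_differential(norm, meta)
        mirna_raw, adjusted = simulate_mirna_with_associations(
            sim_cfg, truth, meta, gene_diff0
        )
        meta = simulate_survival(meta, _diff_matrix(truth), sim_cfg, truth=truth)
        write_expression_matrix(counts, out / "counts.tsv")
        write_expression_matrix(mirna_raw, out / "mirna_intensity.tsv")
        write_sample_meta(meta, out / "meta.csv")
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "true_log_fc": truth.true_log_fc,
                    "mirna_true_log_fc": truth.mirna_true_log_fc,
                    "assoc_betas": {f"{g}|{m}": b for (g, m), b in truth.assoc_betas.items()},
                    "seed_sites": truth.seed_sites,
                    "cox_betas": truth.cox_betas,
                    "survival_mirna": truth.survival_mirna,
                    "censor_time": truth.censor_time,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
        log("simulate", f"{counts.shape[0]} genes x {counts.shape[1]} samples; "
                        f"{mirna_raw.shape[0]} miRNAs")
    else:
        counts = read_expression_matrix(config.counts_path, MatrixKind.MRNA_COUNTS)
        meta = read_sample_meta(config.meta_path)
        pathway = read_pathway_gene_list(config.pathway_path)
        mirna_raw = (
            read_expression_matrix(config.mirna_path, MatrixKind.MIRNA_INTENSITY)
            if config.mirna_path
            else None
        )
        norm = rpmpcg_normalize(counts, counts.feature_ids)
        adjusted = None

    # --- normalize -------------------------------------------------------
    gene_diff = adjusted if adjusted is not None else paired_differential(norm, meta)
    write_expression_matrix(norm, out / "rpmpcg.tsv")
    write_expression_matrix(gene_diff, out / "gene_differential.tsv")
    mirna_diff = None
    if mirna_raw is not None:
        mirna_scaled = mirna_quantile_scale(mirna_raw)
        mirna_diff = paired_differential(mirna_scaled, meta)
        write_expression_matrix(mirna_scaled, out / "mirna_scaled.tsv")
        write_expression_matrix(mirna_diff, out / "mirna_differential.tsv")
    log("normalize", f"gene differential {gene_diff.shape}; "
                     f"mirna {'none' if mirna_diff is None else mirna_diff.shape}")
    _provenance(out, "normalize", config, [out / "counts.tsv"] if config.simulate else
                [Path(p) for p in (config.counts_path, config.meta_path) if p])

    gene_de = mirna_de = None
    # --- differential expression ----------------------------------------
    if config.diffexp:
        gene_de = run_de(counts, meta, pathway, test=config.de_test)
        _de_table(gene_de).to_csv(out / "diffexp.tsv", sep="\t", index=False)
        summary = classify_dysregulated(gene_de, config.fc_lower, config.fc_upper, config.alpha)
        log("diffexp", f"{len(gene_de)} genes tested; "
                       f"{summary.n_down} down, {summary.n_up} up")
        _provenance(out, "diffexp", config, [out / "counts.tsv"])

    # --- association screen ----------------------------------------------
    assoc = None
    if config.associate and mirna_diff is not None and gene_de:
        mirna_de = _mirna_de_from_means(mirna_scaled, meta)
        screen_cfg = ScreenConfig(
            fc_lower=config.fc_lower,
            fc_upper=config.fc_upper,
            alpha=config.alpha,
            n_boot=config.n_boot,
            rng_seed=config.rng_seed,
        )
        try:
            assoc = run_association_screen(
                gene_de, mirna_de, gene_diff, mirna_diff, meta, screen_cfg
            )
        except ValidationError as exc:
            log("associate", f"skipped: {exc}")
            assoc = None
        if assoc is not None:
            pd.DataFrame(
                [
                    {
                        "gene": a.gene,
                        "mirna": a.mirna,
                        "beta": round(a.beta, 4),
                        "f_stat": round(a.f_stat, 4),
                        "boot_p": a.boot_p,
                        "fdr_p": a.fdr_p,
                        "direction": a.direction,
                        "significant": a.significant,
                    }
                    for a in assoc
                ]
            ).to_csv(out / "associations.tsv", sep="\t", index=False)
            log("associate", f"{len(assoc)} pairs tested; "
                             f"{sum(a.significant for a in assoc)} significant")
            _provenance(out, "associate", config,
                        [out / "gene_differential.tsv", out / "mirna_differential.tsv"])

    # --- seed matching ----------------------------------------------------
    if config.seedmatch and config.mirna_fasta_path and config.utr_fasta_path:
        mirna_seqs = read_fasta(config.mirna_fasta_path, "rna")
        utrs = read_fasta(config.utr_fasta_path, "dna")
        matches = scan_many(utrs, mirna_seqs, source=Path(config.utr_fasta_path).name)
        pd.DataFrame(
            [
                {
                    "mirna": m.mirna,
                    "target": m.target,
                    "seed_length": m.seed_length,
                    "position": m.position,
                    "site": m.site,
                    "source_fasta": m.source,
                }
                for m in matches
            ]
        ).to_csv(out / "seed_matches.tsv", sep="\t", index=False)
        log("seedmatch", f"{len(matches)} matches")
        if assoc is not None:
            calls = classify_interactions(assoc, matches)
            pd.DataFrame(
                [
                    {
                        "gene": c.gene,
                        "mirna": c.mirna,
                        "has_seed_match": c.has_seed_match,
                        "beta_sign": c.beta_sign,
                        "call": c.call,
                    }
                    for c in calls
                ]
            ).to_csv(out / "interaction_calls.tsv", sep="\t", index=False)
            log("seedmatch", f"{len(calls)} interaction calls")
        _provenance(out, "seedmatch", config,
                    [Path(config.mirna_fasta_path), Path(config.utr_fasta_path)])

    # --- survival ---------------------------------------------------------
    if config.survival and mirna_diff is not None:
        for cohort in config.survival_cohorts:
            try:
                res = run_survival(
                    meta, mirna_diff, cohort=cohort,
                    n_perm=config.n_perm, rng_seed=config.rng_seed,
                )
            except ValidationError as exc:
                log("survival", f"cohort {cohort}: skipped ({exc})")
                continue
            pd.DataFrame(
                [
                    {
                        "mirna": r.mirna,
                        "q1": round(r.q1, 2),
                        "q3": round(r.q3, 2),
                        "hr_iqr": round(r.hr_iqr, 2),
                        "ci_low": round(r.ci_low, 2),
                        "ci_high": round(r.ci_high, 2),
                        "perm_p": r.perm_p,
                        "q_value": r.q_value,
                        "fdr_p": r.fdr_p,
                    }
                    for r in res
                ]
            ).to_csv(out / f"survival_{cohort}.tsv", sep="\t", index=False)
            log("survival", f"cohort {cohort}: {len(res)} miRNAs")
        _provenance(out, "survival", config, [out / "mirna_differential.tsv"])

    # --- cohort report ----------------------------------------------------
    make_cohort_report(meta).to_csv(out / "cohort_report.tsv", sep="\t", index=False)
    log("report", f"{len({m.subject_id for m in meta})} subjects")
    (out / "run.log").write_text("".join(line + "\n" for line in log_lines))
    return out


def _diff_matrix(truth) -> ExpressionMatrix:
    return ExpressionMatrix(truth.mirna_differential, MatrixKind.DIFFERENTIAL)


def _mirna_de_from_means(mirna_scaled: ExpressionMatrix, meta) -> list[DEResult]:
    """Descriptive DE results (means and FC only) for miRNAs, used by the
    fold-change filter of the association screen."""
    from .diffexp import summarize_fc

    out = []
    for mir in mirna_scaled.feature_ids:
        tm, nm, fc = summarize_fc(mirna_scaled, meta, mir)
        out.append(DEResult(mir, tm, nm, fc, float("nan"), 1.0, 1.0))
    return out
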