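"""Readers/writers for the pipeline's tabular formats, run configuration
and the end-to-end orchestrator.

All matrices are plain delimited text: first column = feature id, header
row = sample ids; "NA" or empty fields are missing. Phenotypes are a CSV
with one row per sample. Gene annotation is BED-like (chrom, start, end,
gene). Every pipeline stage writes its result table plus a JSON manifest
(seed, thresholds, input/output counts, library versions) so a run can
be reproduced from its output directory alone.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_phenotypes",
    "validate_cohort",
    "read_annotation",
    "read_gene_bed",
    "write_bundle",
    "RunConfig",
    "load_config",
    "run_pipeline",
]

REQUIRED_PHENOTYPE_COLUMNS = (
    "age",
    "sex",
    "smoking_status",
    "pack_years",
    "stage",
    "histology",
    "center",
    "time",
    "event",
)


class ConfigError(ValueError):
    """Invalid run configuration (maps to CLI exit code 2)."""


def _sep_for(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_matrix(path, kind: str = "beta") -> pd.DataFrame:
    """Read a feature x sample matrix, validating values per kind.

    kind="beta" and kind="detection" require values in [0, 1];
    kind="expression" is unconstrained. Duplicated feature or sample ids
    are rejected; out-of-range entries are reported with their row and
    column ids.
    """
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, na_values=["NA", ""])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][:5].tolist()
        raise ValueError(f"duplicated feature ids in {path}: {dup}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][:5].tolist()
        raise ValueError(f"duplicated sample ids in {path}: {dup}")
    vals = df.to_numpy(dtype=float)
    if kind in ("beta", "detection"):
        bad = (vals < 0) | (vals > 1)
        bad &= ~np.isnan(vals)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{kind} value out of [0, 1] at probe {df.index[i]!r}, "
                f"sample {df.columns[j]!r}: {vals[i, j]}"
            )
    return df.astype(float)


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep=_sep_for(path), na_rep="NA")


def validate_cohort(pheno: pd.DataFrame, require_survival: bool = True) -> pd.DataFrame:
    """Check phenotype invariants; returns the validated frame.

    time > 0; event in {0, 1}; smoking levels in {never, ever, current};
    never-smokers must have pack_years == 0 (when non-missing).
    """
    missing = [c for c in REQUIRED_PHENOTYPE_COLUMNS if c not in pheno.columns]
    if not require_survival:
        missing = [c for c in missing if c not in ("time", "event")]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    if pheno.index.duplicated().any():
        raise ValueError("duplicated sample ids in phenotype table")
    levels = set(pheno["smoking_status"].astype(str)) - {"never", "ever", "current"}
    if levels:
        raise ValueError(f"unknown smoking_status levels {sorted(levels)}")
    never = pheno["smoking_status"] == "never"
    py = pheno["pack_years"]
    bad = never & py.notna() & (py != 0)
    if bad.any():
        raise ValueError(
            f"never-smokers with nonzero pack_years: {pheno.index[bad][:5].tolist()}"
        )
    if require_survival:
        if (pheno["time"] <= 0).any():
            raise ValueError("survival times must be > 0")
        if not pheno["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")
    return pheno


def read_phenotypes(path, require_survival: bool = True) -> pd.DataFrame:
    pheno = pd.read_csv(path, index_col=0, na_values=["NA", ""])
    return validate_cohort(pheno, require_survival=require_survival)


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    for col in ("snp_flag", "cross_reactive"):
        if col not in ann.columns:
            raise ValueError(f"probe annotation missing column {col!r}")
    return ann


def read_gene_bed(path) -> pd.DataFrame:
    genes = pd.read_csv(path, sep="\t", header=None).iloc[:, :4]
    genes.columns = ["chrom", "start", "end", "gene"]
    return genes


def write_bundle(bundle, outdir) -> None:
    """Persist a synthetic bundle as plain-text tables + truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(bundle.beta, out / "beta.tsv")
    write_matrix(bundle.detection_p, out / "detection_p.tsv")
    bundle.cohort.to_csv(out / "phenotypes.csv")
    bundle.annotation.to_csv(out / "annotation.tsv", sep="\t")
    if bundle.expression is not None:
        write_matrix(bundle.expression, out / "expression.tsv")
    if bundle.gene_annotation is not None:
        bundle.gene_annotation.to_csv(out / "genes.bed", sep="\t", header=False, index=False)
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2))


@dataclass
class PhaseFiles:
    beta: str
    phenotypes: str
    detection: str | None = None
    annotation: str | None = None
    expression: str | None = None
    gene_annotation: str | None = None


@dataclass
class RunConfig:
    discovery: PhaseFiles
    validation: PhaseFiles
    out_dir: str
    exposure: str = "pack_years"
    fixed_probes: tuple = ()
    max_order: int = 4
    scheme: str = "full_factorial"
    ties: str = "efron"
    fdr_level: float = 0.05
    validation_p: float = 0.05
    horizons: tuple = (3.0, 5.0)
    cv_threshold: float = 0.05
    detection_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name, v in (
            ("fdr_level", self.fdr_level),
            ("validation_p", self.validation_p),
            ("cv_threshold", self.cv_threshold),
            ("detection_threshold", self.detection_threshold),
        ):
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1), got {v}")
        if any(h <= 0 for h in self.horizons):
            raise ConfigError("horizons must be > 0")
        if self.max_order < 2:
            raise ConfigError("max_order must be >= 2")
        for phase in (self.discovery, self.validation):
            for attr in ("beta", "phenotypes", "detection", "annotation", "expression"):
                p = getattr(phase, attr, None)
                if p is not None and not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text())
    try:
        disc = PhaseFiles(**raw.pop("discovery"))
        valid = PhaseFiles(**raw.pop("validation"))
        cfg = RunConfig(discovery=disc, validation=valid, **raw)
    except (KeyError, TypeError) as exc:
        raise ConfigError(f"malformed run config: {exc}") from exc
    if isinstance(cfg.fixed_probes, list):
        cfg.fixed_probes = tuple(cfg.fixed_probes)
    if isinstance(cfg.horizons, list):
        cfg.horizons = tuple(cfg.horizons)
    cfg.validate()
    return cfg


def _manifest(stage: str, cfg: RunConfig, counts: dict) -> dict:
    cfg_text = json.dumps(
        {k: str(v) for k, v in vars(cfg).items()}, sort_keys=True, default=str
    )
    return {
        "stage": stage,
        "seed": cfg.seed,
        "config_sha1": hashlib.sha1(cfg_text.encode()).hexdigest(),
        "fdr_level": cfg.fdr_level,
        "validation_p": cfg.validation_p,
        "counts": counts,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "finished_utc": _time.strftime("%Y-%m-%dT%H:%M:%SZ", _time.gmtime()),
    }


def _load_phase(files: PhaseFiles):
    beta = read_matrix(files.beta, "beta")
    pheno = read_phenotypes(files.phenotypes)
    det = read_matrix(files.detection, "detection") if files.detection else None
    ann = read_annotation(files.annotation) if files.annotation else None
    expr = read_matrix(files.expression, "expression") if files.expression else None
    genes = read_gene_bed(files.gene_annotation) if files.gene_annotation else None
    shared = [s for s in pheno.index if s in beta.columns]
    return beta[shared], pheno.loc[shared], det[shared] if det is not None else None, ann, expr, genes


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute qc -> scan -> two-phase -> score -> evaluation -> cis.

    Stage failures abort with the stage name; completed stages persist
    their outputs. Re-running the same config reproduces identical
    tables (all stages are deterministic given the config seed).
    """
    from . import expression as expr_mod
    from . import qc as qc_mod
    from .evaluate import nested_models
    from .scan import fit_interaction_model, hill_climb
    from .terms import term_name
    from .triune import group_hazard_ratios, km_curve, risk_scores

    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        disc = _load_phase(cfg.discovery)
        valid = _load_phase(cfg.validation)

        stage = "qc"
        phases = {}
        for name, (beta, pheno, det, ann, expr, genes) in (
            ("discovery", disc),
            ("validation", valid),
        ):
            keep, sreport = qc_mod.filter_samples(beta, det, pheno)
            beta, pheno = beta[keep], pheno.loc[keep]
            det = det[keep] if det is not None else None
            fbeta, preport = qc_mod.filter_probes(
                beta,
                det,
                ann,
                pheno["center"],
                cv_threshold=cfg.cv_threshold,
                detection_p_threshold=cfg.detection_threshold,
            )
            preport.table.to_csv(out / f"qc_probes_{name}.tsv", sep="\t")
            sreport.table.to_csv(out / f"qc_samples_{name}.tsv", sep="\t")
            phases[name] = (fbeta, pheno, ann, expr, genes)
        (out / "manifest_qc.json").write_text(
            json.dumps(
                _manifest(
                    "qc",
                    cfg,
                    {
                        name: {"probes": len(phases[name][0]), "samples": phases[name][0].shape[1]}
                        for name in phases
                    },
                ),
                indent=2,
            )
        )

        stage = "scan"
        beta_d, pheno_d = phases["discovery"][:2]
        beta_v, pheno_v = phases["validation"][:2]
        shared_probes = beta_d.index.intersection(beta_v.index)
        beta_d, beta_v = beta_d.loc[shared_probes], beta_v.loc[shared_probes]
        audit = hill_climb(
            pheno_d,
            beta_d,
            pheno_v,
            beta_v,
            cfg.exposure,
            max_order=cfg.max_order,
            initial_winners=cfg.fixed_probes,
            scheme=cfg.scheme,
            ties=cfg.ties,
            q_threshold=cfg.fdr_level,
            p_threshold=cfg.validation_p,
        )
        for k, tables in audit["orders"].items():
            tables["scan"].to_csv(out / f"scan_order{k}.tsv", sep="\t")
            tables["decisions"].to_csv(out / f"decisions_order{k}.tsv", sep="\t")
        winners = audit["winners"]
        (out / "manifest_scan.json").write_text(
            json.dumps(_manifest("scan", cfg, {"winners": winners}), indent=2)
        )
        if len(winners) < 3:
            (out / "manifest_run.json").write_text(
                json.dumps(
                    _manifest("run", cfg, {"status": "stopped", "winners": winners}),
                    indent=2,
                )
            )
            return out

        stage = "triune"
        comb_pheno = pd.concat(
            [
                pheno_d.assign(center="disc_" + pheno_d["center"].astype(str)),
                pheno_v.assign(center="valid_" + pheno_v["center"].astype(str)),
            ]
        )
        comb_beta = pd.concat([beta_d, beta_v], axis=1)
        fit, spec = fit_interaction_model(
            comb_pheno, comb_beta, cfg.exposure, winners[:3], scheme=cfg.scheme, ties=cfg.ties
        )
        (out / "fit_four_way.json").write_text(fit.to_json())
        scores = risk_scores(fit, comb_pheno, comb_beta, spec)
        scores.to_csv(out / "triune_scores.csv")
        hr_table = group_hazard_ratios(comb_pheno, scores["group"].to_numpy())
        hr_table.to_csv(out / "group_hazard_ratios.csv")
        km_rows = []
        for g in sorted(scores["group"].unique()):
            mask = (scores["group"] == g).to_numpy()
            curve = km_curve(
                comb_pheno["time"].to_numpy()[mask], comb_pheno["event"].to_numpy()[mask]
            )
            frame = curve.to_frame()
            frame.insert(0, "group", g)
            km_rows.append(frame)
        pd.concat(km_rows).to_csv(out / "km_by_group.tsv", sep="\t", index=False)
        (out / "manifest_triune.json").write_text(
            json.dumps(_manifest("triune", cfg, {"n_scored": len(scores)}), indent=2)
        )

        stage = "evaluate"
        comp = nested_models(
            comb_pheno, comb_beta, winners[:3], cfg.exposure, horizons=cfg.horizons
        )
        comp.summary().to_csv(out / "model_comparison.csv", index=False)
        comp.aucs.to_csv(out / "model_aucs.csv")
        pd.Series(comp.c_indices, name="c_index").to_csv(out / "model_cindex.csv")
        (out / "manifest_evaluate.json").write_text(
            json.dumps(
                _manifest("evaluate", cfg, {"horizons": list(cfg.horizons)}), indent=2
            )
        )

        stage = "cis"
        expr_d = phases["discovery"][3]
        ann_d = phases["discovery"][2]
        genes_d = phases["discovery"][4]
        if expr_d is not None and ann_d is not None and genes_d is not None:
            corr = expr_mod.methylation_expression_correlation(
                beta_d, expr_d, pheno_d, probes=[p for p in winners[:3] if p in beta_d.index]
            )
            corr.to_csv(out / "meth_expr_correlation.tsv", sep="\t", index=False)
            cis = expr_mod.cis_candidates(ann_d, genes_d, corr)
            cis.to_csv(out / "cis_candidates.tsv", sep="\t", index=False)
        (out / "manifest_run.json").write_text(
            json.dumps(_manifest("run", cfg, {"status": "complete", "winners": winners}), indent=2)
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out
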