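"""End-to-end driver: simulate -> differential layers -> integration -> report.

The pipeline is a plain sequential orchestrator over the library.  One
top-level seed fans out to per-stage seeds via a stable hash of the stage
name, so any stage can be re-run in isolation; identical config + seed
yields a byte-identical report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .design import validate_design
from .expression import DifferentialExpressionModel
from .integration import (
    PROMOTER_CLASSES,
    concordance,
    count_dmegs,
    deg_dml_association,
    summarize_gene_methylation,
)
from .metabolites import MetaboliteEnrichmentModel
from .methylation import MethylationModel
from . import simulate as sim


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the run seed."""
    digest = hashlib.blake2s(f"{stage}:{int(base_seed)}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class PipelineConfig:
    """Every threshold and toggle the stages read; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "triomic_run"
    # stage toggles
    run_expression: bool = True
    run_metabolomics: bool = True
    run_methylation: bool = True
    # simulation sizes / conditions (defaults = the study layout)
    n_genes: int = 500
    frac_deg: float = 0.2
    expr_effect_sd: float = 2.0
    expr_noise_sd: float = 0.25
    n_metab: int = 200
    frac_dem: float = 0.25
    metab_effect_sd: float = 0.6
    metab_noise_sd: float = 0.15
    n_probes: int = 1000
    frac_dml: float = 0.1
    delta_beta: float = 20.0
    meth_noise_sd: float = 2.0
    fail_rate: float = 0.02
    outlier_rate: float = 0.02
    favor_prob: float = 0.6  # bias of planted probes toward DEG promoters
    # thresholds
    alpha: float = 0.05
    alpha_posthoc: float = 0.05
    floor: float = 0.01
    weighting: str = "hazard"
    error_pooling: str = "per_gene"
    effect_mode: str = "as_written"
    promoter_classes: list[str] = field(default_factory=lambda: list(PROMOTER_CLASSES))
    concordance_convention: str = "promoter_inverse"

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def fingerprint(self) -> str:
        """Hash of the scientific configuration (I/O location excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        payload = json.dumps(fields, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and write artifacts + report under out_dir.

    Returns the report dict (also written as ``report.json`` and
    ``report.md``).  All artifacts are written before the report.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "software": {"package": "triomic", "version": __version__},
        "config": asdict(config),
        "config_fingerprint": config.fingerprint(),
        "stages": {},
    }

    designs = []
    deg_res = None
    expr_study = None
    if config.run_expression:
        expr_study = sim.generate_expression(
            n_genes=config.n_genes,
            frac_deg=config.frac_deg,
            effect_sd=config.expr_effect_sd,
            noise_sd=config.expr_noise_sd,
            seed=stage_seed(config.seed, "expression"),
        )
        sim.write_expression(expr_study, out / "expression")
        designs.append(expr_study.design)
        model = DifferentialExpressionModel.from_study(
            expr_study,
            floor=config.floor,
            weighting=config.weighting,
            error_pooling=config.error_pooling,
            effect_mode=config.effect_mode,
        )
        deg_res = model.fit(alpha=config.alpha, alpha_posthoc=config.alpha_posthoc)
        deg_res.table.to_csv(out / "deg_table.tsv", sep="\t")
        report["stages"]["expression"] = {
            "n_features": int(len(deg_res.table)),
            "n_deg": deg_res.n_deg,
            "per_day": deg_res.day_counts().to_dict("index"),
            "intersection_all_days": int(len(deg_res.intersection_all_days())),
            "evaluation": deg_res.evaluate(expr_study.truth),
        }

    if config.run_metabolomics:
        metab_study = sim.generate_metabolomics(
            n_metab=config.n_metab,
            frac_dem=config.frac_dem,
            effect_sd=config.metab_effect_sd,
            noise_sd=config.metab_noise_sd,
            seed=stage_seed(config.seed, "metabolomics"),
        )
        sim.write_metabolomics(metab_study, out / "metabolomics")
        designs.append(metab_study.design)
        dem_res = MetaboliteEnrichmentModel.from_study(
            metab_study, floor=config.floor
        ).fit(alpha=config.alpha, alpha_posthoc=config.alpha_posthoc)
        dem_res.table.to_csv(out / "dem_table.tsv", sep="\t")
        report["stages"]["metabolomics"] = {
            "n_features": int(len(dem_res.table)),
            "n_dem": dem_res.n_dem,
            "threshold": dem_res.threshold,
            "per_day": dem_res.day_counts().to_dict("index"),
            "intersection_all_days": int(len(dem_res.intersection_all_days())),
            "evaluation": dem_res.evaluate(metab_study.truth),
        }

    dml_res = None
    if config.run_methylation:
        favor = None
        if deg_res is not None and config.favor_prob > 0:
            favor = list(expr_study.truth_any().index[expr_study.truth_any()])
        meth_study = sim.generate_methylation(
            n_probes=config.n_probes,
            frac_dml=config.frac_dml,
            delta_beta=config.delta_beta,
            noise_sd=config.meth_noise_sd,
            fail_rate=config.fail_rate,
            outlier_rate=config.outlier_rate,
            seed=stage_seed(config.seed, "methylation"),
            annotation=_gene_annotation_for(expr_study, config),
            favor_genes=favor,
            favor_prob=config.favor_prob if favor else 0.0,
            favor_classes=tuple(config.promoter_classes),
        )
        sim.write_methylation(meth_study, out / "methylation")
        designs.append(meth_study.design)
        dml_res = MethylationModel.from_study(meth_study).fit(
            alpha=config.alpha, alpha_posthoc=config.alpha_posthoc
        )
        dml_res.table.to_csv(out / "dml_table.tsv", sep="\t")
        dml_res.beta.beta.to_csv(out / "beta_post_qc.tsv", sep="\t")
        dml_res.beta.provenance.to_csv(out / "beta_provenance.tsv", sep="\t")
        qc = dml_res.beta.qc_summary
        report["stages"]["methylation"] = {
            "n_features": int(len(dml_res.table)),
            "n_dml": dml_res.n_dml,
            "qc": {
                "blocks": qc.n_blocks,
                "kept": qc.n_keep,
                "imputed": qc.n_imputed,
                "discarded": qc.n_discarded,
                "excluded_probes": len(qc.excluded_probes),
            },
            "per_day": dml_res.day_counts().to_dict("index"),
            "by_location_class": dml_res.location_class_counts().to_dict(),
            "evaluation": dml_res.evaluate(meth_study.truth),
        }

    verdict = validate_design(designs)
    report["design_check"] = {"ok": verdict.ok, "errors": verdict.errors}

    if deg_res is not None and dml_res is not None:
        integration: dict = {"per_day": {}}
        summaries = {}
        for d in deg_res.days:
            s = summarize_gene_methylation(
                dml_res.table,
                d,
                promoter_classes=tuple(config.promoter_classes),
                alpha_posthoc=config.alpha_posthoc,
            )
            summaries[d] = s
            n_dmeg, pct = count_dmegs(
                deg_res.table, s, d, alpha_posthoc=config.alpha_posthoc
            )
            conc = concordance(
                deg_res.table,
                s,
                d,
                scope="promoter",
                convention=config.concordance_convention,
                alpha_posthoc=config.alpha_posthoc,
            )
            integration["per_day"][d] = {
                "n_dmeg": n_dmeg,
                "pct_of_degs": pct,
                "concordance": conc.fraction,
                "concordance_quadrants": conc.quadrants,
            }
        universe = len(deg_res.table)
        cont = deg_dml_association(deg_res.table, summaries, universe_size=universe)
        integration["contingency"] = {
            "a": cont.a,
            "b": cont.b,
            "c": cont.c,
            "d": cont.d,
            "odds_ratio": cont.odds_ratio,
            "corrected": cont.corrected,
            "chi2": cont.chi2,
            "p": cont.p,
        }
        report["integration"] = integration
        for d, s in summaries.items():
            s.to_csv(out / f"gene_methylation_day{d}.tsv", sep="\t")

    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_json_default)
    )
    (out / "report.md").write_text(render_report_md(report))
    return report


def _json_default(obj):
    """Coerce numpy scalars for JSON serialisation."""
    if hasattr(obj, "item"):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _gene_annotation_for(expr_study, config: PipelineConfig):
    """Gene annotation shared between the expression and methylation layers."""
    n = config.n_genes if expr_study is not None else max(50, config.n_probes // 5)
    annot = sim.generate_annotation(
        n_genes=n,
        genome_length=max(10_000_000, n * 10_000),
        seed=stage_seed(config.seed, "annotation"),
    )
    if expr_study is not None:
        # use the expression gene ids so the layers share a universe
        annot.table["gene_id"] = list(expr_study.rpkm.index[: len(annot.table)])
    return annot


def render_report_md(report: dict) -> str:
    lines = [
        "# Pipeline report",
        "",
        f"- package: {report['software']['package']} {report['software']['version']}",
        f"- config fingerprint: `{report['config_fingerprint']}`",
        "",
    ]
    for stage, info in report.get("stages", {}).items():
        lines.append(f"## {stage}")
        for key, val in info.items():
            if key == "per_day":
                for d, counts in val.items():
                    lines.append(f"- day {d}: {counts}")
            else:
                lines.append(f"- {key}: {val}")
        lines.append("")
    if "integration" in report:
        lines.append("## integration")
        for d, info in report["integration"]["per_day"].items():
            lines.append(f"- day {d}: {info}")
        lines.append(f"- contingency: {report['integration']['contingency']}")
        lines.append("")
    check = report.get("design_check", {})
    lines.append(f"design check ok: {check.get('ok')}")
    return "\n".join(lines) + "\n"
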