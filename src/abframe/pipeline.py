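"""One-shot reproducible run: simulate -> design -> fit -> stats -> report."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import dsf, germline, io, kabat, pk, sec, spr, stats
from .simulate import (
    AssaySuite,
    GeneratorConfig,
    PanelBundle,
    generate_assay_suite,
    generate_pk_study,
    generate_variant_panel,
)

log = logging.getLogger("abframe")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "abframe_run"
    t_end_h: float = 144.0
    spearman_alternative: str = "greater"
    tm_method: str = "derivative"
    retention_windows: Optional[Dict[str, list]] = None
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)

    def __post_init__(self):
        if isinstance(self.generator, dict):
            self.generator = GeneratorConfig(**self.generator)
        self.generator = dataclasses.replace(self.generator, seed=self.seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls(**yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]


def _windows(config: RunConfig):
    if config.retention_windows is None:
        return None
    return {k: tuple(v) for k, v in config.retention_windows.items()}


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full germline-design and assay-analysis workflow.

    Deterministic given `config.seed`; writes the germline report, variant
    panel, per-assay fit tables, PK parameters, statistics and a summary
    document under `config.outdir` and returns the summary dict.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("run start: config hash %s", config.config_hash())
    (outdir / "config.yaml").write_text(config.to_yaml())

    # --- design ---------------------------------------------------------
    try:
        bundle: PanelBundle = generate_variant_panel(config.generator)
        match = bundle.match
        (outdir / "germline_report.json").write_text(
            germline.scan_report(bundle.parental, match))
        io.write_fasta(outdir / "variant_panel.fasta", [
            (f"{v.id}-{v.name}", v.sequence.sequence) for v in bundle.panel.variants
        ])
        panel_df = pd.DataFrame([
            {"id": v.id, "name": v.name,
             "germline_regions": "+".join(v.germline_regions) or "none",
             "c_terminal_lysine": v.c_terminal_lysine}
            for v in bundle.panel.variants
        ])
        panel_df.to_csv(outdir / "variant_panel.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("design", exc) from exc

    # --- assays ---------------------------------------------------------
    try:
        suite: AssaySuite = generate_assay_suite(config.generator, bundle.panel)
        spr_rows, tm_results = [], {}
        for variant in bundle.panel.variants:
            name = variant.name
            fit = spr.fit_langmuir_1to1(suite.sensorgrams[name])
            tm_results[name] = dsf.extract_tm(
                suite.melt_curves[name], method=config.tm_method)
            spr_rows.append({
                "name": name, "ka_per_m_s": fit.ka, "kd_per_s": fit.kd,
                "kD_m": fit.kD, "rmax_ru": fit.rmax, "rss": fit.rss,
            })
        spr_df = pd.DataFrame(spr_rows).set_index("name")
        spr_df.to_csv(outdir / "spr_fits.tsv", sep="\t")

        parental_tm = tm_results["DIQMAQ"]
        dsf_df = pd.DataFrame([
            {"name": n, "tm_c": r.tm,
             "delta_tm_c": dsf.delta_tm(r, parental_tm)}
            for n, r in tm_results.items()
        ]).set_index("name")
        dsf_df.to_csv(outdir / "dsf_tm.tsv", sep="\t")

        sec_summaries = {}
        for short, course in suite.chromatograms.items():
            weeks = [w for w, _ in course]
            tables = [sec.quantify_species(tr, _windows(config)) for _, tr in course]
            summary = sec.summarize_timecourse(
                sec.StabilityTimeCourse(weeks, tables))
            summary.insert(0, "name", short)
            sec_summaries[short] = summary
        sec_df = pd.concat(sec_summaries.values())
        sec_df.to_csv(outdir / "sec_timecourse.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assays", exc) from exc

    # --- pharmacokinetics ----------------------------------------------
    try:
        study = generate_pk_study(config.generator)
        pk_rows = []
        for (antibody, dose), data in study.items():
            fit, selection = pk.select_decay_model(data)
            import warnings as _warnings
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                params = pk.nca(data, fit, t_end=config.t_end_h)
            pk_rows.append({
                "antibody": antibody, "dose_mg_per_kg": dose,
                "model": fit.model,
                "f_p_value": selection.p_value if selection else float("nan"),
                "c0_mg_per_l": params.c0_mg_per_l,
                "t_half_beta_h": params.t_half_beta_h,
                "auc_mg_h_per_l": params.auc_mg_h_per_l,
                "cl_ml_per_h_per_kg": params.cl_ml_per_h_per_kg,
                "mrt_h": params.mrt_h,
                "vdss_ml_per_kg": params.vdss_ml_per_kg,
            })
        pk_df = pd.DataFrame(pk_rows)
        pk_df.to_csv(outdir / "pk_parameters.tsv", sep="\t", index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("pharmacokinetics", exc) from exc

    # --- statistics -----------------------------------------------------
    try:
        summaries = [
            stats.VariantSummary(
                name=name,
                titer_replicates=suite.titers[name],
                tm=tm_results[name].tm,
                kD=float(spr_df.loc[name, "kD_m"]),
            )
            for name in spr_df.index
        ]
        corr = stats.spearman_tm_titer(
            summaries, alternative=config.spearman_alternative)
        anova = stats.anova_tukey({s.name: list(s.titer_replicates)
                                   for s in summaries})
        folds = stats.fold_check(
            {s.name: s.kD for s in summaries}, reference="DIQMAQ", bound=2.0)
        stats_payload = {
            "spearman_tm_titer": {
                "rho": corr.rho, "p_value": corr.p_value, "n": corr.n,
                "method": corr.p_method, "alternative": corr.alternative,
            },
            "anova": {"F": anova.f_statistic, "p_value": anova.p_value,
                      "normality_p": anova.normality_p},
            "kd_fold_check": {"max_fold": folds.max_fold,
                              "max_variant": folds.max_variant,
                              "passed": folds.passed},
        }
        (outdir / "stats.json").write_text(json.dumps(stats_payload, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise StageError("statistics", exc) from exc

    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "germline": {
            "gene": match.germline_id,
            "framework_identity_pct": round(match.framework_identity, 2),
            "mutation_regions": [r.label for r in bundle.regions],
        },
        "n_variants": len(bundle.panel.variants),
        "variants": bundle.panel.full_names(),
        "n_pk_arms": len(study),
        "kd_max_fold_vs_parental": round(folds.max_fold, 3),
        "tm_max_shift_c": round(
            max(dsf_df["delta_tm_c"]), 2),
        "spearman_p": round(corr.p_value, 4),
        "pk": pk_df.round(3).to_dict(orient="records"),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    log.info("run complete: %d variants, %d PK arms",
             summary["n_variants"], summary["n_pk_arms"])
    return summary
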