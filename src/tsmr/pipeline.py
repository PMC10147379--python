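"""End-to-end analysis orchestration and report shaping.

For each exposure x outcome pair: significance selection, LD clumping,
harmonization, the four combined estimators plus per-SNP Wald ratios,
heterogeneity statistics, the measurement-error diagnostic with a
conditional SIMEX-corrected Egger fit, and a conditional outlier analysis
with corrected IVW.  The pipeline adds no computation of its own; it wires
the module operations together, records every gate decision and seed, and
shapes the results into estimate/diagnostic/audit report tables.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import diagnostics as diag
from . import estimators as est
from .harmonize import HarmonizedSet, harmonize
from .instruments import LDMatrix, greedy_clump, instrument_stats, select_genomewide
from .sumstats import SummaryStatsTable, load_column_map, read_sumstats, write_report

__all__ = [
    "PipelineSettings",
    "AnalysisConfig",
    "AnalysisResult",
    "ReportBundle",
    "run_analysis",
    "format_table",
    "write_bundle",
    "load_analysis_config",
]


@dataclass
class PipelineSettings:
    """Thresholds, estimator options, and seeds for one pipeline run."""

    p_select: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: int = 10_000
    palindrome_maf: float = 0.3
    se_method: str = "first_order"
    ivw_model: str = "multiplicative_random_effects"
    n_boot: int = 1000
    mode_phi: float = 1.0
    simex_lambdas: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)
    simex_n_sim: int = 200
    i2_simex_threshold: float = 0.90  # SIMEX runs when I2 falls below this
    presso_q_gate: float | None = 0.05  # outlier analysis runs when Q p < gate
    presso_n_distributions: int = 1000
    presso_sig_threshold: float = 0.05
    seed: int = 0
    run_egger: bool = True
    run_median: bool = True
    run_mode: bool = True


@dataclass
class TableSpec:
    """Where one summary-statistics table comes from (path or in-memory)."""

    name: str
    trait_type: str = "continuous"
    path: str | None = None
    column_map: dict | None = None
    unit_note: str = ""
    table: SummaryStatsTable | None = None

    def load(self) -> SummaryStatsTable:
        if self.table is not None:
            return self.table
        if self.path is None:
            raise ValueError(f"table spec {self.name!r} has neither path nor table")
        return read_sumstats(
            self.path,
            column_map=self.column_map,
            trait_name=self.name,
            trait_type=self.trait_type,
            unit_note=self.unit_note,
        )


@dataclass
class AnalysisConfig:
    exposure: TableSpec
    outcomes: list[TableSpec]
    ld: LDMatrix | None = None
    settings: PipelineSettings = field(default_factory=PipelineSettings)


@dataclass
class AnalysisResult:
    exposure_name: str
    outcome_name: str
    status: str  # "ok" or "no instrument"
    n_snps: int
    estimates: dict[str, est.MREstimate]
    egger_intercept: est.EggerIntercept | None
    simex: est.EggerResult | None
    q_ivw: diag.QStats | None
    q_egger: diag.QStats | None
    i2_gx: float | None
    presso: diag.PressoResult | None
    instrument: object
    harmonization_audit: dict
    scatter: list[dict]
    scale: str
    log: list[str]


@dataclass
class ReportBundle:
    analyses: list[AnalysisResult]
    settings: PipelineSettings

    def estimates_rows(self) -> list[dict]:
        rows = []
        for a in self.analyses:
            for name, e in a.estimates.items():
                rows.append(
                    {
                        "exposure": a.exposure_name,
                        "outcome": a.outcome_name,
                        "method": name,
                        "n_snps": e.n_snps,
                        "beta": e.beta,
                        "se": e.se,
                        "ci_low": e.ci_low,
                        "ci_high": e.ci_high,
                        "pval": e.pval,
                        "scale": e.scale,
                        **(
                            {
                                "or": math.exp(e.beta),
                                "or_ci_low": math.exp(e.ci_low),
                                "or_ci_high": math.exp(e.ci_high),
                            }
                            if e.scale == "log_or"
                            else {}
                        ),
                    }
                )
        return rows

    def diagnostics_rows(self) -> list[dict]:
        rows = []
        for a in self.analyses:
            row: dict = {
                "exposure": a.exposure_name,
                "outcome": a.outcome_name,
                "status": a.status,
                "n_snps": a.n_snps,
            }
            if a.q_ivw is not None:
                row.update(q_ivw=a.q_ivw.q, q_ivw_df=a.q_ivw.df, q_ivw_pval=a.q_ivw.pval)
            if a.q_egger is not None:
                row.update(q_egger=a.q_egger.q, q_egger_df=a.q_egger.df, q_egger_pval=a.q_egger.pval)
            if a.egger_intercept is not None:
                row.update(
                    egger_intercept=a.egger_intercept.beta,
                    egger_intercept_se=a.egger_intercept.se,
                    egger_intercept_pval=a.egger_intercept.pval,
                )
            if a.i2_gx is not None:
                row["i2_gx"] = a.i2_gx
                row["simex_triggered"] = a.simex is not None
            if a.simex is not None:
                row.update(simex_slope=a.simex.slope.beta, simex_slope_pval=a.simex.slope.pval)
            if a.presso is not None:
                row.update(
                    presso_global_pval=a.presso.global_pval,
                    presso_n_outliers=len(a.presso.outlier_indices),
                    presso_corrected_beta=a.presso.corrected_estimate.beta,
                    presso_corrected_pval=a.presso.corrected_estimate.pval,
                    presso_distortion_pval=a.presso.distortion_pval,
                )
            inst = a.instrument
            if inst is not None:
                row.update(
                    instrument_r2=inst.r2_total,
                    instrument_f_overall=inst.f_overall,
                    instrument_f_mean=(
                        float(np.mean(inst.f_per_snp)) if inst.f_per_snp else None
                    ),
                )
            rows.append(row)
        return rows


def _analyze_pair(
    hset: HarmonizedSet,
    exposure_name: str,
    outcome_name: str,
    inst_stats,
    s: PipelineSettings,
) -> AnalysisResult:
    log: list[str] = []
    k = hset.n_snps
    scale = hset.scale
    estimates: dict[str, est.MREstimate] = {}
    scatter = [
        {
            "snp_id": r.snp_id,
            "beta_exp": r.beta_exp,
            "se_exp": r.se_exp,
            "beta_out": r.beta_out,
            "se_out": r.se_out,
            "wald_beta": (r.beta_out / r.beta_exp) if r.beta_exp != 0 else float("nan"),
        }
        for r in hset.records
    ]

    if k == 0:
        return AnalysisResult(
            exposure_name, outcome_name, "no instrument", 0, {}, None, None, None,
            None, None, None, inst_stats, hset.audit, scatter, scale, ["no SNPs survived harmonization"],
        )

    estimates["ivw"] = est.ivw(hset, model=s.ivw_model)
    if k == 1:
        log.append("single SNP: IVW degenerates to the Wald ratio")

    egger = None
    simex = None
    q_egger = None
    i2 = None
    if s.run_egger and k >= 3:
        egger = est.mr_egger(hset)
        estimates["egger_slope"] = egger.slope
        q_egger = diag.cochran_q(hset, egger)
        i2 = est.i2_gx(hset)
        if i2 < s.i2_simex_threshold:
            log.append(f"I2={i2:.3f} < {s.i2_simex_threshold}: SIMEX Egger triggered")
            simex = est.simex_egger(
                hset, lambdas=s.simex_lambdas, n_sim=s.simex_n_sim, seed=s.seed
            )
            estimates["egger_simex"] = simex.slope
    if s.run_median and k >= 3:
        estimates["weighted_median"] = est.weighted_median(hset, n_boot=s.n_boot, seed=s.seed)
    if s.run_mode and k >= 3:
        estimates["weighted_mode"] = est.weighted_mode(
            hset, phi=s.mode_phi, n_boot=s.n_boot, seed=s.seed
        )

    q_ivw = diag.cochran_q(hset, estimates["ivw"]) if k >= 2 else None
    presso = None
    if (
        s.presso_q_gate is not None
        and q_ivw is not None
        and q_ivw.pval < s.presso_q_gate
        and k >= 4
    ):
        log.append(f"Q p={q_ivw.pval:.3g} < {s.presso_q_gate}: outlier analysis triggered")
        presso = diag.mr_presso(
            hset,
            n_distributions=s.presso_n_distributions,
            sig_threshold=s.presso_sig_threshold,
            seed=s.seed,
        )
        estimates["ivw_outlier_corrected"] = presso.corrected_estimate

    return AnalysisResult(
        exposure_name=exposure_name,
        outcome_name=outcome_name,
        status="ok",
        n_snps=k,
        estimates=estimates,
        egger_intercept=egger.intercept if egger else None,
        simex=simex,
        q_ivw=q_ivw,
        q_egger=q_egger,
        i2_gx=i2,
        presso=presso,
        instrument=inst_stats,
        harmonization_audit=hset.audit,
        scatter=scatter,
        scale=scale,
        log=log,
    )


def run_analysis(cfg: AnalysisConfig) -> ReportBundle:
    """Run the full battery for one exposure against each outcome."""
    s = cfg.settings
    exposure = cfg.exposure.load()
    selected = select_genomewide(exposure, s.p_select)
    if cfg.ld is not None:
        selected = greedy_clump(selected, cfg.ld, s.clump_r2, s.clump_window_kb)
    try:
        inst_stats = instrument_stats(selected)
    except ValueError:
        inst_stats = None

    analyses = []
    for out_spec in cfg.outcomes:
        outcome = out_spec.load()
        hset = harmonize(selected, outcome, s.palindrome_maf)
        analyses.append(
            _analyze_pair(hset, exposure.trait_name, outcome.trait_name, inst_stats, s)
        )
    return ReportBundle(analyses=analyses, settings=s)


def _fmt_or(e: est.MREstimate) -> tuple[str, str]:
    o, lo, hi = math.exp(e.beta), math.exp(e.ci_low), math.exp(e.ci_high)
    return f"{o:.2f} ({lo:.2f}, {hi:.2f})", f"{e.pval:.2f}"


def _fmt_beta(e: est.MREstimate) -> tuple[str, str]:
    return f"{e.beta:.2f} ({e.se:.2f})", f"{e.pval:.2f}"


def format_table(bundle: ReportBundle, style: str = "table1") -> list[dict]:
    """Shape the bundle as report rows.

    ``table1``: one row per exposure x outcome with OR (95% CI) and p per
    combined estimator (beta (SE) formatting for continuous outcomes).
    ``supp2``: the diagnostics block (heterogeneity, intercepts, outliers,
    corrected estimates, instrument strength).
    """
    if not bundle.analyses:
        raise ValueError("empty report bundle")
    if style == "supp2":
        return bundle.diagnostics_rows()
    if style != "table1":
        raise ValueError(f"unknown style {style!r}")
    rows = []
    methods = ("ivw", "weighted_median", "weighted_mode", "egger_slope")
    for a in bundle.analyses:
        row = {
            "exposure": a.exposure_name,
            "outcome": a.outcome_name,
            "n_snps": a.n_snps,
            "status": a.status,
        }
        fmt = _fmt_or if a.scale == "log_or" else _fmt_beta
        label = "or_95ci" if a.scale == "log_or" else "beta_se"
        for m in methods:
            if m in a.estimates:
                val, p = fmt(a.estimates[m])
            else:
                val, p = "NA", "NA"
            row[f"{m}_{label}"] = val
            row[f"{m}_pval"] = p
        rows.append(row)
    return rows


def write_bundle(bundle: ReportBundle, out_dir: str | Path, fmt: str = "tsv") -> None:
    """Write estimates, diagnostics, formatted tables, audit, and scatter data."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_report(bundle.estimates_rows(), out_dir / f"estimates.{fmt}", format=fmt)
    write_report(bundle.diagnostics_rows(), out_dir / f"diagnostics.{fmt}", format=fmt)
    write_report(format_table(bundle, "table1"), out_dir / f"table1.{fmt}", format=fmt)
    audit = {
        f"{a.exposure_name}~{a.outcome_name}": {
            "status": a.status,
            "harmonization": a.harmonization_audit,
            "log": a.log,
        }
        for a in bundle.analyses
    }
    with open(out_dir / "audit.json", "w") as fh:
        json.dump(audit, fh, indent=1)
    for a in bundle.analyses:
        if a.scatter:
            name = f"scatter_{a.exposure_name}_{a.outcome_name}.{fmt if fmt != 'json' else 'tsv'}"
            write_report(a.scatter, out_dir / name, format="tsv" if fmt == "json" else fmt)


def load_analysis_config(path: str | Path) -> AnalysisConfig:
    """Build an AnalysisConfig from a YAML or JSON document.

    Expected keys: ``exposure`` and ``outcomes`` (each with ``path``,
    ``name``, ``trait_type``, optional ``column_map`` inline or as a file
    path, optional ``unit_note``), optional ``ld`` (``path`` +
    ``format: square|long``), optional ``settings`` overriding any
    :class:`PipelineSettings` field.  Relative paths resolve against the
    config file's directory.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    base = path.parent

    def _resolve(p: str | None) -> str | None:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    def _spec(d: dict) -> TableSpec:
        cmap = d.get("column_map")
        if isinstance(cmap, str):
            cmap = load_column_map(_resolve(cmap))
        return TableSpec(
            name=d["name"],
            trait_type=d.get("trait_type", "continuous"),
            path=_resolve(d.get("path")),
            column_map=cmap,
            unit_note=d.get("unit_note", ""),
        )

    ld = None
    if "ld" in doc and doc["ld"]:
        ld_doc = doc["ld"]
        ld_path = _resolve(ld_doc["path"])
        if ld_doc.get("format", "square") == "long":
            ld = LDMatrix.from_long_tsv(ld_path)
        else:
            ld = LDMatrix.from_square_tsv(ld_path)

    settings = PipelineSettings(**{
        k: (tuple(v) if k == "simex_lambdas" else v)
        for k, v in doc.get("settings", {}).items()
    })
    return AnalysisConfig(
        exposure=_spec(doc["exposure"]),
        outcomes=[_spec(d) for d in doc["outcomes"]],
        ld=ld,
        settings=settings,
    )
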