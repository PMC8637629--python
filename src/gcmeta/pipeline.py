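"""End-to-end pipeline: validate -> HWE screen -> effects -> heterogeneity
-> model selection -> pooling -> leave-one-out -> funnel + Egger.

The pipeline writes one machine-readable report (``report.json``, full
precision) plus a rounded narrative (``report.md``) and three plot-ready
tables: ``forest.tsv`` (per-study ORs, CIs, weights), ``sensitivity.tsv``
(leave-one-out pools) and ``funnel.tsv`` (+ ``funnel_boundary.tsv``).
The JSON is a serialization of the in-memory results, never a
recomputation, so two runs on the same input are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import bias_sensitivity as bias
from . import dataset, effects as eff, hwe as hwe_mod, meta

log = logging.getLogger("gcmeta")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline settings; the defaults are the standard thresholds of the
    genetic-association meta-analysis literature (HWE screen 0.001,
    heterogeneity rule p_Q < 0.1 with I2 > 50%, Z-test at 0.05, Egger at
    0.01) and reproduce the bundled worked example."""

    input: str = "bundled"                 # path or the "bundled" keyword
    orientation: str = "t_vs_c"            # or "c_vs_t" to flip the effect allele
    correction: eff.Correction = "add_half_if_zero"
    alpha: float = 0.05
    q_p_threshold: float = 0.1
    i2_threshold: float = 50.0
    hwe_threshold: float = 0.001
    egger_alpha: float = 0.01
    outdir: str = "gcmeta_out"
    verbose: bool = False


@dataclass
class RunReport:
    """Everything the pipeline computed, ready to serialize."""

    config: RunConfig
    table: dataset.StudyTable
    hwe: list[hwe_mod.HweResult]
    effects: list[eff.EffectEstimate]
    heterogeneity: meta.HeterogeneityResult
    pooled: meta.PooledResult
    leave_one_out: list[bias.LeaveOneOutEntry] | None
    funnel: bias.FunnelData | None
    egger: bias.EggerResult | None

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        # outdir/verbose are presentation settings, not analysis settings;
        # excluding them keeps report.json identical across output locations
        config = {
            k: v
            for k, v in plain(self.config).items()
            if k not in ("outdir", "verbose")
        }
        return {
            "config": config,
            "k": self.table.k,
            "n_cases": self.table.n_cases,
            "n_controls": self.table.n_controls,
            "hwe": plain(self.hwe),
            "effects": plain(self.effects),
            "heterogeneity": plain(self.heterogeneity),
            "pooled": plain(self.pooled),
            "leave_one_out": plain(self.leave_one_out),
            "egger": plain(self.egger),
        }


def _load_table(config: RunConfig) -> dataset.StudyTable:
    if config.input == "bundled":
        return dataset.bundled_table1()
    return dataset.read_study_table(config.input)


def _flip(table: dataset.StudyTable) -> dataset.StudyTable:
    """Swap which homozygote carries the effect allele (C vs T analysis)."""
    return dataset.StudyTable(
        tuple(
            dataset.StudyRecord(
                study_id=s.study_id,
                population=s.population,
                case=dataset.GenotypeCounts(cc=s.case.tt, ct=s.case.ct, tt=s.case.cc),
                control=dataset.GenotypeCounts(cc=s.control.tt, ct=s.control.ct, tt=s.control.cc),
            )
            for s in table
        )
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write the report bundle to ``config.outdir``."""
    level = logging.DEBUG if config.verbose else logging.INFO
    if not log.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("[gcmeta:%(levelname)s] %(message)s"))
        log.addHandler(handler)
    log.setLevel(level)

    table = _load_table(config)
    if config.orientation == "c_vs_t":
        table = _flip(table)
    elif config.orientation != "t_vs_c":
        raise ValueError(f"unknown orientation {config.orientation!r}")
    log.info("stage=load k=%d cases=%d controls=%d", table.k, table.n_cases, table.n_controls)

    with warnings.catch_warnings():
        warnings.simplefilter("always")
        hwe_results = hwe_mod.screen_controls(table, threshold=config.hwe_threshold)
    n_fail = sum(not r.passes for r in hwe_results)
    log.info("stage=hwe threshold=%g failures=%d (flagged only)", config.hwe_threshold, n_fail)

    effects = eff.study_effects(table, correction=config.correction, alpha=config.alpha)

    het = meta.heterogeneity(effects)
    model = meta.select_model(het, config.q_p_threshold, config.i2_threshold)
    log.info(
        "stage=heterogeneity Q=%.4f df=%d p=%.4f I2=%.1f%% -> %s-effect model",
        het.q, het.df, het.p_q, het.i2, model,
    )
    pooled = meta.pool_random(effects, alpha=config.alpha) if model == "random" else meta.pool_fixed(
        effects, alpha=config.alpha
    )
    log.info(
        "stage=pool model=%s OR=%.4f CI=%.4f-%.4f z=%.3f p=%.3g",
        pooled.model, pooled.or_, pooled.ci_low, pooled.ci_high, pooled.z, pooled.p,
    )

    if table.k >= 3:
        loo = bias.leave_one_out(
            table,
            correction=config.correction,
            alpha=config.alpha,
            p_threshold=config.q_p_threshold,
            i2_threshold=config.i2_threshold,
        )
        egger = bias.egger_test(effects, alpha=config.egger_alpha)
        log.info("stage=egger intercept=%.3f t=%.3f df=%d p=%.3f", egger.intercept, egger.t, egger.df, egger.p)
    else:
        loo, egger = None, None
        log.info("stage=sensitivity skipped: k=%d < 3", table.k)
    funnel = bias.funnel_points(effects, scale="or")

    report = RunReport(
        config=config,
        table=table,
        hwe=hwe_results,
        effects=effects,
        heterogeneity=het,
        pooled=pooled,
        leave_one_out=loo,
        funnel=funnel,
        egger=egger,
    )
    _write_outputs(report, Path(config.outdir))
    return report


def _fmt_p(p: float) -> str:
    if p < 1e-15:
        return "< 1e-15"
    return f"{p:.2g}"


def _write_outputs(report: RunReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)

    (outdir / "report.json").write_text(
        json.dumps(report.to_dict(), indent=2, allow_nan=True) + "\n", encoding="utf-8"
    )

    with (outdir / "forest.tsv").open("w", encoding="utf-8") as fh:
        fh.write("study_id\tor\tci_low\tci_high\tweight_pct\n")
        for e in report.effects:
            w = report.pooled.weights.get(e.study_id, float("nan")) * 100
            fh.write(f"{e.study_id}\t{e.or_:.6f}\t{e.ci_low:.6f}\t{e.ci_high:.6f}\t{w:.3f}\n")

    with (outdir / "sensitivity.tsv").open("w", encoding="utf-8") as fh:
        fh.write("omitted_study_id\tmodel\tor\tci_low\tci_high\tp\n")
        if report.leave_one_out is not None:
            for entry in report.leave_one_out:
                p = entry.pooled
                fh.write(
                    f"{entry.omitted_study_id}\t{p.model}\t{p.or_:.6f}\t"
                    f"{p.ci_low:.6f}\t{p.ci_high:.6f}\t{p.p:.6g}\n"
                )

    if report.funnel is not None:
        with (outdir / "funnel.tsv").open("w", encoding="utf-8") as fh:
            fh.write("study_id\tor\tse\n")
            for pt in report.funnel.points:
                fh.write(f"{pt.study_id}\t{pt.x:.6f}\t{pt.y:.6f}\n")
        with (outdir / "funnel_boundary.tsv").open("w", encoding="utf-8") as fh:
            fh.write("se\tlow\thigh\n")
            for s, lo, hi in zip(
                report.funnel.boundary_se, report.funnel.boundary_low, report.funnel.boundary_high
            ):
                fh.write(f"{s:.6f}\t{lo:.6f}\t{hi:.6f}\n")

    (outdir / "report.md").write_text(_render_markdown(report), encoding="utf-8")


def _render_markdown(report: RunReport) -> str:
    het, pooled = report.heterogeneity, report.pooled
    lines = [
        "# Meta-analysis report",
        "",
        f"Studies: {report.table.k} | cases: {report.table.n_cases:,} | "
        f"controls: {report.table.n_controls:,}",
        "",
        "## Hardy-Weinberg screen (controls)",
        "",
        "| study | chi2 | p | effect-allele freq | passes |",
        "|---|---|---|---|---|",
    ]
    for r in report.hwe:
        lines.append(
            f"| {r.study_id} | {r.chi2:.2f} | {_fmt_p(r.p)} | {r.effect_allele_freq:.3f} "
            f"| {'yes' if r.passes else 'NO'} |"
        )
    lines += [
        "",
        "## Per-study allele-model odds ratios (T vs C)",
        "",
        "| study | OR | 95% CI | weight |",
        "|---|---|---|---|",
    ]
    for e in report.effects:
        w = pooled.weights.get(e.study_id, float("nan")) * 100
        lines.append(f"| {e.study_id} | {e.or_:.2f} | {e.ci_low:.2f}-{e.ci_high:.2f} | {w:.1f}% |")
    lines += [
        "",
        "## Heterogeneity",
        "",
        f"Q = {het.q:.2f} on {het.df} df, p = {_fmt_p(het.p_q)}; "
        f"I2 = {het.i2:.0f}%; tau2 = {het.tau2:.4f}.",
        f"Model selected: **{pooled.model}-effect**.",
        "",
        "## Pooled association",
        "",
        f"OR = {pooled.or_:.2f}, 95% CI {pooled.ci_low:.2f}-{pooled.ci_high:.2f}, "
        f"Z = {pooled.z:.2f}, p = {_fmt_p(pooled.p)}.",
        "",
        "## Sensitivity (leave-one-out)",
        "",
    ]
    if report.leave_one_out is None:
        lines.append("not computed (k < 3)")
    else:
        lines += ["| omitted | OR | 95% CI |", "|---|---|---|"]
        for entry in report.leave_one_out:
            p = entry.pooled
            lines.append(f"| {entry.omitted_study_id} | {p.or_:.2f} | {p.ci_low:.2f}-{p.ci_high:.2f} |")
    lines += ["", "## Publication bias (Egger)", ""]
    if report.egger is None:
        lines.append("not computed (k < 3)")
    else:
        e = report.egger
        lines.append(
            f"intercept = {e.intercept:.2f} (SE {e.se_intercept:.2f}), t = {e.t:.2f} on {e.df} df, "
            f"p = {_fmt_p(e.p)} -> {'SIGNIFICANT' if e.significant else 'no significant bias'} "
            f"at {report.config.egger_alpha}."
        )
    lines.append("")
    return "\n".join(lines)
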