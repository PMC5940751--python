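"""End-to-end orchestration: instrument selection through MR, LD-score
regression, region scans and pleiotropy annotation, with variant-level
exclusion bookkeeping.

The workflow mirrors a standard two-sample MR study: select instruments in
the exposure GWAS, replace outcome-missing variants by LD proxies, harmonize
alleles, estimate per-variant Wald ratios, pool by fixed-effect IVW with
Cochran's Q, diagnose the dominant outlier by leave-one-out, refit without
it, and run Egger regression as the pleiotropy sensitivity analysis. Every
variant that enters is either analysed or excluded with a recorded reason —
the exclusion log is a first-class output because locus in/out decisions
carry the scientific story.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import mr
from .ldsc import LdscFit, read_ldscores, rg_regression
from .pairwise import RegionData, RegionModelPosteriors, ScanPriors, region_posteriors
from .sumstats import (
    DEFAULT_PALINDROME_WINDOW,
    GWS_ALPHA,
    HaplotypePanel,
    SumStatsTable,
    find_proxy,
    harmonization_report,
    harmonize,
    read_sumstats,
    select_instruments,
)

__all__ = [
    "AnalysisConfig",
    "AnnotationTable",
    "PipelineAbort",
    "MRWorkflowResult",
    "FullStudyResult",
    "run_mr_workflow",
    "annotate_pleiotropy",
    "run_full_study",
]


class PipelineAbort(RuntimeError):
    """Raised when a workflow cannot proceed (e.g. too few instruments)."""


@dataclass
class AnalysisConfig:
    """Flat, file-round-trippable configuration of a full study."""

    exposure_path: str = ""
    outcome_path: str = ""
    out_dir: str | None = None
    seed: int = 0
    selection_mode: str = "gws"  # gws | fdr
    gws_alpha: float = GWS_ALPHA
    fdr_q: float = 0.05
    maf_min: float = 0.05
    instruments: list[str] | None = None  # explicit list overrides selection
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW
    r2_min: float = 0.80
    wald_order: str = "first"
    panel_matrix_path: str | None = None
    panel_variants_path: str | None = None
    panel_vcf_path: str | None = None
    ldscore_path: str | None = None
    regions: list[str] = field(default_factory=list)  # "chrom:start-end"
    annotation_path: str | None = None
    annotation_alpha: float | None = None

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def load_panel(self) -> HaplotypePanel | None:
        if self.panel_vcf_path:
            return HaplotypePanel.from_vcf(self.panel_vcf_path)
        if self.panel_matrix_path and self.panel_variants_path:
            return HaplotypePanel.from_matrix_files(self.panel_matrix_path,
                                                    self.panel_variants_path)
        return None


@dataclass
class AnnotationTable:
    """Locally supplied variant -> (phenotype, p-value, source) associations,
    standing in for an online phenome-scan service."""

    df: pd.DataFrame  # columns: rsid, phenotype, pvalue, source

    def __post_init__(self) -> None:
        required = {"rsid", "phenotype", "pvalue"}
        if not required.issubset(self.df.columns):
            raise ValueError(f"annotation table needs columns {sorted(required)}")
        p = self.df["pvalue"].astype(float)
        if ((p <= 0) | (p > 1)).any():
            raise ValueError("annotation p-values must be in (0, 1]")
        if "source" not in self.df.columns:
            self.df = self.df.assign(source="")

    @classmethod
    def read(cls, path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t"))

    @property
    def n_phenotypes(self) -> int:
        return int(self.df["phenotype"].nunique())


@dataclass
class MRWorkflowResult:
    selected: list[str]
    analysed: list[str]
    exclusions: pd.DataFrame  # rsid, stage, reason
    pairs: list
    estimates: list
    fit_all: mr.MRFit | None
    loo: mr.LeaveOneOutResult | None
    fit_excluding: mr.MRFit | None
    egger_fit: mr.EggerFit | None
    results_table: pd.DataFrame
    forest_table: pd.DataFrame
    notices: list[str]
    proxies: dict[str, str]

    def accounted_for(self) -> bool:
        """Conservation check: every selected variant is analysed or excluded."""
        return set(self.selected) == set(self.analysed) | set(self.exclusions["rsid"])


def _results_row(label: str, k: int, theta: float, se: float, p: float,
                 q: float, df: int, p_het: float) -> dict:
    return {
        "analysis": label, "k": k,
        "or": float(np.exp(theta)),
        "ci_low": float(np.exp(theta - 1.96 * se)),
        "ci_high": float(np.exp(theta + 1.96 * se)),
        "p": p, "q": q, "df": df, "p_het": p_het,
    }


def run_mr_workflow(
    config: AnalysisConfig,
    exposure: SumStatsTable | None = None,
    outcome: SumStatsTable | None = None,
    panel: HaplotypePanel | None = None,
) -> MRWorkflowResult:
    """Execute the MR arm of the study and write its result tables.

    Tables may be passed in directly (e.g. straight from the simulator);
    otherwise they are read from the configured paths. Aborts with a
    diagnostic when fewer than 3 instruments survive harmonization under
    automatic selection; an explicit short instrument list instead degrades
    gracefully, skipping Q/leave-one-out/Egger with a notice.
    """
    notices: list[str] = []
    if exposure is None:
        exposure = read_sumstats(config.exposure_path, provenance="exposure")
    if outcome is None:
        outcome = read_sumstats(config.outcome_path, provenance="outcome")
    if panel is None:
        panel = config.load_panel()

    exclusions: list[dict] = []
    explicit = config.instruments is not None
    if explicit:
        selected = list(config.instruments)
        missing = [r for r in selected if r not in exposure]
        for r in missing:
            exclusions.append({"rsid": r, "stage": "selection", "reason": "absent from exposure table"})
        selected = [r for r in selected if r in exposure]
    else:
        sel = select_instruments(exposure, mode=config.selection_mode,
                                 gws_alpha=config.gws_alpha, fdr_q=config.fdr_q,
                                 maf_min=config.maf_min)
        selected = list(sel.rsids)
        for r in sel.low_maf:
            notices.append(f"{r}: minor allele frequency < {config.maf_min} (flagged, kept)")
    all_selected = list(selected) + [e["rsid"] for e in exclusions]

    # recessive-model variants require an input flag column (summary tables
    # do not encode the genetic model)
    if "recessive" in exposure.df.columns:
        recessive = set(exposure.df.index[exposure.df["recessive"].fillna(False).astype(bool)])
        for r in [r for r in selected if r in recessive]:
            exclusions.append({"rsid": r, "stage": "selection", "reason": "recessive-model"})
        selected = [r for r in selected if r not in recessive]

    # proxy search for instruments missing from the outcome study
    proxies: dict[str, str] = {}
    analysed_ids: list[str] = []
    for r in selected:
        if r in outcome:
            analysed_ids.append(r)
            continue
        if panel is None:
            exclusions.append({"rsid": r, "stage": "proxy",
                               "reason": "absent from outcome; proxy search disabled (no LD panel)"})
            continue
        if r not in panel:
            exclusions.append({"rsid": r, "stage": "proxy",
                               "reason": "absent from outcome and from LD panel"})
            continue
        candidates = outcome.subset([c for c in outcome.rsids if c in exposure and c in panel])
        proxy = find_proxy(r, candidates, panel, r2_min=config.r2_min)
        if proxy is None:
            exclusions.append({"rsid": r, "stage": "proxy",
                               "reason": f"no proxy with r2 >= {config.r2_min}"})
        else:
            proxies[r] = proxy
            notices.append(f"{r}: replaced by proxy {proxy}")
            analysed_ids.append(proxy)

    pairs = harmonize(exposure.subset(analysed_ids), outcome,
                      palindrome_eaf_window=config.palindrome_window)
    kept_pairs = []
    for p in pairs:
        if p.dropped:
            exclusions.append({"rsid": p.rsid, "stage": "harmonization",
                               "reason": p.reason or p.action})
        elif p.beta_exp == 0:
            exclusions.append({"rsid": p.rsid, "stage": "wald",
                               "reason": "zero exposure effect, ratio undefined"})
        else:
            kept_pairs.append(p)
    analysed = [p.rsid for p in kept_pairs]
    k = len(analysed)

    if k == 0 or (k < 3 and not explicit):
        raise PipelineAbort(
            f"only {k} instruments survive harmonization "
            f"(selected {len(all_selected)}, excluded {len(exclusions)}); "
            "need at least 3 — see the exclusion log"
        )

    estimates = mr.wald_ratios(kept_pairs, order=config.wald_order)
    fit_all = mr.ivw_fixed(estimates)
    if k < 2:
        notices.append("single instrument: Cochran Q skipped")

    loo = fit_excl = egger_fit = None
    if k >= 3:
        loo = mr.leave_one_out(estimates)
        if loo.outlier is not None:
            fit_excl = loo.fits[loo.outlier]
            notices.append(
                f"{loo.outlier}: dominant outlier; its removal resolves heterogeneity "
                f"(residual p_het = {fit_excl.p_het:.3g})"
            )
        egger_fit = mr.egger(kept_pairs)
    else:
        notices.append(f"{k} instruments: leave-one-out and Egger regression skipped (need >= 3)")

    rows = [_results_row("IVW (all instruments)", fit_all.k, fit_all.theta_hat,
                         fit_all.se, fit_all.p, fit_all.q, fit_all.df, fit_all.p_het)]
    if fit_excl is not None:
        rows.append(_results_row(f"IVW (excluding {loo.outlier})", fit_excl.k,
                                 fit_excl.theta_hat, fit_excl.se, fit_excl.p,
                                 fit_excl.q, fit_excl.df, fit_excl.p_het))
    if egger_fit is not None:
        rows.append(_results_row("Egger regression", egger_fit.k, egger_fit.slope,
                                 egger_fit.slope_se, egger_fit.slope_p,
                                 fit_all.q, fit_all.df, fit_all.p_het))
    results_table = pd.DataFrame(rows)

    forest_table = _forest_table(kept_pairs)
    # bookkeeping is in terms of the originally selected variants, so map
    # proxy rsids back to the instrument they stand in for
    inverse_proxy = {v: k_ for k_, v in proxies.items()}
    for e in exclusions:
        e["rsid"] = inverse_proxy.get(e["rsid"], e["rsid"])
    exclusions_df = pd.DataFrame(exclusions, columns=["rsid", "stage", "reason"])
    result = MRWorkflowResult(
        selected=all_selected,
        analysed=[inverse_proxy.get(r, r) for r in analysed],
        exclusions=exclusions_df, pairs=kept_pairs, estimates=estimates,
        fit_all=fit_all, loo=loo, fit_excluding=fit_excl, egger_fit=egger_fit,
        results_table=results_table, forest_table=forest_table,
        notices=notices, proxies=proxies,
    )
    if config.out_dir:
        _write_mr_outputs(config, result, pairs)
    return result


def _forest_table(pairs) -> pd.DataFrame:
    """Figure-ready per-variant odds ratios, oriented to the risk-increasing
    exposure allele (exposure ORs > 1)."""
    rows = []
    for p in pairs:
        s = 1.0 if p.beta_exp >= 0 else -1.0
        bx, by = s * p.beta_exp, s * p.beta_out
        rows.append({
            "rsid": p.rsid,
            "exposure_or": np.exp(bx),
            "exposure_ci_low": np.exp(bx - 1.96 * p.se_exp),
            "exposure_ci_high": np.exp(bx + 1.96 * p.se_exp),
            "outcome_or": np.exp(by),
            "outcome_ci_low": np.exp(by - 1.96 * p.se_out),
            "outcome_ci_high": np.exp(by + 1.96 * p.se_out),
        })
    return pd.DataFrame(rows).sort_values("exposure_or", ascending=False).reset_index(drop=True)


def _write_mr_outputs(config: AnalysisConfig, result: MRWorkflowResult, all_pairs) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formatted = result.results_table.copy()
    for col in ("p", "p_het"):
        formatted[col] = formatted[col].map(mr.format_p)
    formatted.to_csv(out / "mr_results.tsv", sep="\t", index=False)
    result.forest_table.to_csv(out / "forest.tsv", sep="\t", index=False)
    harmonization_report(all_pairs).to_csv(out / "harmonization.tsv", sep="\t", index=False)
    result.exclusions.to_csv(out / "exclusions.tsv", sep="\t", index=False)
    with open(out / "run.log", "w", encoding="utf-8") as fh:
        fh.write(f"config_hash\t{config.hash()}\n")
        for n in result.notices:
            fh.write(f"notice\t{n}\n")
        for _, row in result.exclusions.iterrows():
            fh.write(f"excluded\t{row['rsid']}\t{row['stage']}\t{row['reason']}\n")


def annotate_pleiotropy(
    variants: list[str],
    table: AnnotationTable,
    alpha: float | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Phenome-scan style pleiotropy report from a local annotation table.

    For each instrument, lists phenotype associations with p below ``alpha``
    (default: 0.05 Bonferroni-corrected for the number of distinct
    phenotypes in the table). Returns the per-variant report and the count
    of instruments per associated phenotype.
    """
    if len(table.df) == 0:
        warnings.warn("empty annotation table: no pleiotropy lookup performed", stacklevel=2)
        return (pd.DataFrame(columns=["rsid", "phenotype", "pvalue", "source"]), {})
    if alpha is None:
        alpha = 0.05 / table.n_phenotypes
    hits = table.df[table.df["rsid"].isin(variants)
                    & (table.df["pvalue"].astype(float) < alpha)]
    report = hits[["rsid", "phenotype", "pvalue", "source"]].reset_index(drop=True)
    counts = report.groupby("phenotype")["rsid"].nunique().to_dict()
    return report, counts


def _parse_region(spec: str) -> tuple[str, int, int]:
    chrom, _, span = spec.partition(":")
    lo, _, hi = span.partition("-")
    return chrom.strip(), int(lo.replace(",", "")), int(hi.replace(",", ""))


def region_from_tables(
    exposure: SumStatsTable,
    outcome: SumStatsTable,
    spec: str,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> RegionData:
    """Build paired regional data (1-based inclusive interval) from two
    harmonized summary tables; trait 1 is the exposure."""
    chrom, lo, hi = _parse_region(spec)
    df = exposure.df
    in_region = (df["chrom"].astype(str) == chrom) & (df["pos"] >= lo) & (df["pos"] <= hi)
    rsids = df.index[in_region].tolist()
    pairs = [p for p in harmonize(exposure.subset(rsids), outcome, palindrome_window)
             if not p.dropped]
    if not pairs:
        raise PipelineAbort(f"no harmonizable variants in region {spec}")
    return RegionData(
        rsids=[p.rsid for p in pairs],
        beta1=np.array([p.beta_exp for p in pairs]),
        se1=np.array([p.se_exp for p in pairs]),
        beta2=np.array([p.beta_out for p in pairs]),
        se2=np.array([p.se_out for p in pairs]),
        pos=np.array([int(exposure.df.loc[p.rsid, "pos"]) for p in pairs]),
        chrom=chrom,
    )


@dataclass
class FullStudyResult:
    stages: dict[str, str]  # stage -> "ok" | "skipped: ..." | "failed: ..."
    mr_result: MRWorkflowResult | None = None
    ldsc_fit: LdscFit | None = None
    region_results: dict[str, RegionModelPosteriors] = field(default_factory=dict)
    annotation_report: pd.DataFrame | None = None
    annotation_counts: dict[str, int] = field(default_factory=dict)
    config_hash: str = ""

    def summary(self) -> dict:
        out: dict = {"config_hash": self.config_hash, "stages": self.stages}
        if self.mr_result is not None and self.mr_result.fit_all is not None:
            fit = self.mr_result.fit_all
            out["mr"] = {"or": fit.or_, "ci95": list(fit.ci95), "p": fit.p,
                         "q": fit.q, "df": fit.df, "p_het": fit.p_het, "k": fit.k}
            if self.mr_result.fit_excluding is not None:
                fe = self.mr_result.fit_excluding
                out["mr_excluding_outlier"] = {
                    "outlier": self.mr_result.loo.outlier, "or": fe.or_,
                    "ci95": list(fe.ci95), "p": fe.p, "q": fe.q, "p_het": fe.p_het,
                }
        if self.ldsc_fit is not None:
            out["ldsc"] = {"rg": self.ldsc_fit.rg, "rg_se": self.ldsc_fit.rg_se,
                           "p_rg": self.ldsc_fit.p_rg,
                           "intercept_x": self.ldsc_fit.intercept_x,
                           "h2_1": self.ldsc_fit.h2_1, "h2_2": self.ldsc_fit.h2_2}
        if self.region_results:
            out["regions"] = {
                spec: dict(zip(["pp0", "pp1", "pp2", "pp3", "pp4"], pp.as_array().tolist()))
                for spec, pp in self.region_results.items()
            }
        if self.annotation_counts:
            out["pleiotropy_counts"] = self.annotation_counts
        return out


def run_full_study(
    config: AnalysisConfig,
    exposure: SumStatsTable | None = None,
    outcome: SumStatsTable | None = None,
    panel: HaplotypePanel | None = None,
    priors: ScanPriors | None = None,
) -> FullStudyResult:
    """Run every configured stage; a stage failure yields a partial bundle
    with per-stage status rather than a crash."""
    result = FullStudyResult(stages={}, config_hash=config.hash())
    if exposure is None:
        exposure = read_sumstats(config.exposure_path, provenance="exposure")
    if outcome is None:
        outcome = read_sumstats(config.outcome_path, provenance="outcome")
    if panel is None:
        panel = config.load_panel()

    try:
        result.mr_result = run_mr_workflow(config, exposure, outcome, panel)
        result.stages["mr"] = "ok"
    except (PipelineAbort, mr.MREstimationError) as exc:
        result.stages["mr"] = f"failed: {exc}"

    if config.ldscore_path:
        try:
            entries = read_ldscores(config.ldscore_path)
            by_rsid = {e.rsid: e for e in entries}
            shared = [r for r in exposure.rsids if r in outcome and r in by_rsid]
            z1 = np.array([exposure.get(r).z for r in shared])
            z2 = np.array([outcome.get(r).z for r in shared])
            l = np.array([by_rsid[r].l for r in shared])
            n1 = _total_n(exposure)
            n2 = _total_n(outcome)
            n_blocks = min(200, max(2, len(shared) // 25))
            result.ldsc_fit = rg_regression(z1, z2, l, n1, n2, n_blocks=n_blocks)
            result.stages["ldsc"] = "ok"
        except Exception as exc:  # stage isolation is the contract here
            result.stages["ldsc"] = f"failed: {exc}"
    else:
        result.stages["ldsc"] = "skipped: no LD-score file configured"

    for spec in config.regions:
        try:
            region = region_from_tables(exposure, outcome, spec, config.palindrome_window)
            result.region_results[spec] = region_posteriors(region, priors)
            result.stages[f"region:{spec}"] = "ok"
        except Exception as exc:
            result.stages[f"region:{spec}"] = f"failed: {exc}"

    if config.annotation_path:
        try:
            table = AnnotationTable.read(config.annotation_path)
            variants = (result.mr_result.analysed if result.mr_result else exposure.rsids)
            report, counts = annotate_pleiotropy(variants, table, config.annotation_alpha)
            result.annotation_report = report
            result.annotation_counts = counts
            result.stages["annotation"] = "ok"
        except Exception as exc:
            result.stages["annotation"] = f"failed: {exc}"
    else:
        result.stages["annotation"] = "skipped: no annotation table configured"

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(result.summary(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return result


def _total_n(table: SumStatsTable) -> float:
    n = (table.df.get("n_cases", pd.Series(dtype=float)).fillna(0)
         + table.df.get("n_controls", pd.Series(dtype=float)).fillna(0))
    n = n[n > 0]
    if len(n) == 0:
        raise PipelineAbort("sample sizes required for LD-score regression")
    return float(n.median())
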