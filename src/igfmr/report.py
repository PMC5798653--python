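"""End-to-end pipeline orchestration and report generation.

A :class:`RunConfig` (typically loaded from YAML) names the input tables,
the column dialects, the analysis subsets to run and an optional power
design. :func:`run_pipeline` executes read → harmonize → analyses → write,
emitting one results TSV per analysis (one row per SNP plus a pooled row —
the data behind a forest plot), the harmonization audit, and a plain-text
summary. Displayed ORs/CIs are rounded to 2 decimals and p-values to 3
significant figures; the TSVs keep full precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from igfmr import mr
from igfmr.harmonize import (
    DEFAULT_POLICY,
    HarmonizationReport,
    InstrumentSet,
    PalindromePolicy,
    code_molar_ratio,
    harmonize_tables,
)
from igfmr.mr import PooledResult, ivw_meta, or_ci, select_subset, subset_analysis, wald_ratio
from igfmr.power import PowerDesign, min_detectable_or, power_binary
from igfmr.sumstats_io import (
    CANONICAL_DIALECT,
    IGAP_DIALECT,
    Dialect,
    Scale,
    read_association_table,
    read_instrument_specs,
    select_instruments,
)

log = logging.getLogger("igfmr")


class PipelineError(Exception):
    """Hard pipeline failure; message carries the stage label."""


_DIALECTS = {"canonical": CANONICAL_DIALECT, "igap": IGAP_DIALECT}

#: accepted selector spellings → engine selector
_SELECTOR_ALIASES = {
    "main9": "main9",
    "main": "main9",
    "igf1_only": "igf1_only5",
    "igf1_only5": "igf1_only5",
    "igfbp3_only": "igfbp3_only2",
    "igfbp3_only2": "igfbp3_only2",
    "molar_ratio": "molar_ratio8",
    "molar_ratio8": "molar_ratio8",
    "magnitude": "magnitude",
}


def resolve_dialect(name_or_map) -> Dialect:
    if isinstance(name_or_map, Dialect):
        return name_or_map
    if isinstance(name_or_map, str):
        try:
            return _DIALECTS[name_or_map]
        except KeyError:
            raise PipelineError(f"config: unknown dialect {name_or_map!r}") from None
    if isinstance(name_or_map, dict):
        return Dialect(**name_or_map)
    raise PipelineError(f"config: cannot interpret dialect {name_or_map!r}")


@dataclass
class RunConfig:
    """Structural configuration of one named analysis run."""

    exposure_path: str
    outcome_path: str
    instruments_path: str
    out_dir: str
    exposure_dialect: object = "canonical"
    outcome_dialect: object = "canonical"
    analyses: Sequence[str] = ("main9", "igf1_only", "igfbp3_only", "molar_ratio")
    magnitude_mode: bool = False
    power: dict | None = None
    palindrome_policy: str = DEFAULT_POLICY.mode
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def validate(self) -> None:
        for label, p in (
            ("exposure", self.exposure_path),
            ("outcome", self.outcome_path),
            ("instruments", self.instruments_path),
        ):
            if not Path(p).exists():
                raise PipelineError(f"[read] {label} table not found: {p}")
        if not self.analyses:
            raise PipelineError("[config] analysis selector list is empty")
        for a in self.analyses:
            if a not in _SELECTOR_ALIASES:
                raise PipelineError(
                    f"[config] unknown analysis selector {a!r}; valid: {sorted(_SELECTOR_ALIASES)}"
                )


@dataclass
class ReportBundle:
    """Everything a run produced, before and after serialization."""

    analyses: dict[str, PooledResult]
    per_snp: dict[str, pd.DataFrame]
    harmonization: HarmonizationReport
    warnings: list[str] = field(default_factory=list)
    power_lines: list[str] = field(default_factory=list)
    out_files: dict[str, Path] = field(default_factory=dict)


def overlap_fraction(n_overlap: int, n_total: int) -> float:
    """Percentage of one GWAS sample potentially shared with the other, 1 dp."""
    if n_total <= 0:
        raise PipelineError("n_total must be > 0")
    if not (0 <= n_overlap <= n_total):
        raise PipelineError(f"n_overlap must be in [0, {n_total}], got {n_overlap}")
    return round(100.0 * n_overlap / n_total, 1)


def replication_meta(
    primary: tuple[float, float],
    replications: Sequence[tuple[float, float]],
    same_orientation: bool = True,
) -> PooledResult:
    """IVW-pool one primary-sample SNP estimate with replication estimates.

    All estimates must be expressed on the same allele orientation; the
    caller asserts this via ``same_orientation``.
    """
    if not same_orientation:
        raise PipelineError("replication estimates not on the primary allele orientation")
    betas = [primary[0]] + [b for b, _ in replications]
    ses = [primary[1]] + [s for _, s in replications]
    return ivw_meta(betas, ses)


def _sig3(p: float) -> str:
    return f"{p:.3g}"


def _per_snp_frame(iset: InstrumentSet, mode: str) -> pd.DataFrame:
    rows = []
    for pair in iset.pairs:
        if mode == "causal":
            beta, se = pair.beta_gy, pair.se_gy
        else:
            est = wald_ratio(pair)
            beta, se = est.beta_iv, est.se_iv
        o, lo, hi = or_ci(beta, se)
        rows.append(
            {
                "rsid": pair.rsid,
                "coded_allele": pair.coded_allele,
                "beta": beta,
                "se": se,
                "or": o,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def _pooled_row(res: PooledResult) -> dict:
    return {
        "rsid": "POOLED",
        "coded_allele": "",
        "beta": res.beta_pooled,
        "se": res.se_pooled,
        "or": res.or_pooled,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "pvalue": res.pvalue,
        "q_stat": res.q_stat,
        "q_df": res.q_df,
        "q_pvalue": res.q_pvalue,
        "i2": res.i2,
    }


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis described by ``config`` and write the report."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    warnings: list[str] = []

    # --- read ---
    exp_res = read_association_table(
        config.exposure_path, resolve_dialect(config.exposure_dialect)
    )
    out_res = read_association_table(
        config.outcome_path,
        resolve_dialect(config.outcome_dialect),
        trait="AD",
        scale=Scale.LOG_ODDS,
    )
    specs = read_instrument_specs(config.instruments_path)
    for label, res in (("exposure", exp_res), ("outcome", out_res)):
        log.info("[read] %s: %d records, %d rejected", label, len(res.records), len(res.rejections))
        for rownum, msg in res.rejections:
            warnings.append(f"[read] {label} row {rownum}: {msg}")

    exp_sel, exp_missing = select_instruments(exp_res.records, specs)
    out_sel, out_missing = select_instruments(out_res.records, specs)
    for rsid in exp_missing:
        warnings.append(f"[select] {rsid} missing from exposure table")
    for rsid in out_missing:
        warnings.append(f"[select] {rsid} missing from outcome table")

    # --- harmonize ---
    policy = PalindromePolicy(mode=config.palindrome_policy)
    main_set, audit = harmonize_tables(exp_sel, out_sel, specs, policy)
    for rsid, reason in audit.exclusions:
        warnings.append(f"[harmonize] {rsid} excluded: {reason}")

    # --- analyses ---
    analyses: dict[str, PooledResult] = {}
    per_snp: dict[str, pd.DataFrame] = {}
    for raw_selector in config.analyses:
        selector = _SELECTOR_ALIASES[raw_selector]
        try:
            if selector == "magnitude":
                res = subset_analysis(main_set, "main9", mode="magnitude")
                sub = select_subset(main_set, "main9")
                frame = _per_snp_frame(sub, "magnitude")
            elif selector == "molar_ratio8":
                eligible = [
                    p
                    for p in main_set.pairs
                    if main_set.spec_for(p.rsid) is not None
                    and main_set.spec_for(p.rsid).affects.value
                    in ("igf1_only", "igfbp3_only", "bivariate_opposite")
                ]
                ratio_set = code_molar_ratio(eligible, main_set.specs)
                res = subset_analysis(ratio_set, "molar_ratio8", mode="causal")
                frame = _per_snp_frame(ratio_set, "causal")
            else:
                res = subset_analysis(main_set, selector, mode="causal")
                sub = select_subset(main_set, selector)
                frame = _per_snp_frame(sub, "causal")
        except mr.MREngineError as exc:
            raise PipelineError(f"[analysis:{selector}] {exc}") from exc
        analyses[selector] = res
        frame = pd.concat([frame, pd.DataFrame([_pooled_row(res)])], ignore_index=True)
        per_snp[selector] = frame

    # --- power section ---
    power_lines: list[str] = []
    if config.power:
        design = PowerDesign(**config.power)
        lo = min_detectable_or(design, "protective")
        hi = min_detectable_or(design, "harmful")
        power_lines.append(
            f"power design: n={design.n}, case fraction={design.k_frac}, "
            f"R^2={design.r2}, alpha={design.alpha}, target power={design.target_power}"
        )
        power_lines.append(
            f"minimum detectable OR: {lo:.2f} (protective) / {hi:.2f} (harmful)"
        )
        for or_alt in (0.85, 0.90, 0.95, 1.05, 1.10, 1.15):
            power_lines.append(f"  power at OR={or_alt:.2f}: {power_binary(design, or_alt):.3f}")

    # --- write ---
    out_files: dict[str, Path] = {}
    for selector, frame in per_snp.items():
        p = out_dir / f"results_{selector}.tsv"
        frame.to_csv(p, sep="\t", index=False, float_format="%.17g")
        out_files[selector] = p
    audit_path = out_dir / "harmonization_audit.tsv"
    pd.DataFrame(audit.to_rows()).to_csv(audit_path, sep="\t", index=False)
    out_files["audit"] = audit_path

    summary_path = out_dir / "summary.txt"
    with open(summary_path, "w") as fh:
        fh.write("IGF-outcome two-sample MR report\n")
        fh.write("================================\n\n")
        for selector, res in analyses.items():
            fh.write(
                f"{selector}: k={res.k}  OR {res.or_pooled:.2f} "
                f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}; p = {_sig3(res.pvalue)})  "
                f"Q={res.q_stat:.2f} (df={res.q_df}, p={_sig3(res.q_pvalue)})  "
                f"I2={res.i2:.1f}%\n"
            )
        if power_lines:
            fh.write("\n" + "\n".join(power_lines) + "\n")
        if warnings:
            fh.write("\nwarnings:\n")
            for w in warnings:
                fh.write(f"  {w}\n")
    out_files["summary"] = summary_path

    return ReportBundle(
        analyses=analyses,
        per_snp=per_snp,
        harmonization=audit,
        warnings=warnings,
        power_lines=power_lines,
        out_files=out_files,
    )
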