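"""Synthetic two-sample GWAS summary statistics with known ground truth.

Simulation is at the summary-statistics level, not individual genotypes:
for SNP j with effect-allele frequency p_j and target exposure variance
explained r2_j, the true per-allele effect on an SD-scaled exposure is

    b_j = sqrt( r2_j / (2 p_j (1 - p_j)) )

and the observed exposure beta is drawn Normal(b_j, se_j²) with the
standard GWAS information approximation se_j = 1/sqrt(2 p_j q_j n_exp).
The outcome is a case-control log-odds association with true effect
theta·b_j plus any per-SNP direct (pleiotropic) effect, observed with
se = 1/sqrt(2 p_j q_j n_total K(1-K)) where K is the case fraction.

Defaults are shaped like the motivating study: 9 instrument SNPs whose
per-SNP r² sums to 6.5%, an exposure GWAS of n = 30,884, and an outcome
sample of 17,008 cases / 37,154 controls. A single seed spawns independent
substreams for the exposure and outcome tables, preserving the two-sample
independence assumption; identical configs give bit-identical tables.

Generated tables deliberately need harmonization work downstream: a
configurable number of SNPs are coded on the exposure-lowering allele
(orientation flips — the "recoded betas"), and in the outcome table some
SNPs are reported on the swapped allele or the opposite strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from igfmr.sumstats_io import (
    Affects,
    AssociationRecord,
    InstrumentSpec,
    Scale,
    write_association_table,
    write_instrument_specs,
)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Non-palindromic allele pairs cycled across SNPs (raising, lowering).
_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("T", "C"), ("G", "A"), ("A", "C"), ("T", "G")]


class SimulationError(Exception):
    pass


def default_instrument_specs(include_bivariate: bool = True) -> list[InstrumentSpec]:
    """The packaged 9(+1)-SNP instrument panel.

    Only rs2153960 (FOXO3 locus, IGF1-determining) and rs646776 (inverse
    IGF1/IGFBP3 effects) are real identifiers; the remaining rsids are
    synthetic placeholders. The class split — 5 IGF1-only, 2 IGFBP3-only,
    2 affecting both, 1 bivariate-opposite — mirrors a 10-locus panel where
    7 loci determine IGF1 and 4 determine IGFBP3 with 2 shared.
    Raising alleles are assigned from a fixed non-palindromic cycle.
    """
    classes = (
        [("rs2153960", "IGF1", Affects.IGF1_ONLY)]
        + [(f"rs900010{i}", "IGF1", Affects.IGF1_ONLY) for i in range(1, 5)]
        + [(f"rs900020{i}", "IGFBP3", Affects.IGFBP3_ONLY) for i in range(1, 3)]
        + [(f"rs900030{i}", "IGF1", Affects.BOTH) for i in range(1, 3)]
    )
    if include_bivariate:
        classes.append(("rs646776", "IGF1", Affects.BIVARIATE_OPPOSITE))
    return [
        InstrumentSpec(
            rsid=rsid,
            exposure_trait=trait,
            raising_allele=_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)][0],
            affects=affects,
        )
        for i, (rsid, trait, affects) in enumerate(classes)
    ]


@dataclass
class SimConfig:
    """Ground-truth configuration for a paired exposure/outcome simulation.

    theta is the true causal log-odds of outcome per SD of exposure;
    pleiotropy holds per-SNP direct log-odds effects on the outcome.
    noise_scale multiplies the sampling noise only — reported SEs are
    unchanged — so 0 gives noiseless betas for exactness checks.
    n_recoded SNPs are tabulated on the exposure-lowering allele,
    n_swapped outcome records on the swapped allele, n_complemented
    outcome records on the opposite strand.
    """

    n_snps: int = 9
    eafs: Sequence[float] | None = None
    r2_per_snp: Sequence[float] | None = None
    n_exposure: int = 30_884
    n_cases: int = 17_008
    n_controls: int = 37_154
    theta: float = 0.0
    pleiotropy: Sequence[float] | None = None
    seed: int = 0
    noise_scale: float = 1.0
    n_recoded: int = 5
    n_swapped: int = 3
    n_complemented: int = 2
    specs: list[InstrumentSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_exposure < 1 or self.n_cases < 1 or self.n_controls < 1:
            raise SimulationError("all counts must be >= 1")
        if self.eafs is None:
            self.eafs = np.linspace(0.15, 0.85, self.n_snps)
        self.eafs = np.asarray(self.eafs, dtype=float)
        if self.eafs.shape != (self.n_snps,):
            raise SimulationError("eafs must have length n_snps")
        if np.any(self.eafs <= 0) or np.any(self.eafs >= 1):
            raise SimulationError("eafs must be strictly inside (0,1)")
        if self.r2_per_snp is None:
            # uniform shares of the 6.5% aggregate instrument strength
            self.r2_per_snp = np.full(self.n_snps, 0.065 / self.n_snps)
        self.r2_per_snp = np.asarray(self.r2_per_snp, dtype=float)
        if self.r2_per_snp.shape != (self.n_snps,):
            raise SimulationError("r2_per_snp must have length n_snps")
        if np.any(self.r2_per_snp <= 0) or self.r2_per_snp.sum() >= 1:
            raise SimulationError("per-SNP r2 must be positive and sum to < 1")
        if self.pleiotropy is None:
            self.pleiotropy = np.zeros(self.n_snps)
        self.pleiotropy = np.asarray(self.pleiotropy, dtype=float)
        if self.pleiotropy.shape != (self.n_snps,):
            raise SimulationError("pleiotropy must have length n_snps")
        if self.noise_scale < 0:
            raise SimulationError("noise_scale must be >= 0")
        for name in ("n_recoded", "n_swapped", "n_complemented"):
            v = getattr(self, name)
            if not (0 <= v <= self.n_snps):
                raise SimulationError(f"{name} must be in [0, n_snps]")
        if not self.specs:
            base = default_instrument_specs(include_bivariate=False)
            if self.n_snps <= len(base):
                self.specs = base[: self.n_snps]
            else:
                extra = [
                    InstrumentSpec(
                        rsid=f"rs800{i:04d}",
                        exposure_trait="IGF1",
                        raising_allele=_ALLELE_CYCLE[i % len(_ALLELE_CYCLE)][0],
                        affects=Affects.IGF1_ONLY,
                    )
                    for i in range(len(base), self.n_snps)
                ]
                self.specs = base + extra
        if len(self.specs) != self.n_snps:
            raise SimulationError("specs must have length n_snps")

    @property
    def n_outcome(self) -> int:
        return self.n_cases + self.n_controls

    @property
    def case_fraction(self) -> float:
        return self.n_cases / self.n_outcome

    def true_effects(self) -> np.ndarray:
        """Per-allele true exposure effects b_j on the raising allele, SD units."""
        pq2 = 2 * self.eafs * (1 - self.eafs)
        return np.sqrt(self.r2_per_snp / pq2)

    def exposure_se(self) -> np.ndarray:
        pq2 = 2 * self.eafs * (1 - self.eafs)
        return 1.0 / np.sqrt(pq2 * self.n_exposure)

    def outcome_se(self) -> np.ndarray:
        pq2 = 2 * self.eafs * (1 - self.eafs)
        k = self.case_fraction
        return 1.0 / np.sqrt(pq2 * self.n_outcome * k * (1 - k))


def draw_replicates(
    config: SimConfig, n_reps: int, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Vectorized summary-statistics draws for Monte-Carlo studies.

    Returns raising-allele-oriented arrays: ``beta_gx``/``beta_gy`` of shape
    (n_reps, n_snps) plus the fixed ``se_gx``/``se_gy`` and truth ``b``.
    Shares the exact sampling model with :func:`simulate_two_sample`.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    b = config.true_effects()
    se_gx = config.exposure_se()
    se_gy = config.outcome_se()
    true_gy = config.theta * b + config.pleiotropy
    shape = (n_reps, config.n_snps)
    beta_gx = rng.normal(b, config.noise_scale * se_gx, size=shape)
    beta_gy = rng.normal(true_gy, config.noise_scale * se_gy, size=shape)
    return {"b": b, "beta_gx": beta_gx, "se_gx": se_gx, "beta_gy": beta_gy, "se_gy": se_gy}


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


@dataclass
class SimResult:
    """Exposure/outcome tables plus the ground-truth sidecar."""

    exposure: list[AssociationRecord]
    outcome: list[AssociationRecord]
    specs: list[InstrumentSpec]
    truth: pd.DataFrame
    config: SimConfig


def simulate_two_sample(config: SimConfig) -> SimResult:
    """Generate one paired exposure/outcome summary-statistics realization.

    The exposure and outcome noise use independent substreams spawned from
    the single config seed (two-sample design). Allele coding in the output
    tables follows the config's recode/swap/complement counts, so a
    realistic amount of harmonization work is required downstream; the
    ground-truth sidecar records everything on the raising-allele scale.
    """
    ss = np.random.SeedSequence(config.seed)
    exp_rng, out_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    b = config.true_effects()
    se_gx = config.exposure_se()
    se_gy = config.outcome_se()
    true_gy = config.theta * b + config.pleiotropy
    beta_gx = exp_rng.normal(b, config.noise_scale * se_gx)
    beta_gy = out_rng.normal(true_gy, config.noise_scale * se_gy)

    recoded = set(range(min(config.n_recoded, config.n_snps)))
    swapped = set(range(config.n_snps - config.n_swapped, config.n_snps))
    complemented = (
        {i % config.n_snps for i in range(1, 1 + config.n_complemented)}
        if config.n_complemented
        else set()
    )

    exposure: list[AssociationRecord] = []
    outcome: list[AssociationRecord] = []
    truth_rows = []
    for j, spec in enumerate(config.specs):
        raising = spec.raising_allele
        lowering = _ALLELE_CYCLE[j % len(_ALLELE_CYCLE)][1]
        eaf = float(config.eafs[j])

        # exposure table coding: raising allele, unless this SNP is "recoded"
        if j in recoded:
            ea, oa, sgn, ea_f = lowering, raising, -1.0, 1 - eaf
        else:
            ea, oa, sgn, ea_f = raising, lowering, 1.0, eaf
        exposure.append(
            AssociationRecord(
                rsid=spec.rsid,
                effect_allele=ea,
                other_allele=oa,
                beta=float(sgn * beta_gx[j]),
                se=float(se_gx[j]),
                pvalue=float(_pvalues(beta_gx[j : j + 1], se_gx[j : j + 1])[0]),
                trait=spec.exposure_trait,
                scale=Scale.SD_UNITS,
                chrom=str(1 + j % 22),
                pos=1_000_000 + 1_000 * j,
                eaf=ea_f,
            )
        )

        # outcome table: same coded allele as exposure, then optionally
        # swapped and/or reported on the opposite strand
        o_ea, o_oa, o_sgn, o_f = ea, oa, sgn, ea_f
        if j in swapped:
            o_ea, o_oa, o_sgn, o_f = o_oa, o_ea, -o_sgn, 1 - o_f
        if j in complemented:
            o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
        outcome.append(
            AssociationRecord(
                rsid=spec.rsid,
                effect_allele=o_ea,
                other_allele=o_oa,
                beta=float(o_sgn * beta_gy[j]),
                se=float(se_gy[j]),
                pvalue=float(_pvalues(beta_gy[j : j + 1], se_gy[j : j + 1])[0]),
                trait="AD",
                scale=Scale.LOG_ODDS,
                chrom=str(1 + j % 22),
                pos=1_000_000 + 1_000 * j,
                eaf=o_f,
            )
        )
        truth_rows.append(
            {
                "rsid": spec.rsid,
                "raising_allele": raising,
                "eaf_raising": eaf,
                "b_true": float(b[j]),
                "beta_gx_drawn": float(beta_gx[j]),
                "beta_gy_drawn": float(beta_gy[j]),
                "pleiotropy": float(config.pleiotropy[j]),
                "theta": config.theta,
                "recoded": j in recoded,
                "swapped": j in swapped,
                "complemented": j in complemented,
            }
        )
    return SimResult(
        exposure=exposure,
        outcome=outcome,
        specs=list(config.specs),
        truth=pd.DataFrame(truth_rows),
        config=config,
    )


def make_foxo3_scenario(
    config: SimConfig,
    outlier_index: int = 0,
    outlier_or: float = 1.04,
) -> SimResult:
    """Null-causal-effect scenario with one pleiotropic outlier SNP.

    Mimics a FOXO3-like anomaly: the exposure has no causal effect on the
    outcome (theta = 0), but one instrument carries a direct per-allele
    outcome effect of log(outlier_or). With outlier_or = 1 the draws are
    identical to :func:`simulate_two_sample` under the null (same seed,
    same substreams).
    """
    if config.n_snps < 2:
        raise SimulationError("FOXO3 scenario needs at least 2 SNPs")
    if not (0 <= outlier_index < config.n_snps):
        raise SimulationError("outlier_index out of range")
    if outlier_or <= 0:
        raise SimulationError("outlier_or must be > 0")
    pleio = np.zeros(config.n_snps)
    pleio[outlier_index] = np.log(outlier_or)
    return simulate_two_sample(replace_config(config, theta=0.0, pleiotropy=pleio))


def replace_config(config: SimConfig, **kwargs) -> SimConfig:
    """Copy a SimConfig with fields replaced (re-running validation)."""
    base = {
        "n_snps": config.n_snps,
        "eafs": np.array(config.eafs),
        "r2_per_snp": np.array(config.r2_per_snp),
        "n_exposure": config.n_exposure,
        "n_cases": config.n_cases,
        "n_controls": config.n_controls,
        "theta": config.theta,
        "pleiotropy": np.array(config.pleiotropy),
        "seed": config.seed,
        "noise_scale": config.noise_scale,
        "n_recoded": config.n_recoded,
        "n_swapped": config.n_swapped,
        "n_complemented": config.n_complemented,
        "specs": list(config.specs),
    }
    base.update(kwargs)
    return SimConfig(**base)


def realized_r2(records: Sequence[AssociationRecord]) -> float:
    """Sample exposure variance explained, Σ 2 p q β̂², from a table with EAFs."""
    total = 0.0
    for rec in records:
        if rec.eaf is None:
            raise SimulationError(f"{rec.rsid}: EAF required to compute realized r2")
        total += 2 * rec.eaf * (1 - rec.eaf) * rec.beta ** 2
    return total


def write_fixture(config: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Write exposure/outcome/instrument/truth files in the canonical dialect."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_two_sample(config)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "instruments": outdir / "instruments.tsv",
        "truth": outdir / "truth.tsv",
    }
    write_association_table(sim.exposure, paths["exposure"])
    write_association_table(sim.outcome, paths["outcome"])
    write_instrument_specs(sim.specs, paths["instruments"])
    sim.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
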