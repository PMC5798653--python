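"""Per-SNP causal estimates and fixed-effects IVW pooling with heterogeneity.

The per-SNP causal estimate is the Wald ratio — the SNP-outcome log-odds
divided by the SNP-exposure effect — with a first-order delta-method
standard error carrying both variance terms:

    se_iv^2 = se_gy^2 / beta_gx^2 + beta_gy^2 * se_gx^2 / beta_gx^4

The common one-term simplification ``se_gy/|beta_gx|`` is available as
``method="delta1"`` for comparability with calculators that use it. No
covariance term enters: in a two-sample design the exposure and outcome
betas come from non-overlapping samples.

Pooling is a fixed-effects inverse-variance-weighted (IVW) meta-analysis;
heterogeneity is summarized by Cochran's Q and I² = max(0, (Q-df)/Q)·100,
which flag instruments with pleiotropic (direct) outcome effects. Two modes
of analysis are supported: *causal-inference* mode pools the SNP-outcome
log-odds directly (it tests existence/direction of an effect without
estimating its per-unit magnitude), and *magnitude* mode pools Wald ratios,
giving log-odds of outcome per SD of exposure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from igfmr.harmonize import HarmonizedPair, InstrumentSet, RATIO_RAISING
from igfmr.sumstats_io import Affects


class MREngineError(Exception):
    pass


@dataclass(frozen=True)
class WaldEstimate:
    """Ratio estimate for one SNP: outcome log-odds per exposure unit."""

    rsid: str
    beta_iv: float
    se_iv: float

    @property
    def weight(self) -> float:
        return self.se_iv ** -2


@dataclass(frozen=True)
class PooledResult:
    """Fixed-effects IVW pooled estimate with heterogeneity diagnostics."""

    k: int
    beta_pooled: float
    se_pooled: float
    or_pooled: float
    ci_low: float
    ci_high: float
    z: float
    pvalue: float
    q_stat: float
    q_df: int
    q_pvalue: float
    i2: float


def wald_ratio(pair: HarmonizedPair, method: str = "delta2") -> WaldEstimate:
    """Per-SNP Wald ratio with delta-method SE.

    ``delta2`` (default) keeps both first-order variance terms; ``delta1``
    is the one-term simplification se_gy/|beta_gx|.
    """
    if pair.beta_gx == 0:
        raise MREngineError(
            f"{pair.rsid}: beta_gx = 0, ratio undefined (degenerate weak instrument)"
        )
    beta_iv = pair.beta_gy / pair.beta_gx
    if method == "delta2":
        var = (
            pair.se_gy ** 2 / pair.beta_gx ** 2
            + pair.beta_gy ** 2 * pair.se_gx ** 2 / pair.beta_gx ** 4
        )
        se_iv = math.sqrt(var)
    elif method == "delta1":
        se_iv = pair.se_gy / abs(pair.beta_gx)
    else:
        raise ValueError(f"unknown delta method {method!r}")
    return WaldEstimate(rsid=pair.rsid, beta_iv=beta_iv, se_iv=se_iv)


def or_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float, float]:
    """Odds ratio and CI from a log-odds estimate and its SE."""
    if not (0 < level < 1):
        raise ValueError(f"confidence level must be in (0,1), got {level}")
    if se < 0:
        raise ValueError("se must be >= 0")
    zq = stats.norm.ppf(0.5 + level / 2)
    return math.exp(beta), math.exp(beta - zq * se), math.exp(beta + zq * se)


def ivw_meta(
    betas: Sequence[float],
    ses: Sequence[float],
    level: float = 0.95,
) -> PooledResult:
    """Fixed-effects inverse-variance-weighted meta-analysis.

    Weights are w_i = se_i^-2; the pooled estimate is Σw_i β_i / Σw_i with
    SE (Σw_i)^-1/2. Cochran's Q = Σw_i(β_i - β_pooled)² is referred to a
    chi-square with k-1 df (p = 1 for a single study); I² is floored at 0.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise MREngineError("cannot pool an empty set of estimates")
    if b.shape != s.shape:
        raise MREngineError("betas and ses must have equal length")
    if np.any(s <= 0):
        raise MREngineError("all standard errors must be > 0")

    w = s ** -2.0
    beta_pooled = float(np.sum(w * b) / np.sum(w))
    se_pooled = float(np.sum(w) ** -0.5)
    z = beta_pooled / se_pooled
    pvalue = float(2 * stats.norm.sf(abs(z)))
    q = float(np.sum(w * (b - beta_pooled) ** 2))
    k = int(b.size)
    q_df = k - 1
    q_pvalue = float(stats.chi2.sf(q, q_df)) if q_df >= 1 else 1.0
    i2 = max(0.0, (q - q_df) / q) * 100.0 if (k > 1 and q > 0) else 0.0
    orv, lo, hi = or_ci(beta_pooled, se_pooled, level)
    return PooledResult(
        k=k,
        beta_pooled=beta_pooled,
        se_pooled=se_pooled,
        or_pooled=orv,
        ci_low=lo,
        ci_high=hi,
        z=float(z),
        pvalue=pvalue,
        q_stat=q,
        q_df=q_df,
        q_pvalue=q_pvalue,
        i2=float(i2),
    )


def standardized_residuals(
    betas: Sequence[float], ses: Sequence[float], pooled: PooledResult
) -> np.ndarray:
    """Per-study standardized residuals (β_i - β_pooled)/se_i.

    Their squares sum to Cochran's Q; the largest |residual| points at the
    instrument most likely to carry a direct (pleiotropic) outcome effect.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    return (b - pooled.beta_pooled) / s


_SELECTORS = {
    "main9": (Affects.IGF1_ONLY, Affects.IGFBP3_ONLY, Affects.BOTH),
    "igf1_only5": (Affects.IGF1_ONLY,),
    "igfbp3_only2": (Affects.IGFBP3_ONLY,),
    "molar_ratio8": (Affects.IGF1_ONLY, Affects.IGFBP3_ONLY, Affects.BIVARIATE_OPPOSITE),
}


def select_subset(iset: InstrumentSet, subset: str) -> InstrumentSet:
    """Filter an instrument set by the named analysis subset."""
    if subset not in _SELECTORS:
        raise MREngineError(f"unknown subset selector {subset!r}; valid: {sorted(_SELECTORS)}")
    classes = _SELECTORS[subset]
    if subset == "molar_ratio8":
        if not all(p.orientation == RATIO_RAISING for p in iset.pairs):
            raise MREngineError(
                "molar_ratio8 requires a ratio-coded instrument set "
                "(see harmonize.code_molar_ratio)"
            )
        return iset
    pairs, specs = [], []
    for pair in iset.pairs:
        spec = iset.spec_for(pair.rsid)
        if spec is None:
            raise MREngineError(f"{pair.rsid}: missing instrument spec in set {iset.name!r}")
        if spec.affects in classes:
            pairs.append(pair)
            specs.append(spec)
    if not pairs:
        wanted = [c.value for c in classes]
        raise MREngineError(
            f"subset {subset!r}: no instruments of class {wanted} in set {iset.name!r}"
        )
    return InstrumentSet(name=subset, exposure=iset.exposure, pairs=pairs, specs=specs)


def subset_analysis(
    iset: InstrumentSet,
    subset: str = "main9",
    mode: str = "causal",
    delta_method: str = "delta1",
) -> PooledResult:
    """Pooled IVW result for a named instrument subset.

    ``mode="causal"`` pools the direct SNP-outcome log-odds (per raising
    allele); ``mode="magnitude"`` pools Wald ratios (log-odds per exposure
    unit, requiring exposure betas on a meaningful scale). Magnitude-mode
    pooling weights default to the first-order variance (``delta1``) — the
    standard IVW weighting — because the two-term variance depends on the
    outcome beta and therefore correlates weights with estimation noise,
    biasing the pooled effect slightly toward zero; the two-term SE remains
    the per-SNP reporting default in :func:`wald_ratio`.
    """
    sub = select_subset(iset, subset)
    if mode == "causal":
        betas = [p.beta_gy for p in sub.pairs]
        ses = [p.se_gy for p in sub.pairs]
    elif mode == "magnitude":
        est = [wald_ratio(p, method=delta_method) for p in sub.pairs]
        betas = [e.beta_iv for e in est]
        ses = [e.se_iv for e in est]
    else:
        raise ValueError(f"unknown analysis mode {mode!r}")
    return ivw_meta(betas, ses)
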