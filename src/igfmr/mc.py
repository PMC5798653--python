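"""Monte-Carlo replication studies over the synthetic generator.

These helpers drive the estimator across many simulated realizations of
the same design: calibration of CI coverage and of Cochran's Q under the
causal null, empirical power against the analytic approximation, parameter
recovery, and pleiotropic-outlier detection. Draws come from
:func:`igfmr.simulate.draw_replicates` (the exact per-SNP sampling model of
the table generator); each replicate is pooled with the production
:func:`igfmr.mr.ivw_meta`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from igfmr.mr import PooledResult, ivw_meta, standardized_residuals
from igfmr.simulate import SimConfig, draw_replicates


def _wald_arrays(
    draws: dict[str, np.ndarray], method: str = "delta2"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Wald ratios and delta-method SEs for all replicates."""
    gx, gy = draws["beta_gx"], draws["beta_gy"]
    se_gx, se_gy = draws["se_gx"], draws["se_gy"]
    beta_iv = gy / gx
    if method == "delta2":
        se_iv = np.sqrt(se_gy**2 / gx**2 + gy**2 * se_gx**2 / gx**4)
    elif method == "delta1":
        se_iv = np.broadcast_to(se_gy, gx.shape) / np.abs(gx)
    else:
        raise ValueError(f"unknown delta method {method!r}")
    return beta_iv, se_iv


def pooled_replicates(
    config: SimConfig,
    n_reps: int,
    mode: str = "magnitude",
    delta_method: str = "delta1",
    rng: np.random.Generator | None = None,
) -> list[PooledResult]:
    """IVW-pool each of ``n_reps`` simulated replicates.

    ``magnitude`` pools Wald ratios (estimates of theta); ``causal`` pools
    the direct SNP-outcome log-odds.
    """
    draws = draw_replicates(config, n_reps, rng=rng)
    if mode == "magnitude":
        betas, ses = _wald_arrays(draws, delta_method)
    elif mode == "causal":
        betas = draws["beta_gy"]
        ses = np.broadcast_to(draws["se_gy"], betas.shape)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return [ivw_meta(betas[r], ses[r]) for r in range(n_reps)]


def coverage_and_q_calibration(
    config: SimConfig,
    n_reps: int,
    true_theta: float | None = None,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """CI coverage of the true effect and Q-test rejection rate.

    Under a shared true effect (no pleiotropy) the Q rejection rate should
    sit at the nominal alpha and the CI coverage at 1 - alpha.
    """
    theta = config.theta if true_theta is None else true_theta
    results = pooled_replicates(config, n_reps, mode="magnitude", rng=rng)
    z95 = 1.959963984540054
    covered = np.array(
        [
            r.beta_pooled - z95 * r.se_pooled <= theta <= r.beta_pooled + z95 * r.se_pooled
            for r in results
        ]
    )
    q_reject = np.array([r.q_pvalue < alpha for r in results])
    return {
        "coverage": float(covered.mean()),
        "q_rejection": float(q_reject.mean()),
        "n_reps": n_reps,
    }


def rejection_rate(
    config: SimConfig,
    n_reps: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> float:
    """Empirical two-sided rejection rate of H0: theta = 0."""
    results = pooled_replicates(config, n_reps, mode="magnitude", rng=rng)
    return float(np.mean([r.pvalue < alpha for r in results]))


def recovery_summary(
    config: SimConfig,
    n_reps: int,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Mean pooled estimate, bias against the configured theta, and MC SE."""
    results = pooled_replicates(config, n_reps, mode="magnitude", rng=rng)
    est = np.array([r.beta_pooled for r in results])
    mc_se = float(est.std(ddof=1) / np.sqrt(n_reps))
    return {
        "mean_estimate": float(est.mean()),
        "bias": float(est.mean() - config.theta),
        "mc_se": mc_se,
        "n_reps": n_reps,
    }


def outlier_detection(
    config: SimConfig,
    n_reps: int,
    outlier_index: int,
    alpha: float = 0.05,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-replicate Q p-value and index of the largest |standardized residual|.

    ``config`` should already carry the pleiotropic outlier (e.g. built via
    :func:`igfmr.simulate.make_foxo3_scenario`'s parameters); pooling is in
    causal mode, matching the main-analysis Q diagnostic.
    """
    draws = draw_replicates(config, n_reps, rng=rng)
    betas = draws["beta_gy"]
    ses = np.broadcast_to(draws["se_gy"], betas.shape)
    rows = []
    for r in range(n_reps):
        pooled = ivw_meta(betas[r], ses[r])
        resid = standardized_residuals(betas[r], ses[r], pooled)
        rows.append(
            {
                "q_pvalue": pooled.q_pvalue,
                "q_reject": pooled.q_pvalue < alpha,
                "top_residual_index": int(np.argmax(np.abs(resid))),
                "hit": int(np.argmax(np.abs(resid))) == outlier_index,
            }
        )
    return pd.DataFrame(rows)
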