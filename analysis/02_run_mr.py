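#!/usr/bin/env python
"""Run the two-sample MR analyses on the simulated cohort.

Harmonizes the fixture tables to exposure-raising alleles, then pools the
SNP-outcome log-odds by fixed-effects IVW for the four analysis subsets —
main (9 SNPs), IGF1-only (5), IGFBP3-only (2) and the molar-ratio coding
(8, including the bivariate-opposite SNP) — with Cochran Q / I-squared
heterogeneity diagnostics and a power section. Forest-plot tables land in
results/mr_report/.
"""

import argparse
from pathlib import Path

from igfmr.report import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--fixture", type=Path, default=ROOT / "results" / "fixture")
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "mr_report")
    args = parser.parse_args()

    config = RunConfig(
        exposure_path=str(args.fixture / "exposure.tsv"),
        outcome_path=str(args.fixture / "outcome.tsv"),
        instruments_path=str(args.fixture / "instruments.tsv"),
        out_dir=str(args.out),
        analyses=("main9", "igf1_only", "igfbp3_only", "molar_ratio"),
        power={"n": 54_162, "k_frac": 0.314, "r2": 0.065},
    )
    bundle = run_pipeline(config)
    for name, res in bundle.analyses.items():
        print(
            f"{name:14s} k={res.k}  OR {res.or_pooled:.2f} "
            f"(95% CI {res.ci_low:.2f}-{res.ci_high:.2f}; p = {res.pvalue:.3g})  "
            f"Q={res.q_stat:.2f} p_Q={res.q_pvalue:.3g}  I2={res.i2:.1f}%"
        )
    n_flips = sum(
        "orient_flip" in p.flips_applied for p in bundle.harmonization.pairs
    )
    print(f"harmonization: {len(bundle.harmonization.pairs)} SNPs aligned, "
          f"{n_flips} betas sign-recoded to raising alleles")
    print(f"report: {bundle.out_files['summary']}")


if __name__ == "__main__":
    main()
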