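#!/usr/bin/env python
"""Validate the 20-gene signature on the bulk cohort.

Each sample votes +1/-1 per signature gene around the cohort median; the
summed score is compared between LN-metastasis and non-LN samples (Welch t)
and the cohort is split at the 20th score percentile for Kaplan-Meier /
log-rank survival analysis.
"""

import argparse
import warnings
from pathlib import Path

import metasig as ms
import metasig.io as msio


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--datadir", type=Path, default=Path("results/data"))
    ap.add_argument("--qcdir", type=Path, default=Path("results"))
    ap.add_argument("--low-q", type=float, default=0.20)
    args = ap.parse_args()
    warnings.simplefilter("ignore")

    cohort = ms.BulkCohort(
        expr=msio.read_bulk_expression(args.datadir / "bulk_expression.tsv"),
        meta=msio.read_bulk_metadata(args.datadir / "bulk_metadata.tsv"))
    sig = msio.read_gene_list(args.qcdir / "signature.txt")

    table = ms.signature_score(cohort, sig)
    table.scores.rename("score").to_csv(args.qcdir / "bulk_scores.tsv",
                                        sep="\t")
    cmp = ms.compare_score_groups(table, cohort.meta)
    print(f"signature coverage: {table.coverage}/{len(sig)} genes")
    print(f"group comparison: mean score {cmp['mean_LN_met']:.2f} "
          f"(LN-met, n={cmp['n_LN_met']}) vs {cmp['mean_non_LN_met']:.2f} "
          f"(non-LN, n={cmp['n_non_LN_met']}); Welch t = "
          f"{cmp['t_statistic']:.2f}, p = {cmp['p_value']:.3g}")

    surv = ms.survival_by_signature(cohort, sig, low_q=args.low_q)
    msio.write_json(surv.to_dict(), args.qcdir / "survival.json")
    print(f"survival split at the {args.low_q:.0%} score quantile "
          f"(groups {surv.group_sizes}): log-rank chi2 = "
          f"{surv.statistic:.2f}, p = {surv.p_value:.3g}")


if __name__ == "__main__":
    main()
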