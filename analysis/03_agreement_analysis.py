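"""Reliability and validity analysis of the simulated study.

Builds the full per-stratum agreement report (intra-rater, inter-rater and
method comparisons for every trait and timepoint): Dahlberg error of the
method vs the minimum SD, ICC(2,1) with 95% CI, paired t-tests and
Bland-Altman limits of agreement.  Writes the report table plus the
method-comparison scatter (line of unity) and inter-rater Bland-Altman
figures, and prints the headline findings.
"""

from pathlib import Path

import matplotlib.pyplot as plt

from parscore.agreement import build_agreement_report, reports_to_frame
from parscore.io import read_ratings
from parscore.plots import bland_altman_plot, scatter_with_unity

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = read_ratings(RESULTS / "ratings.csv")
    reports = build_agreement_report(records, comparisons=("intra_rater", "inter_rater", "method"))
    df = reports_to_frame(reports)
    out = RESULTS / "agreement_report.csv"
    df.to_csv(out, index=False)

    figs = RESULTS / "figures"
    figs.mkdir(exist_ok=True)
    total = records[records.trait == "total"]
    piv = total.pivot_table(
        index=["subject", "timepoint", "rater", "session"], columns="method", values="value"
    )
    ax = scatter_with_unity(piv["digital"], piv["manual"], "digital total PAR", "manual total PAR")
    ax.figure.savefig(figs / "scatter_total_methods.svg", bbox_inches="tight")
    plt.close(ax.figure)
    for rep in reports:
        if rep.trait == "total" and rep.comparison == "inter_rater" and rep.timepoint == "T0":
            ax = bland_altman_plot(result=rep.bland_altman, title=f"inter-rater total PAR, T0 {rep.method}")
            ax.figure.savefig(figs / f"bland_altman_T0_{rep.method}.svg", bbox_inches="tight")
            plt.close(ax.figure)

    defined = df[df.icc != "undefined"]
    tot = df[df.trait == "total"]
    print(f"wrote {len(df)} strata -> {out}")
    print(f"  paired tests run: {df.attrs['n_paired_tests']} (no multiplicity correction)")
    print(f"  error of method < MSD: {int(df.error_below_msd.sum())}/{len(df)} strata")
    print(
        "  total-PAR ICC range: "
        f"{tot[tot.icc != 'undefined'].icc.astype(float).min():.2f}"
        f"-{tot[tot.icc != 'undefined'].icc.astype(float).max():.2f}"
    )
    print(f"  strata with undefined ICC (all scores equal): {len(df) - len(defined)}")
    sig = (defined.p_value < 0.05).sum()
    print(f"  paired tests with p < 0.05: {sig}")


if __name__ == "__main__":
    main()
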