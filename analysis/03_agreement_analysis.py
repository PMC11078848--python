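#!/usr/bin/env python
"""Measure the agreement between the two algorithm profiles.

Joins the AMS and CPH rows of results/parameters.csv on case id and runs
the full agreement suite on the normalized maximum slope: Shapiro–Wilk
normality, method-vs-method OLS, absolute and relative Bland–Altman with
limits of agreement and bias t-tests, and proportional-bias regression.
Writes results/agreement.json; --plots additionally renders the scatter and
both Bland–Altman figures under results/figures/.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from icgfa.agreement import bland_altman, method_regression
from icgfa.pipeline import agreement_suite, paired_from_tables

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--plots", action="store_true", help="Also write PNG figures.")
    args = parser.parse_args()

    table = pd.read_csv(ROOT / "results" / "parameters.csv")
    pairs = paired_from_tables(
        table[table["profile"] == "AMS"], table[table["profile"] == "CPH"]
    )
    report = agreement_suite(pairs)
    out = ROOT / "results" / "agreement.json"
    out.write_text(json.dumps(report, indent=2))

    absolute = report["bland_altman_absolute"]
    relative = report["bland_altman_relative_percent"]
    prop = report["proportional_bias_absolute"]
    regression = report["method_regression_a_on_b"]
    print(f"n = {report['n']} paired recordings")
    print(
        f"absolute bias d = {absolute['mean_difference_d']:+.4f} s^-1 "
        f"(LoA {absolute['loa_lower']:.4f} to {absolute['loa_upper']:.4f}, "
        f"bias-test p = {absolute['p_value_bias']:.2e})"
    )
    print(f"relative bias = {relative['mean_difference_d']:+.1f}% "
          f"(LoA {relative['loa_lower']:.1f}% to {relative['loa_upper']:.1f}%)")
    print(
        f"proportional bias: slope {prop['slope']:+.3f} "
        f"(R^2 = {prop['r_squared']:.3f}, p = {prop['p_value']:.2e})"
    )
    print(
        f"AMS = {regression['intercept']:.3f} + {regression['slope']:.3f} * CPH "
        f"(R^2 = {regression['r_squared']:.3f})"
    )
    print(f"report written to {out}")

    if args.plots:
        from icgfa.plots import plot_bland_altman, plot_method_scatter

        fig_dir = ROOT / "results" / "figures"
        fig_dir.mkdir(exist_ok=True)
        plot_method_scatter(
            pairs, method_regression(pairs), fig_dir / "method_scatter.png",
            label_a="AMS", label_b="CPH",
        )
        plot_bland_altman(pairs, bland_altman(pairs, "absolute"),
                          fig_dir / "bland_altman_absolute.png")
        plot_bland_altman(pairs, bland_altman(pairs, "relative_percent"),
                          fig_dir / "bland_altman_relative.png")
        print(f"figures written to {fig_dir}")


if __name__ == "__main__":
    main()
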