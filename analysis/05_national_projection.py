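"""UK-wide projection and one-way sensitivity analyses.

Extrapolates the fixture-based cohort losses to annual national figures via
per-group access rates and UK population estimates, then re-runs the pipeline
at the 95% CI bounds of (a) the unemployment fraction and (b) the per-stratum
discontinued proportions. Writes the full report to results/.
"""

from pathlib import Path

from cfsme_costs import cohort, costs, national

RESULTS = Path("results")


def main() -> None:
    summaries = cohort.load_cohort_summary()
    economics = cohort.load_economics_table()
    fr = cohort.load_fraction_summary()
    fractions = {
        r["sex"]: costs.UnemploymentFraction(
            r["sex"], r["mean_fraction"], r["ci_low"], r["ci_high"], int(r["n"])
        )
        for _, r in fr.iterrows()
    }

    table, groups, estimate = national.project_national(
        summaries, economics, fractions
    )
    print("access rates (per 100,000 per year):")
    for _, g in estimate.groups.iterrows():
        print(f"  {g['sex']:6s} {g['pooled_group']:5s} rate {g['rate']:6.2f}  "
              f"UK patients/yr {g['projected_patients']:7.1f}  "
              f"cost GBP {g['projected_cost']:,.0f}")
    print(f"\nprojected annual UK patients: {estimate.total_patients:,.0f}")
    print(f"projected annual UK cost: GBP {estimate.total_cost:,.0f}")

    sens = [
        national.sensitivity_one_way(summaries, economics, fractions, param)
        for param in ("unemployment_fraction", "discontinued_proportion")
    ]
    for s in sens:
        print(f"  {s.parameter}: GBP {s.low_total / 1e6:.1f}M - "
              f"GBP {s.high_total / 1e6:.1f}M")

    paths = national.render_report(table, estimate, sens, RESULTS)
    print(f"\nreport -> {', '.join(str(p) for p in paths.values())}")


if __name__ == "__main__":
    main()
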