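"""Stratified human-capital productivity losses in the cohort.

Two runs of the cost estimator: (a) on the published per-stratum inputs
shipped as package fixtures — the reproduction of the study's cohort-level
figures; (b) on the simulated cohort with the unemployment fraction
re-estimated from the simulated external sample — the full pipeline end to
end. Writes the fixture-based cost table to results/.
"""

import subprocess
import sys
from pathlib import Path

from cfsme_costs import cohort, costs, scores

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    economics = cohort.load_economics_table()

    # (a) published inputs
    summaries = cohort.load_cohort_summary()
    fr = cohort.load_fraction_summary()
    fractions = {
        r["sex"]: costs.UnemploymentFraction(
            r["sex"], r["mean_fraction"], r["ci_low"], r["ci_high"], int(r["n"])
        )
        for _, r in fr.iterrows()
    }
    table = costs.compute_cost_table(summaries, economics, fractions)
    RESULTS.mkdir(exist_ok=True)
    table.rows.to_csv(RESULTS / "cost_table.csv", index=False, float_format="%.2f")
    print("published inputs:")
    print(f"  total loss GBP {table.total_loss:,.0f} "
          f"(GBP {table.loss_per_patient:,.0f} per patient)")
    for sex, row in table.subtotals.iterrows():
        print(f"  {sex}: GBP {row['loss']:,.0f} "
              f"(GBP {row['loss_per_patient']:,.0f} per patient)")

    # (b) simulated cohort, fractions re-estimated from the external sample
    if not (SIM_DIR / "patients.csv").exists():
        subprocess.run([sys.executable, "analysis/01_simulate_cohort.py"], check=True)
    scored = scores.score_table(cohort.load_patient_table(SIM_DIR / "patients.csv"))
    sim_summaries = costs.summaries_from_cohort(scored)
    external = cohort.load_external_table(SIM_DIR / "external.csv")
    sim_fractions = {
        sex: costs.estimate_unemployment_fraction(external, sex)
        for sex in cohort.SEXES
    }
    sim_table = costs.compute_cost_table(sim_summaries, economics, sim_fractions)
    print("\nsimulated cohort (fractions re-estimated, n=60 external sample):")
    for sex, f in sim_fractions.items():
        print(f"  fraction {sex}: {f.mean_fraction:.2f} "
              f"(95% CI {f.ci_low:.2f}, {f.ci_high:.2f})")
    print(f"  total loss GBP {sim_table.total_loss:,.0f} "
          f"(GBP {sim_table.loss_per_patient:,.0f} per patient)")


if __name__ == "__main__":
    main()
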