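"""Factors associated with discontinuation of employment.

Group comparison (median/IQR, chi-squared and t-tests) followed by the
partially adjusted (one covariate + centre/year) and fully adjusted logistic
models on the complete-case set, on the simulated cohort. Writes the
odds-ratio table and group summaries to results/.
"""

import subprocess
import sys
from pathlib import Path

import pandas as pd

from cfsme_costs import cohort, employment, scores

SIM_DIR = Path("scratch/sim")
RESULTS = Path("results")


def main() -> None:
    if not (SIM_DIR / "scored.csv").exists():
        subprocess.run([sys.executable, "analysis/02_score_inventories.py"], check=True)
    scored = scores.score_table(
        cohort.load_patient_table(SIM_DIR / "patients.csv")
    )

    summary = employment.summarize_by_employment(scored)
    RESULTS.mkdir(exist_ok=True)
    summary.continuous.to_csv(RESULTS / "group_summary_continuous.csv",
                              float_format="%.2f")
    summary.categorical.to_csv(RESULTS / "group_summary_categorical.csv",
                               float_format="%.2f")
    print(
        f"groups: {summary.n_employed} employed, "
        f"{summary.n_discontinued} discontinued"
    )
    for var in ("sex", "age_band", "duration_illness", "sf36pf_total"):
        test = employment.test_association(scored, var)
        print(f"  {var:18s} {test.method:5s} p = {test.p_value:.4f}")

    partial = employment.partially_adjusted_models(scored)
    full = employment.fully_adjusted_model(scored)
    rows = []
    for cov in employment.DEFAULT_COVARIATES:
        p = partial[cov].summary_frame().loc[cov]
        f = full.summary_frame().loc[cov]
        rows.append(
            {
                "covariate": cov,
                "partial_or": p["odds_ratio"], "partial_low": p["or_low"],
                "partial_high": p["or_high"], "partial_p": p["p_value"],
                "full_or": f["odds_ratio"], "full_low": f["or_low"],
                "full_high": f["or_high"], "full_p": f["p_value"],
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "odds_ratios.csv", index=False, float_format="%.4f")
    print(f"\ncomplete-case n = {full.n}; odds ratios -> {RESULTS / 'odds_ratios.csv'}")
    with pd.option_context("display.width", 120):
        print(table.round(2).to_string(index=False))


if __name__ == "__main__":
    main()
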