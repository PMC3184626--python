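"""Score the four inventories on the simulated cohort.

Applies the missing-item rule (pro-rate one missing item, void the total for
more than one) and reports how often each branch fired. Requires the tables
from 01_simulate_cohort.py; regenerates them if absent.
"""

import subprocess
import sys
from pathlib import Path

import numpy as np

from cfsme_costs import cohort, scores

SIM_DIR = Path("scratch/sim")


def main() -> None:
    if not (SIM_DIR / "patients.csv").exists():
        subprocess.run([sys.executable, "analysis/01_simulate_cohort.py"], check=True)
    frame = cohort.load_patient_table(SIM_DIR / "patients.csv")
    scored = scores.score_table(frame)
    scored.to_csv(SIM_DIR / "scored.csv", index=False)

    print(f"scored {len(frame)} records -> {SIM_DIR / 'scored.csv'}")
    for name, (items, _, _, _) in scores.INVENTORIES.items():
        n_missing = frame[list(items)].isna().sum(axis=1)
        pro_rated = int((n_missing == 1).sum())
        voided = int((n_missing > 1).sum())
        col = {"chalder": "chalder_total", "sf36_pf": "sf36pf_total"}.get(name, name)
        med = np.nanmedian(scored[col])
        print(
            f"  {name:16s} median {med:5.1f}  "
            f"pro-rated {pro_rated:3d}  voided {voided:3d}"
        )


if __name__ == "__main__":
    main()
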