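import pandas as pd
import pytest

from cfsme_costs import cohort, costs, scores, synth


@pytest.fixture(scope="session")
def economics() -> pd.DataFrame:
    return cohort.load_economics_table()


@pytest.fixture(scope="session")
def summaries() -> pd.DataFrame:
    return cohort.load_cohort_summary()


@pytest.fixture(scope="session")
def published_fractions() -> dict[str, costs.UnemploymentFraction]:
    frame = cohort.load_fraction_summary()
    return {
        row["sex"]: costs.UnemploymentFraction(
            row["sex"],
            row["mean_fraction"],
            row["ci_low"],
            row["ci_high"],
            int(row["n"]),
        )
        for _, row in frame.iterrows()
    }


@pytest.fixture(scope="session")
def sim_cohort() -> pd.DataFrame:
    """A mid-sized synthetic cohort under default generative conditions."""
    return synth.simulate_cohort(synth.SimulationConfig(n_patients=4000), seed=42)


@pytest.fixture(scope="session")
def sim_scored(sim_cohort) -> pd.DataFrame:
    return scores.score_table(sim_cohort)
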