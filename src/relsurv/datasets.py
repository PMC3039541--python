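"""Published summary tables from a 12-year mortality follow-up of an
Australian women's cohort (the 1921-26 birth cohort of a national
longitudinal health study, ages 70-75 at entry in 1996).

These are the printed aggregate tables a reader of the study can use to
exercise the pipeline without microdata: the annual cohort life-table counts
with the expected-survival columns derived from national life tables, the
baseline characteristics of the cohort versus the contemporaneous national
health survey (percentages), and the multivariate relative-mortality hazard
ratios.  All values are transcribed at their published precision.
"""

from __future__ import annotations

import pandas as pd

#: analysed cohort and reference-survey sizes for the percentage tables
COHORT_N = 12423
REFERENCE_N = 894


def cohort_lifetable_counts() -> pd.DataFrame:
    """Annual cohort life-table counts and expected-survival columns.

    Columns: interval bounds, at-risk ``L``, deaths ``D``, withdrawals ``W``,
    and the published interval (``P_star``) and cumulative (``CP_star``)
    expected survival from matched national life tables.  Withdrawals appear
    only in the final interval (administrative end of follow-up).
    """
    rows = [
        # start, end,     L,    D,   W, P_star, CP_star
        (0.0, 1.0, 12424, 135, 0, 0.981, 0.981),
        (1.0, 2.0, 12289, 181, 0, 0.979, 0.960),
        (2.0, 3.0, 12108, 195, 0, 0.977, 0.938),
        (3.0, 4.0, 11912, 185, 0, 0.975, 0.914),
        (4.0, 5.0, 11727, 237, 0, 0.973, 0.890),
        (5.0, 6.0, 11490, 226, 0, 0.971, 0.864),
        (6.0, 7.0, 11264, 282, 0, 0.968, 0.836),
        (7.0, 8.0, 10981, 359, 0, 0.964, 0.806),
        (8.0, 9.0, 10623, 379, 0, 0.961, 0.774),
        (9.0, 10.0, 10244, 361, 0, 0.956, 0.740),
        (10.0, 11.0, 9882, 422, 0, 0.951, 0.704),
        (11.0, 12.0, 9460, 398, 707, 0.945, 0.665),
    ]
    df = pd.DataFrame(rows, columns=["start", "end", "L", "D", "W", "P_star", "CP_star"])
    df.insert(0, "interval", range(len(df)))
    return df


def baseline_category_percentages() -> pd.DataFrame:
    """Baseline characteristics, cohort vs national health survey, in percent.

    Cohort column is out of ``COHORT_N`` respondents, reference column out of
    ``REFERENCE_N``; printed percentages may not sum exactly to 100.
    """
    rows = [
        ("smoking", "never", 62.1, 64.6),
        ("smoking", "ex", 30.4, 24.3),
        ("smoking", "current", 7.6, 11.0),
        ("marital_status", "partnered", 55.6, 49.6),
        ("marital_status", "separated_divorced", 6.3, 5.6),
        ("marital_status", "widowed", 34.8, 42.4),
        ("marital_status", "never_married", 3.2, 2.4),
        ("country_of_birth", "australia", 73.5, 74.2),
        ("country_of_birth", "other_english_speaking", 13.6, 10.9),
        ("country_of_birth", "europe", 10.1, 12.0),
        ("country_of_birth", "asia", 1.8, 1.4),
        ("country_of_birth", "other", 1.0, 1.6),
        ("self_rated_health", "excellent", 6.4, 7.6),
        ("self_rated_health", "very_good", 26.2, 23.2),
        ("self_rated_health", "good", 39.4, 34.4),
        ("self_rated_health", "fair", 23.6, 24.3),
        ("self_rated_health", "poor", 4.3, 10.5),
        ("state", "NSW", 34.9, 35.8),
        ("state", "ACT", 1.1, 0.8),
        ("state", "QLD", 16.3, 16.6),
        ("state", "SA", 10.2, 10.0),
        ("state", "TAS", 2.8, 2.5),
        ("state", "VIC", 26.0, 25.9),
        ("state", "WA", 8.5, 8.5),
    ]
    return pd.DataFrame(
        rows, columns=["covariate", "category", "cohort_pct", "reference_pct"]
    )


def published_hazard_ratios() -> dict[str, dict[str, float]]:
    """Multivariate relative-mortality hazard ratios (reference level = 1.0)."""
    return {
        "smoking": {"never": 1.0, "ex": 1.27, "current": 1.84},
        "self_rated_health": {
            "excellent": 1.0,
            "very_good": 1.10,
            "good": 1.42,
            "fair": 2.42,
            "poor": 4.86,
        },
        "marital_status": {
            "partnered": 1.0,
            "separated_divorced": 1.09,
            "widowed": 1.10,
            "never_married": 1.36,
        },
    }
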