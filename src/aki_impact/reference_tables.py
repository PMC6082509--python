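"""Published reference counts from a two-site, two-period controlled
before-after evaluation of creatinine e-alerting in UK acute medicine.

These integer tallies — admissions per site x period cell, community-acquired
(CA) AKI counts, hospital-acquired (HA) AKI counts, and outcome counts among
HA-AKI cases — are the regression fixture for the statistics layer: the odds
ratios, Woolf intervals and exact p-values computed from them must match the
published tables to printed precision, without any patient-level data.

Cell orientation everywhere: group 1 = post period, group 2 = pre period.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .stats import TwoByTwoTable

# total acute medical admissions per cell (site, period)
TOTAL_ADMISSIONS = {
    ("intervention", "pre"): 7532,
    ("intervention", "post"): 8636,
    ("control", "pre"): 6749,
    ("control", "post"): 7378,
}

# CA-AKI present at admission; these are removed from the HA-AKI denominator
CA_AKI = {
    ("intervention", "pre"): 670,
    ("intervention", "post"): 755,
    ("control", "pre"): 491,
    ("control", "post"): 586,
}

# incident HA-AKI among admissions free of CA-AKI
HA_AKI = {
    ("intervention", "pre"): 568,
    ("intervention", "post"): 609,
    ("control", "pre"): 410,
    ("control", "post"): 453,
}

# outcome counts among HA-AKI cases
HA_OUTCOMES = {
    "death_in_hospital": {
        ("intervention", "pre"): 156,
        ("intervention", "post"): 132,
        ("control", "pre"): 94,
        ("control", "post"): 112,
    },
    "died_by_day7": {
        ("intervention", "pre"): 92,
        ("intervention", "post"): 64,
        ("control", "pre"): 37,
        ("control", "post"): 57,
    },
    "stage3": {
        ("intervention", "pre"): 47,
        ("intervention", "post"): 40,
        ("control", "pre"): 17,
        ("control", "post"): 25,
    },
    "icu_escalation": {
        ("intervention", "pre"): 42,
        ("intervention", "post"): 42,
        ("control", "pre"): 29,
        ("control", "post"): 48,
    },
}

SITES = ("intervention", "control")


def analysed_denominator(site: str, period: str) -> int:
    """Admissions entering HA-AKI analysis: total minus CA-AKI cases."""
    return TOTAL_ADMISSIONS[(site, period)] - CA_AKI[(site, period)]


def total_admissions() -> int:
    return sum(TOTAL_ADMISSIONS.values())


def overall_ha_pct() -> float:
    num = sum(HA_AKI.values())
    den = sum(analysed_denominator(s, p) for (s, p) in TOTAL_ADMISSIONS)
    return 100.0 * num / den


def overall_ca_pct() -> float:
    return 100.0 * sum(CA_AKI.values()) / total_admissions()


def incidence_table(site: str) -> TwoByTwoTable:
    """Post-vs-pre 2x2 of incident HA-AKI at one site."""
    a = HA_AKI[(site, "post")]
    c = HA_AKI[(site, "pre")]
    return TwoByTwoTable(
        a=a,
        b=analysed_denominator(site, "post") - a,
        c=c,
        d=analysed_denominator(site, "pre") - c,
        outcome="ha_aki",
    )


def outcome_table(outcome: str, site: str) -> TwoByTwoTable:
    """Post-vs-pre 2x2 of an outcome among HA-AKI cases at one site."""
    counts = HA_OUTCOMES[outcome]
    a = counts[(site, "post")]
    c = counts[(site, "pre")]
    return TwoByTwoTable(
        a=a,
        b=HA_AKI[(site, "post")] - a,
        c=c,
        d=HA_AKI[(site, "pre")] - c,
        outcome=outcome,
    )


def incidence_rows() -> pd.DataFrame:
    """Expand the HA-AKI incidence cells into one row per analysed admission.

    Every row gets a unique patient_id, so a saturated DiD logistic fit on
    this frame reproduces the ratio of within-site odds ratios exactly.
    """
    frames = []
    for (site, period) in TOTAL_ADMISSIONS:
        n = analysed_denominator(site, period)
        k = HA_AKI[(site, period)]
        frames.append(
            pd.DataFrame(
                {
                    "site": site,
                    "period": period,
                    "ha_aki": np.r_[np.ones(k, int), np.zeros(n - k, int)],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df["patient_id"] = [f"ref-{i}" for i in range(len(df))]
    return df
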