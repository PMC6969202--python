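"""Recompute cohort group-difference statistics from shipped summary data.

The package ships the published per-group summary statistics of the modelled
cohort (group sizes, means and SDs of age, IQ, head motion and symptom
scores; handedness counts; per-group correlations).  From these inputs the
pooled t-tests, the handedness chi-square, the Fisher r-to-z correlation
comparisons and the variance-ratio F-tests are recomputed from scratch.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from boldvar.inferential_stats import (
    SummaryGroup,
    chi_square,
    fisher_z_compare,
    pooled_t,
    variance_ratio,
)


def load_participant_summaries() -> dict:
    """Load the shipped per-group summary statistics."""
    ref = resources.files("boldvar.data") / "participant_summaries.json"
    return json.loads(ref.read_text())


def _grp(entry: dict) -> SummaryGroup:
    return SummaryGroup(n=entry["n"], mean=entry["mean"], sd=entry["sd"])


def group_difference_table(summaries: dict | None = None) -> pd.DataFrame:
    """Pooled two-sample t for every continuous cohort variable."""
    s = summaries or load_participant_summaries()
    g1, g2 = s["groups"]
    rows = []
    for name, grp in s["continuous"].items():
        res = pooled_t(_grp(grp[g1]), _grp(grp[g2]))
        rows.append({"variable": name, "t": res.statistic, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def handedness_test(summaries: dict | None = None):
    """Chi-square independence test on the handedness count table."""
    s = summaries or load_participant_summaries()
    h = s["handedness"]
    g1, g2 = s["groups"]
    return chi_square([h[g1], h[g2]])


def correlation_comparison_table(summaries: dict | None = None) -> pd.DataFrame:
    """Fisher r-to-z comparison of each pair of per-group correlations."""
    s = summaries or load_participant_summaries()
    rows = []
    for name, c in s["correlation_comparisons"].items():
        res = fisher_z_compare(c["r1"], c["n1"], c["r2"], c["n2"])
        rows.append({"comparison": name, "z": res.statistic, "p": res.p})
    return pd.DataFrame(rows)


def score_variance_table(summaries: dict | None = None) -> pd.DataFrame:
    """Variance-ratio F for the behavior-score SDs of the two groups."""
    s = summaries or load_participant_summaries()
    g1, g2 = s["groups"]
    rows = []
    for name, c in s["behavior_score_sds"].items():
        res = variance_ratio(
            SummaryGroup(n=c[g1]["n"], mean=0.0, sd=c[g1]["sd"]),
            SummaryGroup(n=c[g2]["n"], mean=0.0, sd=c[g2]["sd"]),
        )
        rows.append(
            {"scores": name, "F": res.statistic, "df1": res.df[0],
             "df2": res.df[1], "p": res.p}
        )
    return pd.DataFrame(rows)
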