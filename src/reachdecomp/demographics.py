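"""Published participant demographics for the two study groups.

Sixteen chronic-stroke participants (mild-to-moderate upper-extremity
impairment, Fugl-Meyer motor score 19-66, at least 6 months post-stroke)
and ten non-disabled age-matched controls.  The table ships with the
package because the demographic summaries and the age comparison are part
of the analysis; trial-level movement data are not public and are instead
emulated by :mod:`reachdecomp.synthetic`.

Note: the stroke-duration column averages to 69.7 months; published
summary text rounds this to 72.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats import two_sample_t


def load_demographics() -> pd.DataFrame:
    """Participant table: group, subject, age, gender, MMSE, side, duration, FM."""
    with resources.files("reachdecomp.data").joinpath("demographics.csv").open() as fh:
        return pd.read_csv(fh)


def demographic_summary(demo: pd.DataFrame | None = None) -> dict:
    """Group means/SEs and the pooled-variance age t-test."""
    demo = demo if demo is not None else load_demographics()
    out: dict = {}
    for g, sub in demo.groupby("group"):
        n = len(sub)
        entry = {"n": n,
                 "age_mean": float(sub["age_years"].mean()),
                 "age_se": float(sub["age_years"].std(ddof=1) / n ** 0.5)}
        if sub["fm"].notna().any():
            entry["fm_mean"] = float(sub["fm"].mean())
            entry["fm_se"] = float(sub["fm"].std(ddof=1) / n ** 0.5)
            entry["duration_mean"] = float(sub["stroke_duration_months"].mean())
            entry["duration_se"] = float(
                sub["stroke_duration_months"].std(ddof=1) / n ** 0.5)
        out[g] = entry
    t, df, p = two_sample_t(
        demo.loc[demo["group"] == "stroke", "age_years"],
        demo.loc[demo["group"] == "control", "age_years"], equal_var=True)
    out["age_ttest"] = {"t": t, "df": df, "p": p}
    return out
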