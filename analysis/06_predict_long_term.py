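"""Predicting long-term retention from training-derived metrics.

Regresses each subject's long-term performance change (Pre1 vs 1-month)
on (a) normalized learning and (b) normalized performance change, per
group, with and without the subject showing the worst long-term outcome —
the learning-performance distinction: with positive fatigue the two
predictors separate, without it they coincide.
"""

import json
from pathlib import Path

import pandas as pd

from reachdecomp import io as rio
from reachdecomp.stats import predict_long_term

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    metrics = pd.read_csv(ROOT / "study" / "metrics.csv")
    phases = rio.read_test_phases(ROOT / "study" / "test_phases.csv")
    results = {}
    for grp in ("stroke", "control"):
        m = metrics[metrics.group == grp]
        p = phases[phases.group == grp]
        worst = p.loc[p["long_term_change"].idxmin(), "subject"]
        for pred in ("normalized_learning", "normalized_performance_change"):
            full = predict_long_term(m, p, pred)
            drop = predict_long_term(m, p, pred, exclude=(worst,))
            results[f"{grp}:{pred}"] = {
                "r2": round(full.r2, 3), "p": round(full.p_value, 4),
                "n": full.n,
                "r2_without_worst": round(drop.r2, 3),
                "p_without_worst": round(drop.p_value, 4),
                "excluded": worst}
            print(f"{grp:8s} {pred:32s} R2={full.r2:.2f} (p={full.p_value:.3f}); "
                  f"without {worst}: R2={drop.r2:.2f} (p={drop.p_value:.3f})")
    (ROOT / "study" / "long_term_prediction.json").write_text(
        json.dumps(results, indent=2) + "\n")
    print(f"\nwrote {ROOT / 'study' / 'long_term_prediction.json'}")


if __name__ == "__main__":
    main()
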