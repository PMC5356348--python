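"""Derive per-subject learning and performance metrics from the fit.

Computes initial performance, amount/normalized learning, final fatigue,
normalized performance change and learning half-life for every subject
from the empirical-Bayes parameters of step 03, and prints group medians.
"""

from pathlib import Path

from reachdecomp import io as rio
from reachdecomp.metrics import metrics_frame
from reachdecomp.pipeline import _subjects_from_frame

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    params = rio.read_params(ROOT / "study" / "fitted_params.csv")
    metrics = metrics_frame(_subjects_from_frame(params), 120,
                            groups=list(params["group"]))
    metrics.to_csv(ROOT / "study" / "metrics.csv", index=False)
    for g, sub in metrics.groupby("group"):
        med = sub.median(numeric_only=True)
        print(f"{g}: median initial performance "
              f"{med['initial_performance_ms']:.0f} ms, "
              f"normalized learning {med['normalized_learning']:.2f}, "
              f"final fatigue {med['final_fatigue_ms']:.0f} ms, "
              f"half-life {med['half_life_trials']:.0f} trials")
    print(f"wrote {ROOT / 'study' / 'metrics.csv'}")


if __name__ == "__main__":
    main()
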