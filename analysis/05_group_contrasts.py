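"""Group comparisons: demographics and model-parameter contrasts.

Reproduces the demographic summaries and pooled t-test on age from the
participant table, then contrasts every fitted model parameter between
groups (Shapiro-Wilk screen, median/IQR, Mann-Whitney), writing
results/study/group_contrasts.csv.
"""

import json
from pathlib import Path

from reachdecomp import io as rio
from reachdecomp.demographics import demographic_summary
from reachdecomp.stats import contrast_parameters, contrasts_frame

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    demo = demographic_summary()
    print(f"stroke: n={demo['stroke']['n']}, age {demo['stroke']['age_mean']:.1f} "
          f"± {demo['stroke']['age_se']:.1f} y, FM {demo['stroke']['fm_mean']:.1f}, "
          f"duration {demo['stroke']['duration_mean']:.1f} mo")
    print(f"control: n={demo['control']['n']}, age "
          f"{demo['control']['age_mean']:.1f} ± {demo['control']['age_se']:.1f} y")
    print(f"age difference: pooled t-test p = {demo['age_ttest']['p']:.3f}")

    params = rio.read_params(ROOT / "study" / "fitted_params.csv")
    contrasts = contrasts_frame(contrast_parameters(params))
    contrasts.to_csv(ROOT / "study" / "group_contrasts.csv", index=False)
    print("\nparameter contrasts (stroke vs control):")
    cols = ["parameter", "median_stroke", "median_control", "p"]
    print(contrasts[cols].round(3).to_string(index=False))
    larger = (contrasts["median_stroke"] > contrasts["median_control"]).sum()
    print(f"\nstroke median larger in {larger}/8 parameters")
    (ROOT / "study" / "demographics.json").write_text(
        json.dumps(demo, indent=2, default=float) + "\n")


if __name__ == "__main__":
    main()
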