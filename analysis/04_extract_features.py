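"""Extract the 77-variable per-epoch feature matrices for every cohort.

Writes one CSV per cohort under scratch/ (multi-megabyte intermediates;
features + subject, stage and AHI/ODI labels per row); later steps load
these instead of recomputing.
"""

import warnings
from pathlib import Path

from edasleep.pipeline import cohort_features
from edasleep.synth import Scenario, generate_cohort, osa_scenario

OUT = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    warnings.filterwarnings("ignore")
    cohorts = {
        "strong": generate_cohort(10, Scenario(n_epochs=120), seed=0),
        "null": generate_cohort(10, Scenario(n_epochs=120, null_stages=True), seed=1),
        "osa": generate_cohort(20, osa_scenario(n_epochs=120), seed=2),
    }
    OUT.mkdir(exist_ok=True)
    for name, cohort in cohorts.items():
        fm = cohort_features(cohort)
        fm.to_csv(OUT / f"features_{name}.csv")
        print(f"{name}: {fm.features.shape[0]} epochs x "
              f"{fm.features.shape[1]} features -> features_{name}.csv")


if __name__ == "__main__":
    main()
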