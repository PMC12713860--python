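"""Correlation-based feature reduction on the strong cohort.

Fits the greedy |r| > 0.8 elimination scan on the pooled strong-cohort
feature matrix (the whole-cohort fit mirrors the original protocol;
the classifiers below refit it inside every training fold) and writes
the retained-column manifest plus the elimination trace.
"""

import json
from pathlib import Path

from edasleep.features import FeatureMatrix
from edasleep.reduce import reduce_features

OUT = Path(__file__).resolve().parent.parent / "results"
FEAT = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    fm = FeatureMatrix.from_csv(FEAT / "features_strong.csv")
    numeric = fm.numeric_columns
    cols, res = reduce_features(fm, r_th=0.8)
    payload = {
        "r_th": res.r_th,
        "n_input": len(numeric) + 1,
        "n_retained": len(cols),
        "retained_columns": cols,
        "eliminated": [
            {"dropped": numeric[j], "anchor": numeric[a], "r": round(r, 4)}
            for j, a, r in res.eliminated
        ],
    }
    (OUT / "reduction.json").write_text(json.dumps(payload, indent=2))
    print(f"retained {len(cols)}/77 features at r_th=0.8 -> reduction.json")
    print("first eliminations:", payload["eliminated"][:5])


if __name__ == "__main__":
    main()
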