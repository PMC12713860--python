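"""SHAP interpretation of the staging and OSA models.

Trains one model per task on the full (normalised, reduced) cohort and
ranks features by mean |SHAP| (TreeSHAP, summed over class outputs);
writes the top-20 tables and, when matplotlib is available, a bar plot
per task.
"""

import warnings
from pathlib import Path

import pandas as pd

from edasleep.features import FeatureMatrix, FeatureNormalizer
from edasleep.metrics import shap_report
from edasleep.model import LabelSpec, make_labels, smote_balance, train_classifier
from edasleep.reduce import reduce_features

OUT = Path(__file__).resolve().parent.parent / "results"
FEAT = Path(__file__).resolve().parent.parent / "scratch"


def rank_for(fm: FeatureMatrix, task: str, seed: int = 0) -> pd.DataFrame:
    spec = LabelSpec(task)
    norm = FeatureNormalizer().fit(fm)
    fm_n = norm.transform(fm)
    cols, _ = reduce_features(fm_n, r_th=0.8)
    X = fm_n.data[cols]
    y = make_labels(fm_n, spec)
    Xb, yb = smote_balance(X, y, seed=seed)
    model = train_classifier(Xb, yb, seed=seed)
    ranking = shap_report(model, X, top_k=20)
    return pd.DataFrame(ranking, columns=["feature", "mean_abs_shap"])


def main() -> None:
    warnings.filterwarnings("ignore")
    strong = FeatureMatrix.from_csv(FEAT / "features_strong.csv")
    osa = FeatureMatrix.from_csv(FEAT / "features_osa.csv")
    tables = {}
    for task, fm in (("stage4", strong), ("osa3_ahi", osa)):
        table = rank_for(fm, task)
        table.to_csv(OUT / f"shap_top20_{task}.csv", index=False)
        tables[task] = table
        print(f"{task} top 5:\n{table.head().to_string(index=False)}\n")
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(12, 6))
        for ax, (task, table) in zip(axes, tables.items()):
            ax.barh(table["feature"][::-1], table["mean_abs_shap"][::-1])
            ax.set_title(task)
            ax.set_xlabel("mean |SHAP|")
        fig.tight_layout()
        fig.savefig(OUT / "shap_top20.png", dpi=120)
        print("-> shap_top20_*.csv / shap_top20.png")
    except ImportError:
        print("-> shap_top20_*.csv (matplotlib unavailable; no plot)")


if __name__ == "__main__":
    main()
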