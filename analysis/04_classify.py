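"""Hemisphere classification from the biomarker entropy features.

The entropy values of the biomarker regions form each subject's
feature vector for an RBF-kernel SVM.  (C, g) are tuned by exhaustive
base-2 grid search with stratified inner cross-validation, and the
classifier is evaluated two ways: leave-one-out cross-validation over
all 20 subjects, and a single class-balanced 8-train / 12-test split.

Run after 03_select_biomarkers.py.
"""

import json
from pathlib import Path

import numpy as np

from mselat import BiomarkerSet, SvmGridConfig, holdout_eval, loocv
from mselat.io import read_dataset, read_entropy_matrix, _write_loocv

OUT = Path("results")

# exponent step 1.0 keeps the exhaustive search tractable on one CPU;
# the selected accuracy is insensitive to finer steps on this cohort
SVM_CFG = SvmGridConfig(exponent_step=1.0)


def main() -> None:
    ds = read_dataset(OUT / "dataset" / "manifest.tsv")
    mat, names = read_entropy_matrix(OUT / "entropy_matrix.tsv")
    bio = json.loads((OUT / "biomarkers.json").read_text())
    bs = BiomarkerSet(
        region_indices=bio["region_indices"], region_names=bio["region_names"],
        pvalues=np.asarray(bio["pvalues"]), aucs=np.asarray(bio["aucs"]),
        params=mat.params, alpha_final=bio["alpha_final"],
    )
    result = loocv(mat, bs, ds.labels, SVM_CFG)
    _write_loocv(OUT, result)
    n_correct = sum(t == p for _, t, p, _, _ in result.per_subject)
    print(f"LOOCV over {len(result.per_subject)} subjects: "
          f"{n_correct} correct -> mean accuracy {result.mean_accuracy:.2%}")
    acc = holdout_eval(mat, bs, ds.labels, train_n=8, seed=1, cfg=SVM_CFG)
    print(f"balanced 8-train / 12-test holdout: accuracy {acc:.2%}")
    print(f"per-subject predictions in {OUT}/loocv_predictions.tsv")


if __name__ == "__main__":
    main()
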