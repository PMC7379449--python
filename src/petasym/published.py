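"""Published reference lateralization rules and the test-set label table.

The original clinical study printed its learned models verbatim: a
single-split hippocampal tree and a two-region linear score for the
60:40 train/test experiment, plus five single-split trees and five
linear scores from its 5-fold cross-validation runs.  These, together
with the per-patient lateralization columns of its 18-patient test set
(definitive postsurgical side, two readers, consensus, voxel-wise SPM
result, and both data-mining predictions), are reproduced here as model
objects and a DataFrame so the evaluation arithmetic can be exercised
without any patient images.
"""

from __future__ import annotations

import pandas as pd

from .lmt import LinearScoreModel, LogisticModelTreeClassifier
from .tree import C45TreeClassifier, TreeNode

HIP = "Hippocampus"
TPM = "Temporal pole of middle temporal gyrus"

#: Token used when a method produced no lateralization call; always
#: counted as incorrect by correct_ratio.
NO_LATERALIZATION = "No lateralization"


def _single_split_tree(feature: str, threshold: float,
                       le_class: str = "Left", gt_class: str = "Right") -> TreeNode:
    return TreeNode(feature=feature, threshold=threshold,
                    le=TreeNode(leaf_class=le_class),
                    gt=TreeNode(leaf_class=gt_class))


def load_published_rules() -> dict:
    """The printed models as fitted classifier objects.

    Returns a dict with:

    * ``j48_test_model`` — "Left if AI[Hippocampus] <= 3.18, else Right";
    * ``lmt_test_model`` — score(Right) = -0.06 + 0.08*AI[Hippocampus]
      + 0.03*AI[Temporal pole of middle temporal gyrus];
    * ``cv_run_models`` — five dicts with run number, both models, and
      the printed per-run correct/total counts.
    """
    j48 = C45TreeClassifier.from_tree(_single_split_tree(HIP, 3.18))
    lmt = LogisticModelTreeClassifier.from_linear_model(
        LinearScoreModel(intercept=-0.06, coef={HIP: 0.08, TPM: 0.03}))

    runs = [
        dict(run=1,
             j48=_single_split_tree("Inferior temporal gyrus", -3.99),
             j48_correct=(9, 10),
             lmt=LinearScoreModel(-0.13, {HIP: 0.07, TPM: 0.02}),
             lmt_correct=(10, 10)),
        dict(run=2,
             j48=_single_split_tree("Inferior temporal gyrus", -3.99),
             j48_correct=(10, 10),
             lmt=LinearScoreModel(-0.14, {HIP: 0.07}),
             lmt_correct=(9, 10)),
        dict(run=3,
             j48=_single_split_tree("Parahippocampal gyrus", -5.46),
             j48_correct=(9, 9),
             lmt=LinearScoreModel(-0.16, {HIP: 0.07, TPM: 0.02}),
             lmt_correct=(9, 9)),
        dict(run=4,
             j48=_single_split_tree("Rolandic operculum", 2.06),
             j48_correct=(8, 10),
             lmt=LinearScoreModel(-0.09, {HIP: 0.07, TPM: 0.03}),
             lmt_correct=(9, 10)),
        dict(run=5,
             j48=_single_split_tree("Parahippocampal gyrus", -0.24),
             j48_correct=(7, 10),
             lmt=LinearScoreModel(-0.23, {HIP: 0.07, TPM: 0.02}),
             lmt_correct=(10, 10)),
    ]
    cv_run_models = [
        dict(run=r["run"],
             j48=C45TreeClassifier.from_tree(r["j48"]),
             lmt=LogisticModelTreeClassifier.from_linear_model(r["lmt"]),
             j48_correct=r["j48_correct"], lmt_correct=r["lmt_correct"])
        for r in runs
    ]
    return {"j48_test_model": j48, "lmt_test_model": lmt,
            "cv_run_models": cv_run_models}


def test_set_lateralizations() -> pd.DataFrame:
    """Per-patient lateralization calls for the 18-subject test set.

    Columns: patient number, definitive (postsurgical) side, the two
    readers and their consensus, the voxel-wise SPM call (with two
    ``No lateralization`` entries), and the J48/LMT predictions.
    """
    L, R, NL = "Left", "Right", NO_LATERALIZATION
    rows = [
        # patient, definitive, reader1, reader2, consensus, spm, j48, lmt
        (1,  L, L, L, L, L,  L, L),
        (2,  L, L, L, L, L,  L, L),
        (3,  L, L, L, L, L,  L, L),
        (4,  L, L, L, L, L,  L, L),
        (5,  L, L, L, L, L,  L, L),
        (6,  L, L, L, L, L,  L, L),
        (7,  L, L, L, L, L,  L, L),
        (8,  L, L, L, L, L,  L, L),
        (9,  R, R, R, R, R,  R, R),
        (10, R, R, R, R, R,  R, R),
        (11, L, L, L, L, L,  L, L),
        (12, L, L, L, L, NL, R, R),
        (13, R, R, L, R, R,  R, R),
        (14, R, R, R, R, NL, R, R),
        (15, R, R, R, R, R,  R, R),
        (16, R, R, R, R, R,  R, R),
        (17, R, R, R, R, R,  R, R),
        (18, R, R, R, R, R,  L, R),
    ]
    return pd.DataFrame(rows, columns=[
        "patient", "definitive", "reader1", "reader2", "consensus",
        "spm", "j48", "lmt"])


#: The worked example: one left-TLE patient whose AI values led both
#: published rules to call "Right TLE" (the documented false call).
WORKED_EXAMPLE_FEATURES = {HIP: 5.71, TPM: 7.94}
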