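#!/usr/bin/env python
"""Audit subject-level vs slice-level fold assignments for leakage exposure.

Preprocesses the null cohort, deals folds under both strategies across
several seeds, and writes the per-fold fraction of test slices whose
subject also appears in training (results/leakage_audit.csv).  This is the
structural half of the argument: slice-level splits expose essentially
every test slice to a same-subject training sibling before any model is
trained.
"""

from pathlib import Path

import pandas as pd

from sliceleak.experiment import desk_null_config
from sliceleak.folds import SLICE_LEVEL, SUBJECT_LEVEL, audit_leakage, make_folds
from sliceleak.preprocess import PreprocessConfig, preprocess_cohort
from sliceleak.synthetic import generate_cohort

OUT = Path("results/leakage_audit.csv")


def main():
    cohort = generate_cohort(desk_null_config(seed=0))
    slices = preprocess_cohort(cohort, PreprocessConfig())
    rows = []
    for strategy in (SUBJECT_LEVEL, SLICE_LEVEL):
        for seed in range(5):
            assignment = make_folds(slices, strategy, k=5, seed=seed)
            per_fold, overall = audit_leakage(assignment, slices)
            rows.append(
                {
                    "strategy": strategy,
                    "seed": seed,
                    "overall_exposure": overall,
                    **{f"fold_{i}": v for i, v in enumerate(per_fold)},
                }
            )
    frame = pd.DataFrame(rows)
    OUT.parent.mkdir(exist_ok=True)
    frame.to_csv(OUT, index=False)
    print(frame.groupby("strategy")["overall_exposure"].describe()[["mean", "min", "max"]])
    print(f"\nwrote {OUT}")
    print(
        "subject-level folds expose 0% of test slices; slice-level folds "
        "expose ~100% — every test slice has near-duplicate training siblings"
    )


if __name__ == "__main__":
    main()
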