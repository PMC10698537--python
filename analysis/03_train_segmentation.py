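"""Train the dual-pathway segmentation CNN with 5-fold slide-level cross-validation.

Desk-scale protocol: tiny backbone, Adam with exponentially decaying learning
rate, inverse-frequency class weights, flip/rotation/photometric augmentation,
early stopping on validation loss. Writes the per-fold training history and
the slide-to-fold manifest; trained fold models go to scratch for the feature
and evaluation steps.
"""

import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd
from common import MASTER_SEED, RESULTS, SCRATCH, ensure_dirs, need

from phccsurv.segmentation import SegModelConfig, train_cv


def main():
    ensure_dirs()
    with open(need(SCRATCH / "patch_pairs.pkl", "02_preprocess.py"), "rb") as fh:
        state = pickle.load(fh)
    config = SegModelConfig(
        backbone="tiny",
        learning_rate=0.02,
        lr_decay=0.95,
        transfer_epochs=0,
        finetune_epochs=15,
        early_stopping_patience=8,
        folds=5,
        seed=MASTER_SEED,
    )
    folds = train_cv(state["pairs"], config)

    history = pd.concat(
        [pd.DataFrame(f.history).assign(fold=f.fold_index) for f in folds],
        ignore_index=True,
    )
    history.to_csv(RESULTS / "seg_training_history.csv", index=False)
    manifest = pd.DataFrame(
        [
            {"slide_id": sid, "fold": f.fold_index, "role": role}
            for f in folds
            for role, ids in (("train", f.train_slides), ("validation", f.val_slides))
            for sid in ids
        ]
    )
    manifest.to_csv(RESULTS / "seg_fold_manifest.csv", index=False)
    with open(SCRATCH / "trained_folds.pkl", "wb") as fh:
        pickle.dump({"config": config, "grid": state["grid"], "folds": folds}, fh)

    last = history.groupby("fold").last()
    print("final validation loss per fold:")
    print(last[["epoch", "val_loss"]].to_string())
    for f in folds:
        assert not set(f.train_slides) & set(f.val_slides)
    print("slide-level split verified: train/validation disjoint in every fold")


if __name__ == "__main__":
    main()
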