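"""Evaluate the segmentation CV out-of-fold: per-slide metrics, pooled ROC, heatmaps.

Every slide is predicted by the fold model that held it out. Reports
accuracy/specificity/sensitivity/precision/F1 per slide with Clopper-Pearson
95% CIs on the pooled pixel counts, the pooled ROC-AUC over all predictions
together, and renders white-to-red probability heatmaps with the ground truth
contoured in green for the best- and worst-F1 slides.
"""

import json
import pickle
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd
from PIL import Image
from common import RESULTS, SCRATCH, ensure_dirs, need

from phccsurv.segeval import clopper_pearson, pooled_roc, render_heatmap, slide_metrics
from phccsurv.segmentation import predict_slide
from phccsurv.synthetic import load_slide


def main():
    ensure_dirs()
    with open(need(SCRATCH / "trained_folds.pkl", "03_train_segmentation.py"), "rb") as fh:
        state = pickle.load(fh)
    slide_dir = SCRATCH / "slides"

    rows, probs, truths, maps = [], [], [], {}
    for f in state["folds"]:
        for sid in f.val_slides:
            slide = load_slide(slide_dir, sid)
            pm = predict_slide(f.model, slide, state["grid"])
            m = slide_metrics(pm.binary, slide.tumor_mask, valid=pm.visited)
            rows.append({"slide_id": sid, "fold": f.fold_index, "tp": m.tp, "fp": m.fp,
                         "tn": m.tn, "fn": m.fn, "accuracy": m.accuracy,
                         "specificity": m.specificity, "sensitivity": m.sensitivity,
                         "precision": m.precision, "f1": m.f1})
            probs.append(pm.prob)
            truths.append(slide.tumor_mask)
            maps[sid] = (pm, slide)
    metrics = pd.DataFrame(rows).sort_values("slide_id")
    metrics.to_csv(RESULTS / "seg_metrics.csv", index=False)

    tp, fp = metrics.tp.sum(), metrics.fp.sum()
    tn, fn = metrics.tn.sum(), metrics.fn.sum()
    n = tp + fp + tn + fn
    *_, auc = pooled_roc(probs, truths)
    pooled = {
        "pixels_evaluated": int(n),
        "accuracy": (tp + tn) / n,
        "accuracy_ci": clopper_pearson(int(tp + tn), int(n)),
        "specificity": tn / (tn + fp),
        "specificity_ci": clopper_pearson(int(tn), int(tn + fp)),
        "sensitivity": tp / (tp + fn),
        "sensitivity_ci": clopper_pearson(int(tp), int(tp + fn)),
        "precision": tp / (tp + fp),
        "precision_ci": clopper_pearson(int(tp), int(tp + fp)),
        "f1": 2 * tp / (2 * tp + fp + fn),
        "pooled_roc_auc": auc,
    }
    with open(RESULTS / "seg_pooled.json", "w") as fh:
        json.dump(pooled, fh, indent=1)

    heat_dir = SCRATCH / "heatmaps"
    heat_dir.mkdir(exist_ok=True)
    for label, sid in (("best", metrics.loc[metrics.f1.idxmax(), "slide_id"]),
                       ("worst", metrics.loc[metrics.f1.idxmin(), "slide_id"])):
        pm, slide = maps[sid]
        img = render_heatmap(pm.prob, slide.tumor_mask)
        Image.fromarray(img).save(heat_dir / f"{label}_{sid}_heatmap.png")

    print(f"out-of-fold evaluation over {len(metrics)} slides, {n} pixels")
    print(f"pooled: acc {pooled['accuracy']:.3f}, spec {pooled['specificity']:.3f}, "
          f"sens {pooled['sensitivity']:.3f}, prec {pooled['precision']:.3f}, "
          f"F1 {pooled['f1']:.3f}, ROC-AUC {auc:.3f}")
    print(f"per-slide F1: min {metrics.f1.min():.3f}, median {metrics.f1.median():.3f}, "
          f"max {metrics.f1.max():.3f}; heatmaps in {heat_dir}")


if __name__ == "__main__":
    main()
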