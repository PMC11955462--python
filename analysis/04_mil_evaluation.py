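"""Aggregate patch predictions into patient-level calls under four MIL
strategies and report the metric suite.

Each patient is a bag of patch instances; the bag probability is pooled
as the mean, top-10 mean, top-100 mean, or maximum of the instance
probabilities, thresholded at 0.5.  Reports AUC, accuracy, precision,
recall and F1 per strategy on the held-out validation patients.

Usage: python analysis/04_mil_evaluation.py [--seed 1] [--out results/run]
"""

import argparse
import json
from pathlib import Path

from hemil.presets import end_to_end_config
from hemil.workflow import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    out = Path(args.out)
    run_pipeline(end_to_end_config(args.seed, args.out),
                 stages=["predict", "aggregate", "evaluate"])

    metrics = json.loads((out / "metrics.json").read_text())
    print(f"{'strategy':<8} {'AUC':>6} {'acc':>6} {'prec':>6} {'rec':>6} {'F1':>6}"
          "   (validation patients)")
    for strat in ("mean", "top10", "top100", "max"):
        m = metrics["val"][strat]
        print(f"{strat:<8} {m['auc']:6.4f} {m['accuracy']:6.4f} "
              f"{m['precision']:6.4f} {m['recall']:6.4f} {m['f1']:6.4f}")
    print(f"full report: {out / 'metrics.json'}")


if __name__ == "__main__":
    main()
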