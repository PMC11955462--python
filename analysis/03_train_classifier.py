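"""Split the cohort and train the residual patch classifier.

Patients are split 80/20 (label-stratified, patient-level so no patch of
a validation patient is seen in training), and the reduced residual
backbone is trained with SGD momentum 0.9 on cross-entropy, saving the
checkpoint of the first epoch that achieves the best validation accuracy.

Usage: python analysis/03_train_classifier.py [--seed 1] [--out results/run]
"""

import argparse
from pathlib import Path

import pandas as pd

from hemil.presets import end_to_end_config
from hemil.workflow import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    out = Path(args.out)
    run_pipeline(end_to_end_config(args.seed, args.out), stages=["split", "train"])

    split = pd.read_csv(out / "split.csv")
    log = pd.read_csv(out / "training_log.csv")
    best = log[log["is_best"]].iloc[-1]
    print(f"split: {(split['split'] == 'train').sum()} train / "
          f"{(split['split'] == 'val').sum()} validation patients")
    print(log.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    print(f"best checkpoint: epoch {int(best['epoch'])} "
          f"(val accuracy {best['val_accuracy']:.4f}) -> {out / 'checkpoint.npz'}")


if __name__ == "__main__":
    main()
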