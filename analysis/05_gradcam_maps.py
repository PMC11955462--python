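"""Render Grad-CAM heatmaps for a few patches of the trained model.

The class-activation map is computed at the last residual stage: channel
weights are spatially averaged gradients of the "high" logit, combined
into a rectified heatmap, upsampled to 224x224 and overlaid on the H&E
patch.  On the synthetic cohort the hot regions should sit on the brown
macrophage-like blobs that carry the planted signal.

Usage: python analysis/05_gradcam_maps.py [--seed 1] [--out results/run]
"""

import argparse
from pathlib import Path

from hemil.presets import end_to_end_config
from hemil.workflow import run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", default="results/run")
    args = ap.parse_args()
    out = Path(args.out)
    run_pipeline(end_to_end_config(args.seed, args.out), stages=["gradcam"])
    maps = sorted((out / "gradcam_maps").glob("*_overlay.png"))
    print(f"wrote {len(maps)} heatmap/overlay pairs under {out / 'gradcam_maps'}:")
    for p in maps:
        print(" ", p.name)


if __name__ == "__main__":
    main()
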