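"""Configuration-driven orchestration of the full study loop.

Canonical stage order::

    simulate -> tile -> deconvolve -> label -> split -> train -> predict
             -> aggregate -> evaluate -> gradcam -> survival

Each stage reads the artifacts of its upstream stages from the run
directory and writes its own in plain formats (CSV/TSV/JSON/PNG/NPZ).
A run manifest records the config hash, the per-stage seeds and SHA-256
checksums of every input and output, so a completed stage is skipped on
resume when its recorded checksums still match, and the manifest alone
suffices to re-execute the run bit-identically on the same platform.

Per-stage seeds are derived from the global seed and the stage name, so
any stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import classifier, deconv, gradcam, mil, patches, survival, synthetic

log = logging.getLogger(__name__)

STAGES = ["simulate", "tile", "deconvolve", "label", "split", "train",
          "predict", "aggregate", "evaluate", "gradcam", "survival"]

#: artifacts each stage consumes (dependency -> producing stage)
STAGE_INPUTS = {
    "simulate": {},
    "tile": {"cohort/manifest.json": "simulate"},
    "deconvolve": {"cohort/expression.tsv": "simulate"},
    "label": {"fractions.csv": "deconvolve"},
    "split": {"labels.csv": "label"},
    "train": {"patches.npy": "tile", "patch_manifest.csv": "tile",
              "labels.csv": "label", "split.csv": "split"},
    "predict": {"checkpoint.npz": "train", "patches.npy": "tile"},
    "aggregate": {"predictions.csv": "predict"},
    "evaluate": {"bag_predictions.csv": "aggregate", "labels.csv": "label"},
    "gradcam": {"checkpoint.npz": "train", "patches.npy": "tile"},
    "survival": {"cohort/survival.csv": "simulate", "labels.csv": "label"},
}


class DependencyError(RuntimeError):
    def __init__(self, stage: str, missing: str, producer: str):
        super().__init__(f"stage {stage!r} is missing {missing!r}; "
                         f"run stage {producer!r} first")
        self.producer = producer


class ConfigError(ValueError):
    def __init__(self, fields: list[str]):
        super().__init__("invalid config fields: " + ", ".join(fields))
        self.fields = fields


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    cohort: dict = field(default_factory=dict)          # SyntheticCohortSpec overrides
    tiling: dict = field(default_factory=lambda: {"tile_size": 224, "stride": 224})
    filtering: dict = field(default_factory=lambda: {
        "whiteness_cutoff": patches.DEFAULT_WHITENESS_CUTOFF,
        "min_tissue_fraction": patches.DEFAULT_MIN_TISSUE_FRACTION})
    deconvolution: dict = field(default_factory=lambda: {
        "nu_grid": list(deconv.DEFAULT_NU_GRID)})
    labels_from: str = "deconvolution"  # or "truth"
    backbone: dict = field(default_factory=dict)        # BackboneConfig overrides
    training: dict = field(default_factory=dict)        # TrainConfig overrides
    mil: dict = field(default_factory=lambda: {
        "strategies": ["mean", "top10", "top100", "max"], "threshold": 0.5})
    gradcam: dict = field(default_factory=lambda: {"n_patches": 4})
    survival_covariates: list = field(default_factory=lambda: ["group", "age", "stage"])

    def __post_init__(self) -> None:
        bad = []
        if self.labels_from not in ("deconvolution", "truth"):
            bad.append("labels_from")
        for s in self.mil.get("strategies", []):
            if s not in mil.STRATEGY_K:
                bad.append(f"mil.strategies[{s}]")
        if bad:
            raise ConfigError(bad)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ConfigError(unknown)
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2 ** 31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    """One pipeline execution over a run directory."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.out / "run_manifest.json"
        if self.manifest_path.exists():
            self.manifest = json.loads(self.manifest_path.read_text())
        else:
            self.manifest = {"stages": {}, "metrics": {}}
        cfg_json = json.dumps(config.to_dict(), sort_keys=True)
        self.manifest["config"] = config.to_dict()
        self.manifest["config_hash"] = hashlib.sha256(cfg_json.encode()).hexdigest()
        self.manifest["seed"] = config.seed

    # -- helpers -----------------------------------------------------------
    def _p(self, rel: str) -> Path:
        return self.out / rel

    def _require(self, stage: str) -> None:
        for rel, producer in STAGE_INPUTS[stage].items():
            if not self._p(rel).exists():
                raise DependencyError(stage, rel, producer)

    def _record(self, stage: str, outputs: list[str]) -> None:
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage),
            "inputs": {rel: _sha256(self._p(rel)) for rel in STAGE_INPUTS[stage]},
            "outputs": {rel: _sha256(self._p(rel)) for rel in outputs},
            "completed": True,
        }
        self._save()

    def _save(self) -> None:
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True))

    def _up_to_date(self, stage: str) -> bool:
        entry = self.manifest["stages"].get(stage)
        if not entry or not entry.get("completed"):
            return False
        try:
            ins = all(_sha256(self._p(r)) == h for r, h in entry["inputs"].items())
            outs = all(_sha256(self._p(r)) == h for r, h in entry["outputs"].items())
        except FileNotFoundError:
            return False
        return ins and outs

    # -- stages ------------------------------------------------------------
    def simulate(self) -> list[str]:
        spec = synthetic.SyntheticCohortSpec(
            seed=stage_seed(self.cfg.seed, "simulate"), **self.cfg.cohort)
        synthetic.generate_cohort(spec, self.out / "cohort")
        outs = ["cohort/manifest.json", "cohort/ground_truth.csv",
                "cohort/expression.tsv", "cohort/signature.tsv", "cohort/survival.csv"]
        return outs

    def tile(self) -> list[str]:
        cohort = json.loads(self._p("cohort/manifest.json").read_text())
        cutoff = self.cfg.filtering["whiteness_cutoff"]
        min_tf = self.cfg.filtering["min_tissue_fraction"]
        stacks, rows = [], []
        for pid, files in sorted(cohort["files"]["tiles"].items()):
            for rel in files:
                img = np.asarray(Image.open(self.out / "cohort" / rel).convert("RGB"))
                source = Path(rel).stem
                recs = patches.tile_image(img, source_id=source,
                                          tile_size=self.cfg.tiling["tile_size"],
                                          stride=self.cfg.tiling["stride"])
                for r in recs:
                    r.tissue_fraction = patches.tissue_fraction(r, cutoff)
                kept = patches.filter_background(recs, min_tf)
                for r in kept:
                    rows.append({"patch_id": r.patch_id, "patient_id": pid,
                                 "source_id": r.source_id, "grid_row": r.grid_row,
                                 "grid_col": r.grid_col,
                                 "tissue_fraction": r.tissue_fraction})
                    stacks.append(r.pixels)
        np.save(self._p("patches.npy"), np.stack(stacks) if stacks else
                np.zeros((0, 224, 224, 3), np.uint8))
        pd.DataFrame(rows).to_csv(self._p("patch_manifest.csv"), index=False)
        return ["patches.npy", "patch_manifest.csv"]

    def deconvolve(self) -> list[str]:
        expr = pd.read_csv(self._p("cohort/expression.tsv"), sep="\t", index_col=0)
        sig = pd.read_csv(self._p("cohort/signature.tsv"), sep="\t", index_col=0)
        frac = deconv.estimate_fraction_table(
            expr, sig, tuple(self.cfg.deconvolution["nu_grid"]))
        frac.rename_axis("sample_id").to_csv(self._p("fractions.csv"))
        return ["fractions.csv"]

    def label(self) -> list[str]:
        if self.cfg.labels_from == "truth":
            truth = pd.read_csv(self._p("cohort/ground_truth.csv"))
            frac = truth.set_index("patient_id")[["true_m2_fraction"]]
            frac.columns = ["M2"]
        else:
            frac = pd.read_csv(self._p("fractions.csv"), index_col=0)
        kept = deconv.exclude_zero_m2(frac, "M2")
        lab = deconv.dichotomize_by_mean(kept, "M2")
        lab.labels.rename_axis("sample_id").to_frame().to_csv(self._p("labels.csv"))
        self._p("label_boundary.json").write_text(json.dumps(
            {"boundary": lab.boundary, "celltype": "M2",
             "n_labeled": len(kept), "n_excluded": len(frac) - len(kept)},
            indent=2, sort_keys=True))
        return ["labels.csv", "label_boundary.json"]

    def _bags(self) -> list[mil.Bag]:
        labels = pd.read_csv(self._p("labels.csv"), index_col=0)["label"]
        pm = pd.read_csv(self._p("patch_manifest.csv"))
        bags = []
        for pid, sub in pm.groupby("patient_id"):
            if pid in labels.index:
                bags.append(mil.Bag(patient_id=pid,
                                    patch_ids=list(sub["patch_id"]),
                                    label=labels.loc[pid]))
        return bags

    def split(self) -> list[str]:
        tc = classifier.TrainConfig(seed=stage_seed(self.cfg.seed, "split"),
                                    **self.cfg.training)
        train_bags, val_bags = classifier.split_cohort(self._bags(), tc)
        rows = ([{"patient_id": b.patient_id, "split": "train"} for b in train_bags]
                + [{"patient_id": b.patient_id, "split": "val"} for b in val_bags])
        pd.DataFrame(rows).sort_values("patient_id").to_csv(
            self._p("split.csv"), index=False)
        return ["split.csv"]

    def _patch_arrays(self):
        pm = pd.read_csv(self._p("patch_manifest.csv"))
        px = np.load(self._p("patches.npy"))
        return pm, px

    def train(self) -> list[str]:
        pm, px = self._patch_arrays()
        labels = pd.read_csv(self._p("labels.csv"), index_col=0)["label"]
        split = pd.read_csv(self._p("split.csv"), index_col=0)["split"]
        pm = pm[pm["patient_id"].isin(labels.index)]
        y = (labels.loc[pm["patient_id"]] == "high").to_numpy().astype(int)
        sides = split.loc[pm["patient_id"]].to_numpy()
        x = np.stack([patches.normalize_patch(px[i]) for i in pm.index]).astype(np.float32)
        bc = classifier.BackboneConfig(**self.cfg.backbone)
        tc = classifier.TrainConfig(seed=stage_seed(self.cfg.seed, "train"),
                                    **self.cfg.training)
        model = classifier.build_backbone(bc, seed=tc.seed)
        model, records = classifier.train(model, x[sides == "train"], y[sides == "train"],
                                          x[sides == "val"], y[sides == "val"], tc)
        best = [r for r in records if r.is_best][-1]
        model.save_weights(self._p("checkpoint.npz"),
                           meta={"best_epoch": best.epoch,
                                 "val_accuracy": best.val_accuracy})
        pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
            self._p("training_log.csv"), index=False)
        return ["checkpoint.npz", "checkpoint.json", "training_log.csv"]

    def _load_model(self) -> classifier.Backbone:
        bc = classifier.BackboneConfig(**self.cfg.backbone)
        model = classifier.build_backbone(bc, seed=0)
        model.load_weights(self._p("checkpoint.npz"))
        return model

    def predict(self) -> list[str]:
        pm, px = self._patch_arrays()
        model = self._load_model()
        x = np.stack([patches.normalize_patch(p) for p in px]).astype(np.float32)
        probs = classifier.predict_patch_probs(model, x)
        out = pm[["patch_id", "patient_id"]].copy()
        out["prob_high"] = probs
        out.to_csv(self._p("predictions.csv"), index=False)
        return ["predictions.csv"]

    def aggregate(self) -> list[str]:
        preds = pd.read_csv(self._p("predictions.csv"))
        by_bag = {pid: sub["prob_high"].to_numpy()
                  for pid, sub in preds.groupby("patient_id")}
        rows = []
        for strat in self.cfg.mil["strategies"]:
            for bp in mil.predict_bags(by_bag, strat,
                                       threshold=self.cfg.mil["threshold"]):
                rows.append(dataclasses.asdict(bp))
        pd.DataFrame(rows).to_csv(self._p("bag_predictions.csv"), index=False)
        return ["bag_predictions.csv"]

    def evaluate(self) -> list[str]:
        bp = pd.read_csv(self._p("bag_predictions.csv"))
        labels = pd.read_csv(self._p("labels.csv"), index_col=0)["label"]
        split = pd.read_csv(self._p("split.csv"), index_col=0)["split"]
        report: dict[str, dict] = {}
        for side in ("train", "val"):
            ids = split[split == side].index
            report[side] = {}
            for strat, sub in bp.groupby("strategy"):
                sub = sub[sub["patient_id"].isin(ids)].set_index("patient_id")
                if sub.empty:
                    continue
                m = mil.compute_metrics(labels.loc[sub.index],
                                        sub["predicted_label"], sub["bag_prob"])
                report[side][strat] = dataclasses.asdict(m)
        self._p("metrics.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        self.manifest["metrics"] = report
        return ["metrics.json"]

    def gradcam(self) -> list[str]:
        pm, px = self._patch_arrays()
        model = self._load_model()
        gdir = self._p("gradcam_maps")
        gdir.mkdir(exist_ok=True)
        n = min(self.cfg.gradcam["n_patches"], len(pm))
        outs = []
        for i in range(n):
            rec = pm.iloc[i]
            x = patches.normalize_patch(px[i]).astype(np.float32)
            hm = gradcam.gradcam(model, x, "high")
            raw = (hm.upsampled * 255).astype(np.uint8)
            Image.fromarray(raw).save(gdir / f"{rec.patch_id}_heat.png")
            Image.fromarray(gradcam.overlay(hm, px[i])).save(
                gdir / f"{rec.patch_id}_overlay.png")
            outs += [f"gradcam_maps/{rec.patch_id}_heat.png",
                     f"gradcam_maps/{rec.patch_id}_overlay.png"]
        return outs

    def survival(self) -> list[str]:
        surv = pd.read_csv(self._p("cohort/survival.csv"))
        labels = pd.read_csv(self._p("labels.csv"), index_col=0)["label"]
        surv = surv[surv["patient_id"].isin(labels.index)].copy()
        surv["group"] = labels.loc[surv["patient_id"]].to_numpy()
        lr = survival.logrank(surv)
        cox_uni = survival.cox_fit(surv.assign(
            m2_high=(surv["group"] == "high").astype(float)), ["m2_high"])
        covs = ["m2_high" if c == "group" else c for c in self.cfg.survival_covariates]
        cox_multi = survival.cox_fit(surv.assign(
            m2_high=(surv["group"] == "high").astype(float)), covs)
        cox = pd.concat([cox_uni.assign(model="univariate"),
                         cox_multi.assign(model="multivariate")])
        cox.to_csv(self._p("cox.csv"))
        curves = survival.km_curve(surv)
        km_rows = [{"group": c.group, "time": t, "survival": s}
                   for c in curves.values() for t, s in zip(c.times, c.survival)]
        pd.DataFrame(km_rows).to_csv(self._p("km_curves.csv"), index=False)
        self._p("logrank.json").write_text(json.dumps(lr, indent=2, sort_keys=True))
        return ["cox.csv", "km_curves.csv", "logrank.json"]

    # -- driver ------------------------------------------------------------
    def run(self, stages=None) -> dict:
        requested = STAGES if stages is None else [s for s in STAGES if s in set(stages)]
        unknown = set(stages or []) - set(STAGES)
        if unknown:
            raise ConfigError([f"stages[{u}]" for u in sorted(unknown)])
        for stage in requested:
            self._require(stage)
            if self._up_to_date(stage):
                log.info("stage %s up to date; skipping", stage)
                continue
            log.info("running stage %s", stage)
            outputs = getattr(self, stage)()
            self._record(stage, outputs)
        self._save()
        return self.manifest


def run_pipeline(config: RunConfig, stages=None) -> dict:
    """Execute (a subset of) the pipeline; returns the run manifest."""
    return _Run(config).run(stages)
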