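"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes, with
three coupled forward models driven by one latent per-patient M2-macrophage
fraction:

* **Tiles** — near-white background, eosin-pink tissue regions, purple
  nuclei, and brown "macrophage" blobs whose expected count per unit tissue
  area grows linearly with the M2 level:
  ``base_density * (1 + visual_effect * m2_level)`` per 224x224 of tissue.
* **Bulk expression** — ``signature @ fractions`` plus truncated Gaussian
  noise, the forward model that SVR deconvolution inverts.
* **Survival** — exponential event times whose hazard is multiplied by
  ``exp(true_log_hr)`` in the high-M2 group, with uniform right-censoring
  calibrated to a requested censoring rate.

The latent M2 fraction is zero-inflated (a point mass at exactly 0) so the
cohort reproduces the exclusion pathway for patients without any M2
infiltration; the label boundary is the cohort mean fraction.

Every output is a pure function of (spec, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.optimize import brentq

log = logging.getLogger(__name__)

#: expected macrophage blobs per 224x224 of tissue at m2_level = 0
BASE_BLOB_DENSITY = 3.0
PATCH_AREA = 224 * 224

CELLTYPE_NAMES = ["M2", "M1", "CD8_T", "B_cell", "NK", "Monocyte", "Treg", "DC"]


@dataclass
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 86
    tiles_per_patient: int = 4
    tile_size: int = 1120          # 5x5 grid of 224px patches
    m2_mean: float = 0.25          # latent fraction distribution (truncated normal)
    m2_sd: float = 0.15
    zero_inflation_prob: float = 21 / 86   # point mass at exactly zero infiltration
    visual_effect: float = 5.0     # strength of the M2 -> blob-density link
    n_genes: int = 60
    n_celltypes: int = 5
    expression_noise_sd: float = 0.05
    true_log_hr: float = float(np.log(4.0))   # planted high-vs-low log hazard ratio
    baseline_hazard: float = 0.02  # events per month in the low-M2 group
    censor_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.tiles_per_patient < 1:
            raise ValueError("n_patients and tiles_per_patient must be positive")
        if self.tile_size < 224:
            raise ValueError("tile_size must be >= 224")
        if not (0 < self.m2_mean < 1) or self.m2_sd <= 0:
            raise ValueError("m2_mean must be in (0,1) and m2_sd > 0")
        if not (0 <= self.zero_inflation_prob < 1):
            raise ValueError("zero_inflation_prob must be in [0,1)")
        if self.visual_effect < 0 or self.expression_noise_sd < 0:
            raise ValueError("visual_effect and expression_noise_sd must be >= 0")
        if self.n_celltypes < 2:
            raise ValueError("n_celltypes must be >= 2 (one of them is M2)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must be in [0,1)")

    @property
    def celltype_names(self) -> list[str]:
        if self.n_celltypes <= len(CELLTYPE_NAMES):
            return CELLTYPE_NAMES[: self.n_celltypes]
        extra = [f"CT{i}" for i in range(len(CELLTYPE_NAMES), self.n_celltypes)]
        return CELLTYPE_NAMES + extra


def _fill_ellipse(mask: np.ndarray, cy: float, cx: float, a: float, b: float,
                  theta: float) -> None:
    h, w = mask.shape
    r = max(a, b)
    y0, y1 = max(0, int(cy - r)), min(h, int(cy + r) + 1)
    x0, x1 = max(0, int(cx - r)), min(w, int(cx + r) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    mask[y0:y1, x0:x1] |= (u * u + v * v) <= 1.0


def _draw_disk(img: np.ndarray, cy: int, cx: int, r: int,
               color: tuple[int, int, int], jitter: int,
               rng: np.random.Generator, region: np.ndarray | None = None) -> None:
    h, w = img.shape[:2]
    y0, y1 = max(0, cy - r), min(h, cy + r + 1)
    x0, x1 = max(0, cx - r), min(w, cx + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    if region is not None:  # cells stay inside the tissue region
        m &= region[y0:y1, x0:x1]
    n = int(m.sum())
    if n == 0:
        return
    jit = rng.integers(-jitter, jitter + 1, size=(n, 3))
    img[y0:y1, x0:x1][m] = np.clip(np.array(color) + jit, 0, 255).astype(np.uint8)


def render_tile(m2_level: float, visual_effect: float, tile_size: int = 1120,
                seed: int = 0, *, base_density: float = BASE_BLOB_DENSITY,
                tissue_coverage: float = 0.55, return_mask: bool = False):
    """Render one synthetic H&E-like tile.

    Brown macrophage-like blobs are planted with expected count
    ``base_density * (1 + visual_effect * m2_level)`` per 224x224 of drawn
    tissue.  Deterministic given the seed.
    """
    if tile_size < 224:
        raise ValueError("tile_size must be >= 224")
    if not (0 <= m2_level <= 1):
        raise ValueError("m2_level must be in [0,1]")
    rng = np.random.default_rng(seed)
    img = np.full((tile_size, tile_size, 3), 255, dtype=np.uint8)
    mask = np.zeros((tile_size, tile_size), dtype=bool)
    if tissue_coverage > 0:
        for _ in range(300):
            if mask.mean() >= tissue_coverage:
                break
            cy, cx = rng.uniform(0, tile_size, 2)
            a = rng.uniform(tile_size / 8, tile_size / 3)
            b = rng.uniform(tile_size / 8, tile_size / 3)
            _fill_ellipse(mask, cy, cx, a, b, rng.uniform(0, np.pi))
    tissue_px = int(mask.sum())
    if tissue_px > 0:
        jit = rng.integers(-10, 11, size=(tissue_px, 3))
        img[mask] = np.clip(np.array([231, 168, 188]) + jit, 0, 255).astype(np.uint8)
        idx = np.flatnonzero(mask)
        area_units = tissue_px / PATCH_AREA
        # hematoxylin-stained nuclei
        n_nuclei = rng.poisson(25.0 * area_units)
        for pos in rng.choice(idx, size=n_nuclei, replace=True):
            _draw_disk(img, pos // tile_size, pos % tile_size,
                       int(rng.integers(2, 5)), (128, 70, 148), 12, rng, region=mask)
        # brown macrophage-like blobs carry the planted class signal
        lam = base_density * (1.0 + visual_effect * m2_level) * area_units
        n_blobs = rng.poisson(lam)
        for pos in rng.choice(idx, size=n_blobs, replace=True):
            _draw_disk(img, pos // tile_size, pos % tile_size,
                       int(rng.integers(3, 6)), (115, 78, 42), 7, rng, region=mask)
    if return_mask:
        return img, mask
    return img


def make_signature(n_genes: int, n_celltypes: int, seed: int = 0,
                   celltype_names: list[str] | None = None) -> pd.DataFrame:
    """Gene x cell-type reference profiles with distinct marker blocks."""
    rng = np.random.default_rng(seed)
    names = celltype_names or (CELLTYPE_NAMES[:n_celltypes]
                               + [f"CT{i}" for i in range(len(CELLTYPE_NAMES), n_celltypes)])
    base = rng.lognormal(mean=0.0, sigma=0.4, size=(n_genes, n_celltypes))
    block = max(1, n_genes // n_celltypes)
    for j in range(n_celltypes):
        lo = j * block
        hi = n_genes if j == n_celltypes - 1 else (j + 1) * block
        base[lo:hi, j] *= 8.0  # marker genes for cell type j
    return pd.DataFrame(base, index=[f"G{i:04d}" for i in range(n_genes)],
                        columns=names[:n_celltypes])


def synthesize_expression(fractions: np.ndarray, signature: pd.DataFrame | np.ndarray,
                          noise_sd: float, seed: int = 0) -> np.ndarray:
    """Forward mixture model: signature @ fractions + truncated Gaussian noise.

    Noise is scaled by the mean magnitude of the clean mixture column so
    ``noise_sd`` is a relative noise level.
    """
    sig = signature.to_numpy() if isinstance(signature, pd.DataFrame) else np.asarray(signature)
    f = np.asarray(fractions, dtype=float)
    if sig.shape[1] != f.shape[0]:
        raise ValueError(f"signature has {sig.shape[1]} cell types, fractions {f.shape[0]}")
    if (f < 0).any() or not np.isclose(f.sum(), 1.0, atol=1e-8):
        raise ValueError("fractions must be non-negative and sum to 1")
    clean = sig @ f
    if noise_sd == 0:
        return clean
    rng = np.random.default_rng(seed)
    sd = noise_sd * float(np.abs(clean).mean())
    return np.clip(clean + rng.normal(0.0, sd, size=clean.shape), 0.0, None)


def _censor_horizon(rates: np.ndarray, censor_rate: float) -> float:
    """Upper bound of the Uniform(0, c) censoring law giving the requested
    overall censoring probability for exponential event times."""

    def frac_censored(c):
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc)) - censor_rate

    return brentq(frac_censored, 1e-9, 1e9, xtol=1e-10, rtol=1e-12)


def simulate_survival(labels, true_log_hr: float, baseline_hazard: float,
                      censor_rate: float, seed: int = 0) -> pd.DataFrame:
    """Exponential survival with a planted high-vs-low hazard ratio.

    Returns a data frame with columns time_months, event, group.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be > 0")
    rng = np.random.default_rng(seed)
    is_high = np.array([lab == "high" for lab in labels])
    rates = baseline_hazard * np.exp(true_log_hr * is_high.astype(float))
    t_event = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        c_max = _censor_horizon(rates, censor_rate)
        t_cens = rng.uniform(0.0, c_max, size=len(labels))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    else:
        time, event = t_event, np.ones(len(labels), dtype=int)
    return pd.DataFrame({"time_months": time, "event": event, "group": labels})


def _sample_m2_fractions(spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    out = np.empty(spec.n_patients)
    for i in range(spec.n_patients):
        if rng.uniform() < spec.zero_inflation_prob:
            out[i] = 0.0
        else:
            x = rng.normal(spec.m2_mean, spec.m2_sd)
            while not (0 < x <= 1):
                x = rng.normal(spec.m2_mean, spec.m2_sd)
            out[i] = x
    return out


def generate_cohort(spec: SyntheticCohortSpec, out_dir: str | Path) -> dict:
    """Write tiles, ground truth, expression, survival and a manifest.

    Returns the manifest dict (also written as JSON).
    """
    out = Path(out_dir)
    tiles_dir = out / "tiles"
    try:
        tiles_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # unwritable output directory
        raise OSError(f"cannot create output directory {out}: {exc}") from exc

    ss = np.random.SeedSequence(spec.seed)
    s_frac, s_tiles, s_expr, s_surv, s_cov = [s.generate_state(1)[0] % 2**31
                                              for s in ss.spawn(5)]
    patient_ids = [f"P{i:03d}" for i in range(spec.n_patients)]

    fractions = _sample_m2_fractions(spec, np.random.default_rng(s_frac))
    boundary = float(fractions.mean())
    labels = ["high" if f > boundary else "low" for f in fractions]

    # full per-patient composition: remaining mass split over other cell types
    rng_comp = np.random.default_rng(s_frac + 1)
    names = spec.celltype_names
    comp = np.zeros((spec.n_patients, spec.n_celltypes))
    comp[:, 0] = fractions
    other = rng_comp.dirichlet(np.full(spec.n_celltypes - 1, 2.0), size=spec.n_patients)
    comp[:, 1:] = other * (1.0 - fractions)[:, None]

    signature = make_signature(spec.n_genes, spec.n_celltypes, seed=spec.seed,
                               celltype_names=names)
    expr = np.column_stack([
        synthesize_expression(comp[i], signature, spec.expression_noise_sd,
                              seed=int(s_expr + i))
        for i in range(spec.n_patients)
    ])
    expr_df = pd.DataFrame(expr, index=signature.index, columns=patient_ids)

    tile_files: dict[str, list[str]] = {}
    for i, pid in enumerate(patient_ids):
        tile_files[pid] = []
        for j in range(spec.tiles_per_patient):
            img = render_tile(fractions[i], spec.visual_effect, spec.tile_size,
                              seed=int(s_tiles + i * 1000 + j))
            fname = f"{pid}_t{j}.png"
            Image.fromarray(img).save(tiles_dir / fname)
            tile_files[pid].append(f"tiles/{fname}")

    surv = simulate_survival(labels, spec.true_log_hr, spec.baseline_hazard,
                             spec.censor_rate, seed=s_surv)
    rng_cov = np.random.default_rng(s_cov)
    surv.insert(0, "patient_id", patient_ids)
    surv["age"] = np.clip(rng_cov.normal(61, 9, spec.n_patients).round(1), 30, 90)
    surv["stage"] = rng_cov.choice(["II", "III", "IV"], size=spec.n_patients,
                                   p=[0.15, 0.6, 0.25])

    truth = pd.DataFrame({
        "patient_id": patient_ids,
        "true_m2_fraction": fractions,
        "true_label": labels,
        "blob_density": BASE_BLOB_DENSITY * (1.0 + spec.visual_effect * fractions),
        "true_survival_time": surv["time_months"],
        "true_event": surv["event"],
    })

    truth.to_csv(out / "ground_truth.csv", index=False)
    expr_df.to_csv(out / "expression.tsv", sep="\t")
    signature.to_csv(out / "signature.tsv", sep="\t")
    surv.to_csv(out / "survival.csv", index=False)

    manifest = {
        "spec": dataclasses.asdict(spec),
        "boundary_true_m2_mean": boundary,
        "n_zero_m2": int((fractions == 0).sum()),
        "patients": patient_ids,
        "files": {
            "ground_truth": "ground_truth.csv",
            "expression": "expression.tsv",
            "signature": "signature.tsv",
            "survival": "survival.csv",
            "tiles": tile_files,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("cohort: %d patients (%d zero-M2), %d tiles", spec.n_patients,
             manifest["n_zero_m2"], spec.n_patients * spec.tiles_per_patient)
    return manifest
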