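"""Immune-cell deconvolution of bulk expression by linear nu-SVR.

A simplified CIBERSORT-style core: the mixture and the signature matrix are
globally z-scored, a linear nu-support-vector regression of the mixture on
the signature columns is fitted for each nu in a small grid, the fit whose
reconstruction best correlates (Pearson) with the mixture is kept, and its
coefficients are clamped at zero and renormalized to sum to one.  The
permutation p-value and quantile-normalization steps of the published tool
are deliberately omitted: only point estimates of the fractions are
consumed downstream.

Labeling arm: samples with zero M2 fraction are excluded, and the
remainder are dichotomized at the cohort mean M2 fraction (strictly above
the mean = "high"; ties at the boundary = "low").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.svm import NuSVR

log = logging.getLogger(__name__)

DEFAULT_NU_GRID = (0.25, 0.5, 0.75)


class DegenerateInputError(ValueError):
    """Raised for inputs the deconvolution cannot act on (e.g. all-zero mixture)."""


@dataclass
class M2Labels:
    """High/low infiltration labels with the mean-fraction boundary used."""

    labels: pd.Series  # sample_id -> "high" | "low"
    boundary: float


def _align(mixture, signature):
    if isinstance(signature, pd.DataFrame) and isinstance(mixture, pd.Series):
        common = signature.index.intersection(mixture.index)
        if len(common) < 2:
            raise ValueError(f"only {len(common)} overlapping genes between "
                             "mixture and signature")
        dropped = len(signature.index) - len(common)
        if dropped:
            log.info("gene alignment: %d signature genes dropped, %d used",
                     dropped, len(common))
        return mixture.loc[common].to_numpy(float), signature.loc[common].to_numpy(float)
    y = np.asarray(mixture, dtype=float)
    x = np.asarray(signature, dtype=float)
    if x.shape[0] != y.shape[0]:
        raise ValueError(f"mixture has {y.shape[0]} genes, signature {x.shape[0]}")
    return y, x


def estimate_fractions(mixture, signature, nu_grid=DEFAULT_NU_GRID) -> np.ndarray:
    """Estimate non-negative, sum-to-one cell-type fractions for one sample.

    Parameters
    ----------
    mixture : (n_genes,) array or pd.Series indexed by gene id
    signature : (n_genes, n_celltypes) array or pd.DataFrame
    nu_grid : nu values tried; the fit maximizing the Pearson correlation
        between reconstruction and mixture is selected.
    """
    y, x = _align(mixture, signature)
    if (y < 0).any():
        raise ValueError("mixture must be non-negative")
    if np.all(y == 0):
        raise DegenerateInputError("all-zero mixture")
    # global z-scoring makes the result invariant to the mixture's scale
    ys = (y - y.mean()) / y.std()
    xs = (x - x.mean()) / x.std()
    best = None
    for nu in nu_grid:
        svr = NuSVR(kernel="linear", nu=nu, C=10.0, tol=1e-4)
        svr.fit(xs, ys)
        recon = svr.predict(xs)
        if np.std(recon) == 0:
            corr = -np.inf
        else:
            corr = pearsonr(recon, ys)[0]
        if best is None or corr > best[0]:
            best = (corr, svr.coef_.ravel().copy())
    coef = np.clip(best[1], 0.0, None)
    total = coef.sum()
    if total == 0:
        warnings.warn("all SVR coefficients non-positive; returning uniform fractions")
        return np.full(x.shape[1], 1.0 / x.shape[1])
    return coef / total


def estimate_fraction_table(expression: pd.DataFrame, signature: pd.DataFrame,
                            nu_grid=DEFAULT_NU_GRID) -> pd.DataFrame:
    """Deconvolve every column (sample) of a gene x sample expression matrix.

    Returns a sample x cell-type fraction table (rows sum to 1).
    """
    rows = {}
    for sample in expression.columns:
        rows[sample] = estimate_fractions(expression[sample], signature, nu_grid)
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(signature.columns))


def exclude_zero_m2(fractions: pd.DataFrame, celltype: str = "M2") -> pd.DataFrame:
    """Drop samples without any M2 infiltration (fraction == 0)."""
    if celltype not in fractions.columns:
        raise ValueError(f"no {celltype!r} column in fraction table")
    kept = fractions[fractions[celltype] > 0]
    log.info("zero-%s exclusion: kept %d/%d samples", celltype, len(kept), len(fractions))
    if kept.empty:
        warnings.warn(f"every sample has zero {celltype} fraction; nothing retained")
    return kept


def dichotomize_by_mean(fractions: pd.DataFrame, celltype: str = "M2") -> M2Labels:
    """Split samples at the cohort-mean fraction of the named cell type.

    Strictly above the mean -> "high"; at or below (including boundary
    ties) -> "low".
    """
    if len(fractions) < 2:
        raise ValueError("need at least 2 samples to dichotomize")
    values = fractions[celltype]
    boundary = float(values.mean())
    labels = pd.Series(np.where(values > boundary, "high", "low"),
                       index=fractions.index, name="label")
    return M2Labels(labels=labels, boundary=boundary)
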