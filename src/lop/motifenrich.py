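"""Semiparametric logistic enrichment of motif counts in a target gene set.

For each motif the model is

    logit P(y = 1) = b0 + b1 * x1 + s(x2)

where y indicates membership in the target set among expressed genes, x1 is
the motif count in the upstream region, and s(x2) is a natural-cubic-spline
expansion of the scanned (unmasked) sequence length.  The length term
absorbs the confounding between promoter mappability and set membership, so
b1 measures enrichment per additional motif occurrence at fixed scanned
length.  Significance is the Wald Z for b1; BH adjustment runs across the
estimable motifs of a dictionary screen.

The fit is iteratively reweighted least squares with a small ridge for
numerical stability; a fixed-df spline basis (knots at quantiles of x2)
keeps the procedure deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .setcompare import GeneSet

log = logging.getLogger(__name__)

__all__ = ["MotifEnrichmentResult", "natural_cubic_basis", "fit_motif_model",
           "screen_dictionary"]


@dataclass(frozen=True)
class MotifEnrichmentResult:
    motif: str
    beta1: float
    se: float
    z: float
    p: float
    direction: int
    spline_df: int
    n_genes: int
    estimable: bool = True
    separation: bool = False
    q: float = np.nan


def natural_cubic_basis(x: np.ndarray, df: int = 4) -> np.ndarray:
    """Natural cubic spline basis (linear beyond the boundary knots) with
    knots at quantiles of x; returns up to ``df`` columns excluding the
    intercept.  Degenerate x (too few distinct values) yields fewer columns;
    a constant x yields none."""
    x = np.asarray(x, dtype=float)
    knots = np.unique(np.quantile(np.unique(x), np.linspace(0, 1, df + 1)))
    if len(knots) < 2:
        return np.empty((len(x), 0))
    cols = [x]
    K = len(knots)
    if K >= 3:
        def d(k):
            return (np.clip(x - knots[k], 0, None) ** 3
                    - np.clip(x - knots[K - 1], 0, None) ** 3) / (knots[K - 1] - knots[k])
        dK2 = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dK2)
    return np.column_stack(cols)


def _irls_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 1e-8,
                   tol: float = 1e-8, max_iter: int = 100):
    """Ridge-stabilized IRLS for logistic regression.

    Returns (beta, cov, converged, separation); cov is the inverse penalized
    Fisher information.
    """
    n, k = X.shape
    beta = np.zeros(k)
    dev_old = np.inf
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + ridge * np.eye(k)
        beta = np.linalg.solve(H, XtW @ z)
        with np.errstate(divide="ignore"):
            dev = -2.0 * np.sum(y * np.log(np.clip(mu, 1e-300, None))
                                + (1 - y) * np.log(np.clip(1 - mu, 1e-300, None)))
        if abs(dev - dev_old) < tol * (abs(dev) + 0.1):
            converged = True
            break
        dev_old = dev
    eta = X @ beta
    separation = bool(np.abs(eta).max() > 30.0)
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    H = (X.T * w) @ X + ridge * np.eye(k)
    cov = np.linalg.inv(H)
    return beta, cov, converged, separation


def fit_motif_model(y, x1, x2, motif: str = "motif", spline_df: int = 4,
                    ridge: float = 1e-8, min_per_class: int = 20) -> MotifEnrichmentResult:
    """Fit the length-adjusted logistic enrichment model for one motif.

    ``y`` is 0/1 target-set membership over expressed genes, ``x1`` the motif
    count, ``x2`` the scanned length.  A constant ``x1`` is inestimable and
    flagged (excluded from any BH family); complete separation is flagged and
    the penalized-fit p is reported with a warning.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    n1 = int(y.sum())
    if n1 == 0 or n1 == len(y):
        raise ValueError("y must contain both classes")
    if min(n1, len(y) - n1) < min_per_class:
        raise ValueError(f"need >= {min_per_class} genes per class")
    if np.ptp(x1) == 0.0:
        log.warning("motif %s: count covariate is constant; coefficient inestimable", motif)
        return MotifEnrichmentResult(motif, np.nan, np.nan, np.nan, np.nan, 0,
                                     spline_df, len(y), estimable=False)
    spline = natural_cubic_basis(x2, df=spline_df)
    X = np.column_stack([np.ones(len(y)), x1, spline])
    # standardize spline columns for conditioning; b1 itself is untouched
    if spline.shape[1]:
        scale = X[:, 2:].std(axis=0)
        scale[scale == 0] = 1.0
        X[:, 2:] /= scale
    beta, cov, converged, separation = _irls_logistic(X, y, ridge=ridge)
    if not converged and not separation:
        log.warning("motif %s: IRLS did not converge", motif)
    if separation:
        log.warning("motif %s: quasi-complete separation; penalized-fit p reported", motif)
    b1 = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = b1 / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MotifEnrichmentResult(motif, b1, se, z, p, int(np.sign(b1)),
                                 spline_df, len(y), separation=separation)


def screen_dictionary(counts: pd.DataFrame, target: GeneSet, background: GeneSet | set,
                      alpha: float = 0.05, spline_df: int = 4,
                      ridge: float = 1e-8) -> pd.DataFrame:
    """One length-adjusted model per motif over expressed genes
    (target union background), BH-adjusted across estimable motifs.

    ``counts`` is the long-format (gene, motif, count, scanned_length) table.
    Returns a frame sorted by p with columns motif, beta1, se, z, p, q,
    direction, n_genes, estimable, separation.
    """
    bg_genes = background.genes if isinstance(background, GeneSet) else frozenset(background)
    expressed = set(target.genes) | set(bg_genes)
    sub = counts[counts["gene"].isin(expressed)]
    if sub.empty:
        raise ValueError("no expressed genes found in the count table")
    results = []
    for m, grp in sub.groupby("motif", sort=True):
        y = grp["gene"].isin(target.genes).to_numpy(float)
        try:
            r = fit_motif_model(y, grp["count"].to_numpy(), grp["scanned_length"].to_numpy(),
                                motif=str(m), spline_df=spline_df, ridge=ridge)
        except ValueError as exc:
            raise ValueError(f"motif {m}: {exc}") from exc
        results.append(r)
    if not any(r.estimable for r in results):
        raise ValueError("no estimable motif in the dictionary")
    frame = pd.DataFrame([r.__dict__ for r in results])
    est = frame["estimable"]
    frame.loc[est, "q"] = bh_adjust(frame.loc[est, "p"].to_numpy())
    frame = frame.sort_values(["p", "motif"], na_position="last").reset_index(drop=True)
    frame.attrs["alpha"] = alpha
    for sign, name in ((1, "top_increased"), (-1, "top_decreased")):
        side = frame[est & (frame["direction"] == sign)]
        frame.attrs[name] = str(side.iloc[0]["motif"]) if len(side) else None
    return frame
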