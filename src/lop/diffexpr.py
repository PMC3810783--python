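"""Differential expression on a summarized log2 matrix.

The workflow mirrors the classic two-colour-era array analysis: a detection
filter drops probes never expressed above a background floor, an
empirical-Bayes moderated t-statistic shrinks per-probe variances toward a
prior estimated by moment-matching the scaled-F distribution of sample
variances, Benjamini-Hochberg controls the FDR across all retained probes,
sibling probe sets targeting the same gene are collapsed to the
lowest-p probe, and genes are classified by joint FDR and linear
fold-change thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy", "detection_filter", "moderated_t", "bh_adjust",
    "collapse_probes", "classify", "gene_sets", "fit_f_dist",
]


@dataclass
class ExpressionStudy:
    """Probes x samples log2 matrix plus probe->gene map and group design."""

    matrix: pd.DataFrame
    probe_to_gene: Mapping[str, str]
    design: Mapping[str, str]

    def __post_init__(self):
        missing = [s for s in self.matrix.columns if s not in self.design]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.matrix.columns if self.design[s] == group]


def detection_filter(study: ExpressionStudy, floor: float, min_samples: int = 1) -> pd.Index:
    """Probes retained iff expression > floor in at least ``min_samples`` samples."""
    if not np.isfinite(floor) and floor > 0:
        raise ValueError("floor must be finite or -inf")
    above = (study.matrix.to_numpy() > floor).sum(axis=1)
    keep = study.matrix.index[above >= min_samples]
    log.info("detection filter: %d of %d probes retained", len(keep), len(study.matrix))
    return keep


def _trigamma_inverse(y: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(max_iter):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < tol * x:
            break
    return float(x)


def fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F distribution to sample variances.

    Under the hierarchical model the s2 are distributed as s0^2 * F(df, d0);
    matching the mean and variance of log(s2) gives closed-form estimates of
    the prior df d0 and prior variance s0^2 (d0 = inf when the log-variances
    are under-dispersed relative to pure chi-square noise).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if (~ok).any():
        log.warning("fit_f_dist: dropping %d zero/negative variances", int((~ok).sum()))
        s2 = s2[ok]
    if s2.size < 2:
        raise ValueError("need at least two positive variances to fit the prior")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        d0, s02 = np.inf, np.exp(emean)
    return float(d0), float(s02)


def moderated_t(study: ExpressionStudy, group_a: str, group_b: str,
                prior_df: float | None = None) -> pd.DataFrame:
    """Per-probe moderated t-test of group_a vs group_b.

    log2fc = mean_a - mean_b.  The posterior variance is
    (d0*s0^2 + d*s^2) / (d0 + d) and the statistic is referred to a t
    distribution on d0 + d degrees of freedom.  ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary t; inf pools one common variance).
    """
    a = study.matrix[study.samples_in(group_a)].to_numpy(float)
    b = study.matrix[study.samples_in(group_b)].to_numpy(float)
    na, nb = a.shape[1], b.shape[1]
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 samples per group")
    df_resid = na + nb - 2
    if df_resid <= 0:
        raise ValueError("zero residual degrees of freedom")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + ((b - mean_b[:, None]) ** 2).sum(axis=1)
    s2 = ss / df_resid
    lfc = mean_a - mean_b

    d0, s02 = fit_f_dist(s2, df_resid)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    c = np.sqrt(1.0 / na + 1.0 / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = lfc / (np.sqrt(s2_post) * c)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame(
        {"log2fc": lfc, "t_mod": t, "p": p, "s2": s2, "s2_post": s2_post},
        index=study.matrix.index,
    ).assign(df_prior=d0, df_total=df_total, s02_prior=s02)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def collapse_probes(results: pd.DataFrame, probe_to_gene: Mapping[str, str]) -> pd.DataFrame:
    """One record per gene: the minimum-p probe, ties broken by larger
    |log2fc| then lexicographic probe id.  Unmapped probes are logged and
    dropped."""
    df = results.copy()
    df["gene"] = [probe_to_gene.get(pr) for pr in df.index]
    unmapped = df["gene"].isna()
    if unmapped.any():
        log.warning("collapse_probes: dropping %d unmapped probes", int(unmapped.sum()))
        df = df[~unmapped]
    df = df.rename_axis("probe").reset_index()
    df["_neg_abs_lfc"] = -df["log2fc"].abs()
    df = df.sort_values(["p", "_neg_abs_lfc", "probe"], kind="mergesort")
    out = df.groupby("gene", sort=True).first().drop(columns="_neg_abs_lfc")
    return out.rename(columns={"probe": "chosen_probe"})


def classify(gene_results: pd.DataFrame, fdr: float = 0.05,
             up: float = 1.50, down: float = 0.67) -> pd.DataFrame:
    """Partition genes into increased / decreased / unchanged by BH q and
    linear fold change (2**log2fc)."""
    if not (0 < down < 1 < up):
        raise ValueError("fold-change thresholds must satisfy down < 1 < up")
    if "q" not in gene_results.columns:
        raise ValueError("gene_results must carry a BH-adjusted 'q' column")
    out = gene_results.copy()
    out["fold_change"] = 2.0 ** out["log2fc"]
    cls = np.where(
        (out["q"] < fdr) & (out["fold_change"] > up), "increased",
        np.where((out["q"] < fdr) & (out["fold_change"] < down), "decreased", "unchanged"),
    )
    out["class"] = cls
    # genes significant at the FDR cut regardless of fold change: the set
    # excluded from enrichment backgrounds as "differentially expressed"
    out["significant"] = out["q"] < fdr
    return out


def gene_sets(classified: pd.DataFrame) -> tuple[set[str], set[str]]:
    """The (increased, decreased) gene sets from a classified table."""
    inc = set(classified.index[classified["class"] == "increased"])
    dec = set(classified.index[classified["class"] == "decreased"])
    return inc, dec
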