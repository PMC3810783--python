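"""Closed-form phenotype calculators.

HOMA-IR insulin-resistance index, respiratory quotient, delta-delta-Ct qPCR
fold induction, and percent-of-baseline tolerance curves.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["homa_ir", "rq", "pct_baseline", "fold_induction"]


def homa_ir(glucose_mg_dl, insulin_uU_ml):
    """Homeostasis-model insulin-resistance index:
    glucose (mg/dl) x insulin (uU/ml) / 405."""
    g = np.asarray(glucose_mg_dl, dtype=float)
    i = np.asarray(insulin_uU_ml, dtype=float)
    if (g < 0).any() or (i < 0).any():
        raise ValueError("glucose and insulin must be nonnegative")
    out = g * i / 405.0
    return float(out) if out.ndim == 0 else out


def rq(vco2, vo2):
    """Respiratory quotient VCO2/VO2 (lower values index fat oxidation)."""
    vco2 = np.asarray(vco2, dtype=float)
    vo2 = np.asarray(vo2, dtype=float)
    if (vo2 <= 0).any():
        raise ValueError("VO2 must be positive")
    out = vco2 / vo2
    return float(out) if out.ndim == 0 else out


def pct_baseline(glucose_curve):
    """Tolerance-test readings as a percentage of the t=0 baseline."""
    g = np.asarray(glucose_curve, dtype=float)
    if g.size == 0:
        raise ValueError("empty glucose curve")
    if g[0] <= 0:
        raise ValueError("baseline glucose must be positive")
    return 100.0 * g / g[0]


def fold_induction(ct: pd.DataFrame, reference_gene: str = "Gapdh",
                   treated: str = "treated", control: str = "control") -> pd.Series:
    """Relative expression by the delta-delta-Ct method.

    Replicate Ct values are averaged per (sample, gene); per sample,
    dCt = Ct_gene - Ct_reference; ddCt is the difference of condition means
    and fold induction is 2**(-ddCt), so lower treated Ct (more transcript)
    gives fold > 1.
    """
    required = {"sample", "gene", "condition", "ct"}
    if not required <= set(ct.columns):
        raise ValueError(f"Ct table must have columns {sorted(required)}")
    mean_ct = ct.groupby(["condition", "sample", "gene"])["ct"].mean()
    folds = {}
    per_cond_dct = {}
    for cond in (treated, control):
        if cond not in mean_ct.index.get_level_values(0):
            raise ValueError(f"condition {cond!r} absent from the Ct table")
        sub = mean_ct.loc[cond].unstack("gene")
        if reference_gene not in sub.columns or sub[reference_gene].isna().any():
            raise ValueError(f"reference gene {reference_gene!r} missing in some "
                             f"{cond} samples")
        per_cond_dct[cond] = sub.sub(sub[reference_gene], axis=0).mean(axis=0)
    ddct = per_cond_dct[treated] - per_cond_dct[control]
    folds = 2.0 ** (-ddct)
    folds.name = "fold_induction"
    return folds
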