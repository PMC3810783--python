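"""Cross-experiment concordance of gene sets with ranked fold-change lists.

One study's increased/decreased gene sets are tested for systematic rank
bias within another experiment's fold-change ordering using the Wilcoxon
rank-sum test (exact for small groups without ties, normal approximation
with tie correction otherwise).  A screen over a battery of experiments
tallies how many are significant with the set's expected sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSet", "RankedList", "RankEnrichmentResult", "make_ranked_list",
    "rank_enrichment", "concordance_screen", "overlap_counts", "OverlapResult",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    direction: int = 0  # +1 increased set, -1 decreased set, 0 undirected

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))


@dataclass(frozen=True)
class RankedList:
    """Genes ranked 1..n by descending score; score ties broken by gene id."""

    experiment_id: str
    frame: pd.DataFrame  # columns gene, score, rank

    @property
    def genes(self) -> set:
        return set(self.frame["gene"])


def make_ranked_list(df: pd.DataFrame, experiment_id: str | None = None) -> RankedList:
    if df["gene"].duplicated().any():
        raise ValueError("genes in a ranked list must be unique")
    out = df[["gene", "score"]].sort_values(
        ["score", "gene"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return RankedList(
        experiment_id=experiment_id or df.attrs.get("experiment_id", "expt"),
        frame=out,
    )


@dataclass(frozen=True)
class RankEnrichmentResult:
    experiment_id: str
    set_name: str
    statistic: float       # standardized rank-sum Z; >0 = set biased to high scores
    p: float
    n_set_in_list: int
    evaluable: bool = True
    alternative: str = "two-sided"


def _not_evaluable(exp_id, set_name, n) -> RankEnrichmentResult:
    return RankEnrichmentResult(exp_id, set_name, statistic=np.nan, p=np.nan,
                                n_set_in_list=n, evaluable=False)


def rank_enrichment(gene_set: GeneSet, ranked: RankedList,
                    alternative: str = "two-sided") -> RankEnrichmentResult:
    """Wilcoxon rank-sum comparison of set-member vs non-member scores.

    Exact enumeration when min group size <= 10 and the scores are tie-free;
    otherwise the normal approximation with tie correction.  The statistic is
    positive when members sit at higher scores; for one-sided alternatives,
    'greater' means the set is biased toward high scores.
    """
    frame = ranked.frame
    member = frame["gene"].isin(gene_set.genes).to_numpy()
    n1 = int(member.sum())
    n2 = int((~member).sum())
    if n1 == 0 or n2 == 0:
        return _not_evaluable(ranked.experiment_id, gene_set.name, n1)
    x = frame.loc[member, "score"].to_numpy(float)
    y = frame.loc[~member, "score"].to_numpy(float)
    has_ties = len(np.unique(frame["score"].to_numpy())) < len(frame)
    method = "exact" if (min(n1, n2) <= 10 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method,
                             use_continuity=(method == "asymptotic"))
    # standardized Z with tie correction, sign-positive toward high member scores
    u1 = float(res.statistic)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, counts = np.unique(frame["score"].to_numpy(), return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1.0)) if n > 1 else 0.0
    sigma2 = n1 * n2 / 12.0 * (n + 1.0 - tie_term)
    z = (u1 - mu) / np.sqrt(sigma2) if sigma2 > 0 else 0.0
    return RankEnrichmentResult(ranked.experiment_id, gene_set.name,
                                statistic=float(z), p=float(res.pvalue),
                                n_set_in_list=n1, alternative=alternative)


def concordance_screen(sets: Sequence[GeneSet], experiments: Sequence[RankedList],
                       alpha: float = 0.05):
    """All set x experiment rank-enrichment results plus a per-set tally of
    experiments significant (p < alpha) with the set's stated direction."""
    if not experiments:
        raise ValueError("need at least one experiment")
    rows = []
    results = {}
    for gs in sets:
        for exp in experiments:
            r = rank_enrichment(gs, exp)
            results[(gs.name, exp.experiment_id)] = r
            rows.append((gs.name, exp.experiment_id, r.statistic, r.p,
                         r.n_set_in_list, r.evaluable))
    frame = pd.DataFrame(rows, columns=["set", "experiment", "statistic", "p",
                                        "n_set_in_list", "evaluable"])
    tally = {}
    for gs in sets:
        sub = frame[(frame["set"] == gs.name) & frame["evaluable"]]
        hits = ((sub["p"] < alpha) &
                (np.sign(sub["statistic"]) == gs.direction)).sum() if gs.direction else \
               (sub["p"] < alpha).sum()
        tally[gs.name] = (int(hits), len(sub))
    return frame, tally


@dataclass(frozen=True)
class OverlapResult:
    regions: dict          # frozenset of set names -> count exclusive to that region
    pairwise_p: dict       # (name_a, name_b) -> hypergeometric overlap tail p
    universe_size: int
    set_sizes: dict = field(default_factory=dict)


def overlap_counts(sets: Sequence[GeneSet], universe: Iterable[str]) -> OverlapResult:
    """Cardinalities of all 2^k - 1 exclusive regions of a Venn partition and
    pairwise hypergeometric overlap p-values against the stated universe."""
    universe = set(universe)
    for gs in sets:
        outside = gs.genes - universe
        if outside:
            raise ValueError(f"set {gs.name!r} has {len(outside)} genes outside the universe")
    names = [gs.name for gs in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    by_name = {gs.name: gs.genes for gs in sets}
    regions = {}
    for r in range(1, len(names) + 1):
        for inside in combinations(names, r):
            genes = set(universe)
            for nm in inside:
                genes &= by_name[nm]
            for nm in names:
                if nm not in inside:
                    genes -= by_name[nm]
            regions[frozenset(inside)] = len(genes)
    pairwise = {}
    N = len(universe)
    for a, b in combinations(names, 2):
        k = len(by_name[a] & by_name[b])
        pairwise[(a, b)] = float(stats.hypergeom.sf(k - 1, N, len(by_name[a]), len(by_name[b])))
    return OverlapResult(regions=regions, pairwise_p=pairwise, universe_size=N,
                         set_sizes={nm: len(by_name[nm]) for nm in names})
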