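"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate the study design the downstream statistics were built
for: two-genotype x two-diet mouse survival cohorts with Gompertz mortality,
a small (3 vs 3) liver microarray study with sibling probe sets and planted
fold changes, 2 kb promoter regions with masked blocks and planted motif
instances, a toy ontology DAG with true-path annotations, ranked external
fold-change lists with a controllable concordance knob, and qPCR Ct plates.

Every generator is deterministic given its spec's seed, and each returns a
truth table sufficient to score the downstream stage that consumes it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GroupSpec", "CohortSpec", "ExpressionSpec", "PromoterSpec", "QpcrSpec",
    "gen_survival_cohort", "gen_expression_study", "gen_promoter_set",
    "gen_toy_ontology", "gen_qpcr_plate", "gen_ranked_experiment",
    "gen_cr_battery", "gompertz_rate_for_median", "mirror_cohort_spec",
    "mirror_expression_spec",
]


# ---------------------------------------------------------------------------
# survival cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One survival group under Gompertz mortality h(t) = rate * exp(shape*t).

    ``shape`` is per day (0 gives the exponential limit), ``rate`` per day.
    ``censor_fraction`` of animals are right-censored at an independent
    uniform fraction of their death time (non-informative censoring).
    """

    label: str
    n_animals: int
    gompertz_shape: float
    gompertz_rate: float
    censor_fraction: float = 0.0

    def __post_init__(self):
        if self.n_animals < 1:
            raise ValueError(f"group {self.label!r}: n_animals must be >= 1")
        if self.gompertz_rate <= 0:
            raise ValueError(f"group {self.label!r}: gompertz_rate must be > 0")
        if self.gompertz_shape < 0:
            raise ValueError(f"group {self.label!r}: gompertz_shape must be >= 0")
        if not 0.0 <= self.censor_fraction <= 1.0:
            raise ValueError(f"group {self.label!r}: censor_fraction must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("group labels must be unique")


def _gompertz_sample(rng: np.random.Generator, n: int, shape: float, rate: float) -> np.ndarray:
    """Inverse-CDF sampling; S(t) = exp(-(rate/shape)(e^{shape t}-1))."""
    u = rng.uniform(size=n)
    if shape == 0.0:
        return -np.log(u) / rate
    return np.log1p(-shape * np.log(u) / rate) / shape


def gen_survival_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per animal: animal_id, group, time (days), event (1=death)."""
    rows = []
    for gi, g in enumerate(spec.groups):
        rng = np.random.default_rng([spec.seed, gi])
        times = _gompertz_sample(rng, g.n_animals, g.gompertz_shape, g.gompertz_rate)
        event = np.ones(g.n_animals, dtype=int)
        n_cens = int(round(g.censor_fraction * g.n_animals))
        if n_cens:
            idx = rng.choice(g.n_animals, size=n_cens, replace=False)
            times[idx] = times[idx] * rng.uniform(size=n_cens)  # strictly < death time
            event[idx] = 0
        for i in range(g.n_animals):
            rows.append((f"{g.label}-{i + 1:03d}", g.label, float(times[i]), int(event[i])))
    return pd.DataFrame(rows, columns=["animal_id", "group", "time", "event"])


def gompertz_rate_for_median(median_days: float, shape: float) -> float:
    """Baseline hazard giving the requested median lifespan at a fixed shape."""
    if shape == 0.0:
        return math.log(2) / median_days
    return shape * math.log(2) / math.expm1(shape * median_days)


#: mortality-rate doubling time of roughly 87 days, typical for laboratory mice
DEFAULT_GOMPERTZ_SHAPE = 0.008

#: group sizes and median lifespans of the sex-pooled diet-by-genotype design
#: (normal / knockout crossed with ad-libitum / caloric restriction)
MIRROR_COHORT_DESIGN = {
    "N-AL": (108, 636.0),
    "N-CR": (105, 850.0),
    "KO-AL": (97, 931.0),
    "KO-CR": (102, 1050.0),
}


def mirror_cohort_spec(seed: int = 0, shape: float = DEFAULT_GOMPERTZ_SHAPE,
                       design: Mapping[str, tuple[int, float]] | None = None) -> CohortSpec:
    design = design or MIRROR_COHORT_DESIGN
    groups = tuple(
        GroupSpec(label, n, shape, gompertz_rate_for_median(median, shape))
        for label, (n, median) in design.items()
    )
    return CohortSpec(groups=groups, seed=seed)


# ---------------------------------------------------------------------------
# expression studies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionSpec:
    """A two-group log2 expression study with planted differential genes.

    ``n_genes`` expressed genes each get one primary probe; ``n_sibling_probes``
    additional probes are assigned to randomly chosen genes (shared symbol,
    suffixally distinct probe id).  ``n_unexpressed_probes`` probes sit below
    ``detection_floor`` in every sample and map to their own (unexpressed)
    genes, emulating probe sets never detected above background.
    """

    n_genes: int
    planted_up: int = 0
    planted_down: int = 0
    effect_log2fc: float = 2.0
    residual_sd: float = 0.15
    samples_per_group: int = 3
    n_sibling_probes: int = 0
    n_unexpressed_probes: int = 0
    planted_mild_up: int = 0      # significant but inside the fold-change dead zone
    planted_mild_down: int = 0
    mild_log2fc: float = 0.42
    detection_floor: float = 6.0  # log2(64)
    groups: tuple[str, str] = ("KO", "WT")
    seed: int = 0

    def __post_init__(self):
        total = (self.planted_up + self.planted_down
                 + self.planted_mild_up + self.planted_mild_down)
        if total > self.n_genes:
            raise ValueError("planted gene counts exceed n_genes")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.samples_per_group < 2:
            raise ValueError("need >= 2 samples per group for variance estimation")


def mirror_expression_spec(seed: int = 0) -> ExpressionSpec:
    """Study mirroring the array bookkeeping: 45,101 probe sets of which
    19,956 are never detected, 25,145 retained mapping to 13,201 genes,
    with 141 increased and 164 decreased genes planted, plus 60 mild genes
    that are significant at the FDR cut but sit inside the fold-change dead
    zone (differentially expressed for background-exclusion purposes without
    entering either direction list).

    The residual SD is chosen so the planted sets are recoverable: planted
    4-fold effects are detected with probability ~1, the mild 1.34-fold
    effects stay clear of both the detection and the fold-change boundary,
    and the expected number of null genes jointly passing the FDR and
    fold-change rules is far below one, making the accounting deterministic.
    """
    return ExpressionSpec(
        n_genes=13_201, n_sibling_probes=25_145 - 13_201,
        n_unexpressed_probes=19_956, planted_up=141, planted_down=164,
        planted_mild_up=30, planted_mild_down=30,
        effect_log2fc=2.0, mild_log2fc=0.42, residual_sd=0.06, seed=seed,
    )


def gen_expression_study(spec: ExpressionSpec):
    """Returns (study, truth): an ExpressionStudy and a truth table of planted
    directions (gene, direction, log2fc)."""
    from .diffexpr import ExpressionStudy  # local import to avoid a cycle

    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i + 1:05d}" for i in range(spec.n_genes)]

    probes = [f"{g}_at" for g in genes]
    probe_gene = list(genes)
    sib_counts: dict[str, int] = {}
    for gi in rng.integers(0, spec.n_genes, size=spec.n_sibling_probes):
        g = genes[gi]
        sib_counts[g] = sib_counts.get(g, 0) + 1
        probes.append(f"{g}_s{sib_counts[g]}_at")
        probe_gene.append(g)
    for i in range(spec.n_unexpressed_probes):
        probes.append(f"ux{i + 1:05d}_at")
        probe_gene.append(f"ux{i + 1:05d}")

    n = spec.samples_per_group
    samples = [f"{spec.groups[0]}_{i + 1}" for i in range(n)] + \
              [f"{spec.groups[1]}_{i + 1}" for i in range(n)]
    design = {s: (spec.groups[0] if i < n else spec.groups[1]) for i, s in enumerate(samples)}

    n_expr = spec.n_genes + spec.n_sibling_probes
    n_probes = len(probes)
    baseline = np.empty(n_probes)
    baseline[:n_expr] = rng.uniform(spec.detection_floor + 0.5, 13.0, size=n_expr)
    baseline[n_expr:] = rng.uniform(spec.detection_floor - 2.5,
                                    spec.detection_floor - 0.5,
                                    size=spec.n_unexpressed_probes)

    effect = np.zeros(n_probes)
    planted: dict[str, float] = {}
    cursor = 0
    for count, lfc in ((spec.planted_up, spec.effect_log2fc),
                       (spec.planted_down, -spec.effect_log2fc),
                       (spec.planted_mild_up, spec.mild_log2fc),
                       (spec.planted_mild_down, -spec.mild_log2fc)):
        for gi in range(cursor, cursor + count):
            planted[genes[gi]] = lfc
        cursor += count
    for pi in range(n_expr):
        effect[pi] = planted.get(probe_gene[pi], 0.0)

    values = baseline[:, None] + spec.residual_sd * rng.standard_normal((n_probes, 2 * n))
    values[:, :n] += effect[:, None]  # first block is the treated group
    # never-detected probes stay strictly below the floor in every sample
    if spec.n_unexpressed_probes:
        np.clip(values[n_expr:], None, spec.detection_floor - 0.01, out=values[n_expr:])

    matrix = pd.DataFrame(values, index=pd.Index(probes, name="probe_id"), columns=samples)
    truth = pd.DataFrame(
        {"gene": list(planted),
         "direction": [int(np.sign(v)) for v in planted.values()],
         "log2fc": list(planted.values()),
         "mild": [abs(v) == spec.mild_log2fc != spec.effect_log2fc
                  for v in planted.values()]}
    )
    study = ExpressionStudy(matrix=matrix, probe_to_gene=dict(zip(probes, probe_gene)),
                            design=design)
    return study, truth


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterSpec:
    n_genes: int
    region_length: int = 2000
    masked_fraction: float = 0.1
    n_target: int = 0
    instances_per_gene: int = 1
    background_base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    mask_block: int = 50
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.masked_fraction <= 1.0:
            raise ValueError("masked_fraction must be in [0, 1]")
        if abs(sum(self.background_base_freqs) - 1.0) > 1e-9:
            raise ValueError("background base frequencies must sum to 1")
        if self.n_target > self.n_genes:
            raise ValueError("n_target exceeds n_genes")


def _mask_tiles(rng, L: int, frac: float, block: int) -> np.ndarray:
    """Boolean mask over positions; masked bases come in ``block``-sized tiles."""
    masked = np.zeros(L, dtype=bool)
    n_tiles = math.ceil(L / block)
    n_masked_tiles = int(round(frac * n_tiles))
    for t in rng.choice(n_tiles, size=n_masked_tiles, replace=False):
        masked[t * block:(t + 1) * block] = True
    return masked


def gen_promoter_set(spec: PromoterSpec, pwm,
                     gene_names: Sequence[str] | None = None) -> tuple[dict[str, str], pd.DataFrame]:
    """Upstream regions with masked blocks (lowercase or N, alternating per
    tile) and PWM instances planted in unmasked stretches of target genes.

    The first ``n_target`` genes are the target set.  ``gene_names`` (length
    n_genes) overrides the default p00001.. naming so promoters can be tied
    to an expression study's genes.  Returns (sequences, truth) where truth
    lists per-gene target status, number of planted instances and their
    1-based positions.
    """
    if gene_names is not None and len(gene_names) != spec.n_genes:
        raise ValueError("gene_names must have length n_genes")
    rng = np.random.default_rng(spec.seed)
    L = spec.region_length
    motif_len = pwm.length
    if L < motif_len:
        raise ValueError("region_length shorter than the motif")
    bases = np.array(list("ACGT"))
    freqs = np.asarray(spec.background_base_freqs)
    seqs: dict[str, str] = {}
    truth_rows = []
    for gi in range(spec.n_genes):
        gene = gene_names[gi] if gene_names is not None else f"p{gi + 1:05d}"
        is_target = gi < spec.n_target
        arr = rng.choice(bases, size=L, p=freqs)
        masked = _mask_tiles(rng, L, spec.masked_fraction, spec.mask_block)
        positions: list[int] = []
        if is_target and spec.instances_per_gene:
            occupied = np.zeros(L, dtype=bool)
            eligible = [
                s for s in range(L - motif_len + 1)
                if not masked[s:s + motif_len].any()
            ]
            rng.shuffle(eligible)
            for s in eligible:
                if occupied[s:s + motif_len].any():
                    continue
                inst = [bases[rng.choice(4, p=pwm.probs[:, j])] for j in range(motif_len)]
                arr[s:s + motif_len] = inst
                occupied[s:s + motif_len] = True
                positions.append(s + 1)
                if len(positions) == spec.instances_per_gene:
                    break
            if len(positions) < spec.instances_per_gene:
                raise ValueError(
                    f"gene {gene}: could not place {spec.instances_per_gene} "
                    f"instances in unmasked sequence")
        # encode masking: even tiles soft (lowercase), odd tiles hard (N)
        chars = arr.astype(object)
        for p in np.nonzero(masked)[0]:
            chars[p] = chars[p].lower() if (p // spec.mask_block) % 2 == 0 else "N"
        seqs[gene] = "".join(chars)
        truth_rows.append((gene, is_target, len(positions),
                           ",".join(map(str, positions))))
    truth = pd.DataFrame(truth_rows, columns=["gene", "is_target", "n_planted", "positions"])
    return seqs, truth


# ---------------------------------------------------------------------------
# toy ontology, qPCR plates, ranked experiments
# ---------------------------------------------------------------------------

def gen_toy_ontology(n_terms: int, n_genes: int, seed: int = 0,
                     max_direct_terms: int = 3):
    """A rooted random DAG of terms plus direct gene annotations.

    Returns (edges, annotations, genes): edges are (child, parent) pairs with
    every term reachable from the root T000; annotations map each gene to its
    directly annotated terms (ancestor propagation is the consumer's true-path
    step).
    """
    if n_terms < 1:
        raise ValueError("need at least one term")
    rng = np.random.default_rng(seed)
    terms = [f"T{i:03d}" for i in range(n_terms)]
    edges = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.uniform() < 0.3 and i > 1)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.append((terms[i], terms[p]))
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    annotations = {}
    for g in genes:
        k = rng.integers(1, max_direct_terms + 1)
        annotations[g] = {terms[t] for t in rng.choice(n_terms, size=min(k, n_terms),
                                                       replace=False)}
    return edges, annotations, genes


@dataclass(frozen=True)
class QpcrSpec:
    genes: tuple[str, ...]
    fold_changes: Mapping[str, float] = field(default_factory=dict)
    reference_gene: str = "Gapdh"
    n_per_condition: int = 8
    base_ct: float = 22.0
    noise_sd: float = 0.15
    seed: int = 0


def gen_qpcr_plate(spec: QpcrSpec) -> pd.DataFrame:
    """Ct table (sample, gene, condition, ct); treated-condition genes have
    their Ct lowered by log2(fold) relative to control."""
    rng = np.random.default_rng(spec.seed)
    rows = []
    for cond in ("treated", "control"):
        for i in range(spec.n_per_condition):
            sample = f"{cond[0]}{i + 1}"
            load = rng.normal(0.0, 0.3)  # per-sample cDNA loading offset
            rows.append((sample, spec.reference_gene, cond,
                         spec.base_ct + load + rng.normal(0.0, spec.noise_sd)))
            for g in spec.genes:
                if g == spec.reference_gene:
                    continue
                offset = 3.0  # targets less abundant than the reference
                ct = spec.base_ct + offset + load + rng.normal(0.0, spec.noise_sd)
                if cond == "treated":
                    ct -= math.log2(spec.fold_changes.get(g, 1.0))
                rows.append((sample, g, cond, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "condition", "ct"])


def gen_ranked_experiment(concordance: float, set_genes: Iterable[str], direction: int,
                          n_genes: int = 2000, seed: int = 0, effect: float = 1.0,
                          experiment_id: str = "expt") -> pd.DataFrame:
    """A ranked fold-change list (gene, score) for one external experiment.

    ``concordance`` in [-1, 1] scales a mean score shift of ``direction *
    concordance * effect`` applied to the reference set's genes; 0 gives an
    exchangeable null.
    """
    if not -1.0 <= concordance <= 1.0:
        raise ValueError("concordance must be in [-1, 1]")
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    rng = np.random.default_rng(seed)
    set_genes = sorted(set(set_genes))
    if len(set_genes) >= n_genes:
        raise ValueError("set must be smaller than the list")
    background = [f"r{i + 1:05d}" for i in range(n_genes - len(set_genes))]
    genes = set_genes + background
    scores = rng.standard_normal(len(genes))
    scores[: len(set_genes)] += direction * concordance * effect
    df = pd.DataFrame({"gene": genes, "score": scores})
    df.attrs["experiment_id"] = experiment_id
    return df


def gen_cr_battery(set_genes: Iterable[str], direction: int, n_experiments: int = 13,
                   concordance: float = 0.8, n_genes: int = 2000,
                   seed: int = 0) -> list[pd.DataFrame]:
    """A battery of ranked experiments sharing one concordance level,
    mirroring a panel of independent published comparisons."""
    return [
        gen_ranked_experiment(concordance, set_genes, direction, n_genes=n_genes,
                              seed=int(np.random.default_rng([seed, i]).integers(2 ** 31)),
                              experiment_id=f"CR{i + 1:02d}")
        for i in range(n_experiments)
    ]
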