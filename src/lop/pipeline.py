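"""End-to-end orchestration of the synthetic study.

``run_pipeline`` generates every input from a single seed, runs the stages
in dependency order (survival -> differential expression -> concordance /
term enrichment / motif enrichment -> phenotypes) and writes plain-text
artifacts stamped with the seed and a configuration hash, so reruns are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diffexpr, funcenrich, io, motif, motifenrich, phenotype, setcompare, survival, synth

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "DependencyError"]


class DependencyError(RuntimeError):
    """A stage requires the output of a stage that is toggled off."""


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    outdir: str = "lop_out"
    # stage toggles
    run_survival: bool = True
    run_de: bool = True
    run_setcompare: bool = True
    run_funcenrich: bool = True
    run_motif: bool = True
    run_phenotype: bool = True
    # thresholds
    fdr: float = 0.05
    up: float = 1.50
    down: float = 0.67
    min_frac: float = 0.80
    alpha: float = 0.05
    quantile: float = 0.90
    detection_floor: float = 6.0
    # synthetic scale (kept modest for a demo run; the generators accept the
    # full mirror of the study's bookkeeping when asked)
    n_genes: int = 3000
    n_sibling_probes: int = 400
    n_unexpressed_probes: int = 800
    planted_up: int = 60
    planted_down: int = 60
    n_experiments: int = 13
    concordance: float = 0.8
    n_terms: int = 40
    n_promoter_genes: int = 400
    n_motifs: int = 20
    region_length: int = 2000

    def __post_init__(self):
        if not (0 < self.fdr < 1 and 0 < self.alpha < 1 and 0 < self.quantile < 1):
            raise ValueError("fdr, alpha and quantile must be in (0, 1)")
        if not (0 < self.down < 1 < self.up):
            raise ValueError("fold-change thresholds must satisfy down < 1 < up")
        if not 0 < self.min_frac <= 1:
            raise ValueError("min_frac must be in (0, 1]")

    def hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(cfg: PipelineConfig) -> dict:
    return {"seed": cfg.seed, "config": cfg.hash()}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured stages; returns a dict of in-memory results."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = _stamp(cfg)
    results: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}
    summary: dict = {}

    if cfg.run_survival:
        cohort = synth.gen_survival_cohort(synth.mirror_cohort_spec(seed=cfg.seed))
        io.write_survival(cohort, out / "survival.tsv", header=stamp)
        medians = {}
        for grp in cohort["group"].unique():
            medians[grp] = survival.median_survival(survival.km_estimate(cohort, grp))
        lr = survival.logrank_test(cohort, "KO-AL", "N-AL")
        ml = survival.maxlife_quantile_test(cohort, "KO-AL", "N-AL", quantile=cfg.quantile)
        pc = survival.percent_change(medians["KO-AL"], medians["N-AL"])
        results["survival"] = {"medians": medians, "logrank": lr, "maxlife": ml,
                               "percent_change": pc}
        summary["survival"] = {
            "medians": medians,
            "logrank_chi2": lr.chi2, "logrank_p": lr.p,
            "median_increase_pct": pc.one_decimal,
            "maxlife_p": ml.p, "maxlife_threshold": ml.threshold_age,
        }

    inc_set = dec_set = None
    expressed = None
    if cfg.run_de:
        spec = synth.ExpressionSpec(
            n_genes=cfg.n_genes, n_sibling_probes=cfg.n_sibling_probes,
            n_unexpressed_probes=cfg.n_unexpressed_probes,
            planted_up=cfg.planted_up, planted_down=cfg.planted_down,
            detection_floor=cfg.detection_floor, seed=cfg.seed,
        )
        study, truth = synth.gen_expression_study(spec)
        io.write_expression(study.matrix, study.probe_to_gene, out / "expression.tsv",
                            header=stamp)
        io.write_design(study.design, out / "design.tsv", header=stamp)
        retained = diffexpr.detection_filter(study, floor=cfg.detection_floor)
        filtered = diffexpr.ExpressionStudy(study.matrix.loc[retained],
                                            study.probe_to_gene, study.design)
        per_probe = diffexpr.moderated_t(filtered, *spec.groups)
        per_probe["q"] = diffexpr.bh_adjust(per_probe["p"].to_numpy())
        per_gene = diffexpr.collapse_probes(per_probe, study.probe_to_gene)
        classified = diffexpr.classify(per_gene, fdr=cfg.fdr, up=cfg.up, down=cfg.down)
        inc, dec = diffexpr.gene_sets(classified)
        expressed = set(classified.index)
        inc_set = setcompare.GeneSet("increased", inc, direction=1)
        dec_set = setcompare.GeneSet("decreased", dec, direction=-1)
        with open(out / "de_genes.tsv", "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in stamp.items()))
            classified.to_csv(fh, sep="\t")
        io.write_gmt({"increased": inc, "decreased": dec}, out / "de_sets.gmt", header=stamp)
        results["de"] = {"classified": classified, "truth": truth,
                         "n_retained": len(retained)}
        summary["de"] = {"n_retained": len(retained), "n_increased": len(inc),
                         "n_decreased": len(dec)}

    if cfg.run_setcompare:
        if dec_set is None:
            raise DependencyError("setcompare requires the de stage")
        battery = [setcompare.make_ranked_list(df) for df in synth.gen_cr_battery(
            dec_set.genes, direction=-1, n_experiments=cfg.n_experiments,
            concordance=cfg.concordance, seed=cfg.seed)]
        frame, tally = setcompare.concordance_screen([inc_set, dec_set], battery,
                                                     alpha=cfg.alpha)
        with open(out / "concordance.tsv", "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in stamp.items()))
            frame.to_csv(fh, sep="\t", index=False)
        results["setcompare"] = {"frame": frame, "tally": tally}
        summary["setcompare"] = {k: list(v) for k, v in tally.items()}

    if cfg.run_funcenrich:
        if inc_set is None:
            raise DependencyError("funcenrich requires the de stage")
        edges, annotations, _ = synth.gen_toy_ontology(cfg.n_terms, cfg.n_genes,
                                                       seed=cfg.seed)
        annotations = {g: t for g, t in annotations.items() if g in expressed}
        dag = funcenrich.TermDAG.build(edges, annotations)
        background = funcenrich.set_background(expressed, inc_set.genes | dec_set.genes)
        # the tested set re-enters the universe alongside the non-DE background
        universe = background | inc_set.genes
        terms = funcenrich.conditional_walk(dag, inc_set.genes, universe, alpha=cfg.alpha)
        term_frame = pd.DataFrame([t.__dict__ for t in terms])
        with open(out / "terms.tsv", "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in stamp.items()))
            term_frame.to_csv(fh, sep="\t", index=False)
        results["funcenrich"] = {"terms": terms, "background_size": len(background)}
        summary["funcenrich"] = {"n_terms_tested": len(terms),
                                 "background_size": len(background)}

    if cfg.run_motif:
        if inc_set is None:
            raise DependencyError("motif enrichment requires the de stage")
        rng = np.random.default_rng([cfg.seed, 7])
        pwms = []
        for i in range(cfg.n_motifs):
            L = int(rng.integers(6, 11))
            # informative columns: a dominant consensus base plus light noise,
            # as in empirically determined binding-site matrices
            pfm = rng.integers(0, 3, size=(4, L)).astype(float)
            consensus = rng.integers(0, 4, size=L)
            pfm[consensus, np.arange(L)] += rng.integers(12, 20, size=L)
            pwms.append(motif.build_pwm(f"M{i + 1:03d}", pfm))
        planted_pwm = pwms[0]
        targets = sorted(inc_set.genes)[: cfg.n_promoter_genes // 4]
        others = [g for g in sorted(expressed) if g not in set(targets)]
        names = targets + others[: cfg.n_promoter_genes - len(targets)]
        pspec = synth.PromoterSpec(n_genes=len(names), region_length=cfg.region_length,
                                   masked_fraction=0.1, n_target=len(targets),
                                   instances_per_gene=2, seed=cfg.seed)
        seqs, ptruth = synth.gen_promoter_set(pspec, planted_pwm, gene_names=names)
        io.write_fasta(seqs, out / "promoters.fa", header=stamp)
        io.write_pfms({p.id: p.pfm for p in pwms}, out / "motifs.pfm", header=stamp)
        counts = motif.count_table(seqs, pwms, min_frac=cfg.min_frac)
        with open(out / "motif_counts.tsv", "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in stamp.items()))
            counts.to_csv(fh, sep="\t", index=False)
        bg_genes = frozenset(names) - set(targets)
        screen = motifenrich.screen_dictionary(
            counts, setcompare.GeneSet("increased_promoters", frozenset(targets), 1),
            bg_genes, alpha=cfg.alpha)
        with open(out / "motif_enrichment.tsv", "w") as fh:
            fh.write("".join(f"# {k}={v}\n" for k, v in stamp.items()))
            screen.to_csv(fh, sep="\t", index=False)
        results["motif"] = {"screen": screen, "planted": planted_pwm.id,
                            "promoter_truth": ptruth}
        summary["motif"] = {"planted": planted_pwm.id,
                            "top_motif": str(screen.iloc[0]["motif"])}

    if cfg.run_phenotype:
        qspec = synth.QpcrSpec(genes=("Sult2a2", "Cyp2b9", "Fmo3"),
                               fold_changes={"Sult2a2": 1000.0, "Cyp2b9": 12.0, "Fmo3": 8.0},
                               seed=cfg.seed)
        plate = synth.gen_qpcr_plate(qspec)
        io.write_ct(plate, out / "qpcr.tsv", header=stamp)
        folds = phenotype.fold_induction(plate, reference_gene=qspec.reference_gene)
        results["phenotype"] = {"fold_induction": folds}
        summary["phenotype"] = {g: float(f) for g, f in folds.items()}

    with open(out / "summary.json", "w") as fh:
        json.dump({"stamp": stamp, **summary}, fh, indent=2, sort_keys=True, default=str)
    results["summary"] = summary
    return results
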