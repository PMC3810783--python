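import numpy as np
import pandas as pd
import pytest

from lop import diffexpr, synth


@pytest.fixture
def small_cohort():
    """Two Gompertz groups, 60 animals each, no censoring."""
    spec = synth.CohortSpec(
        groups=(
            synth.GroupSpec("A", 60, 0.008, synth.gompertz_rate_for_median(900, 0.008)),
            synth.GroupSpec("B", 60, 0.008, synth.gompertz_rate_for_median(640, 0.008)),
        ),
        seed=11,
    )
    return synth.gen_survival_cohort(spec)


@pytest.fixture
def null_study():
    """2000-probe study with no planted effects."""
    spec = synth.ExpressionSpec(n_genes=2000, planted_up=0, planted_down=0,
                                residual_sd=0.2, seed=5)
    study, _ = synth.gen_expression_study(spec)
    return study


def hand_table(times_events_by_group):
    """Survival table from {group: [(time, event), ...]}."""
    rows = []
    for grp, pairs in times_events_by_group.items():
        for i, (t, e) in enumerate(pairs):
            rows.append((f"{grp}{i}", grp, float(t), int(e)))
    return pd.DataFrame(rows, columns=["animal_id", "group", "time", "event"])


@pytest.fixture
def make_table():
    return hand_table


def run_de(study, floor=6.0, fdr=0.05, up=1.5, down=0.67, prior_df=None):
    """Filter -> moderated t -> BH -> collapse -> classify, as one call."""
    retained = diffexpr.detection_filter(study, floor=floor)
    filtered = diffexpr.ExpressionStudy(study.matrix.loc[retained],
                                        study.probe_to_gene, study.design)
    groups = list(dict.fromkeys(filtered.design.values()))
    res = diffexpr.moderated_t(filtered, groups[0], groups[1], prior_df=prior_df)
    res["q"] = diffexpr.bh_adjust(res["p"].to_numpy())
    per_gene = diffexpr.collapse_probes(res, study.probe_to_gene)
    return diffexpr.classify(per_gene, fdr=fdr, up=up, down=down), len(retained)


@pytest.fixture
def de_pipeline():
    return run_de
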