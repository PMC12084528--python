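"""Reference experiments: end-to-end runs that characterise the pipeline.

The classification-accuracy experiment mirrors the benchmark used to
validate the instrument: five dual-encoded bead populations with per-dye
intensity CVs near 20% are simulated as HDR video, decoded, tracked and
quality-controlled; covariance-ellipse gates are fit on an independent
training run, and the fraction of gated test beads assigned to their
true population is reported.
"""

from __future__ import annotations

import numpy as np

from .calls import GateSet, classify, truth_table
from .config import RunConfig
from .pipeline import decode_stack, match_tracks_to_truth
from .simulate import simulate_run


def _decode_matched(config: RunConfig, n_beads: int, seed: int, bank=None):
    stack, backgrounds, truth = simulate_run(
        config.population, n_beads, seed, config.geometry, config.schedule)
    result = decode_stack(stack, backgrounds, config, bank=bank)
    matched = match_tracks_to_truth(result.track_table, truth)
    usable = matched[matched.included & (matched.bead_id >= 0)]
    return usable, truth, result


def classification_accuracy(n_per_group: int = 200, seed: int = 1,
                            config: RunConfig | None = None) -> dict:
    """Train/test classification accuracy of the full pipeline.

    Simulates ``5 * n_per_group`` beads twice (independent seeds derived
    from ``seed``): gates are fit as Mahalanobis-radius ellipses on the
    decoded training cohort, then applied to the decoded test cohort.
    Accuracy is the fraction of uniquely gated test beads whose call
    matches their true population.
    """
    config = config or RunConfig()
    n_beads = len(config.population.groups) * n_per_group
    bank = config.mask_bank()

    train, _, _ = _decode_matched(config, n_beads, 2 * seed + 1, bank)
    gates = GateSet.fit_ellipses(train.b1_mean.to_numpy(),
                                 train.b2_mean.to_numpy(),
                                 train.true_group.to_numpy(),
                                 radius=config.gate_radius)

    test, truth, result = _decode_matched(config, n_beads, 2 * seed + 2,
                                          bank)
    labels = classify(test.b1_mean.to_numpy(), test.b2_mean.to_numpy(),
                      gates)
    table = truth_table(labels, test.true_group.to_numpy())

    per_group_cv = {}
    for lab, grp in test.groupby("true_group"):
        per_group_cv[str(lab)] = (
            float(grp.b1_mean.std(ddof=1) / grp.b1_mean.mean()),
            float(grp.b2_mean.std(ddof=1) / grp.b2_mean.mean()))

    return {
        "accuracy": table.accuracy,
        "accuracy_pct": 100.0 * table.accuracy,
        "n_gated": table.n_gated,
        "n_test": table.n_total,
        "n_simulated": n_beads,
        "confusion": table.confusion,
        "per_group_cv": per_group_cv,
        "n_positive_calls": int(result.call_table.positive.sum())
        if len(result.call_table) else 0,
        "n_true_positives": int(truth.hrp_positive.sum()),
    }
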