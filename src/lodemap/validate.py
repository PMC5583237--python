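"""Recovery metrics against simulation truth.

These helpers score a built map (and LODE placements) against the truth
bundle of a synthetic study: linkage-group assignment purity, per-group
order concordance (Kendall tau-b between built and true positions, so
honestly co-localised markers drop out), total-length recovery against the
true span of the mapped markers, female-to-male expansion recovery, and
LODE assignment/position accuracy.  They also host the statistical
calibration harness for the sex-heterogeneity test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import kendalltau

from .linkage import GeneticMap, TwoPointResult
from .simulate import TruthBundle
from .stats import sex_heterogeneity_test


@dataclass
class MapRecovery:
    n_mapped: int
    n_markers_true: int
    assignment_accuracy: float      # fraction of mapped markers on their majority group
    taus: list[float]               # per built group, |tau-b| vs true positions
    built_length_cM: float
    true_length_cM: float           # true span of the mapped markers, group by group

    @property
    def min_tau(self) -> float:
        return min(self.taus)

    @property
    def length_ratio(self) -> float:
        return self.built_length_cM / self.true_length_cM


def group_truth_labels(gmap: GeneticMap, truth: TruthBundle) -> dict[str, str]:
    """Majority-rule mapping from built group name to true chromosome."""
    true_lg = truth.true_map.lg_of()
    out = {}
    for g in gmap.groups:
        labels = [true_lg[m] for m in g.marker_ids]
        out[g.name] = max(set(labels), key=labels.count)
    return out


def map_recovery(gmap: GeneticMap, truth: TruthBundle,
                 sexavg_truth: bool = False) -> MapRecovery:
    """Score a built map against the simulation truth.

    With ``sexavg_truth`` the true positions are the mean of the female and
    male truth (appropriate when the study was simulated with a sex-specific
    expansion, since the built sex-average map pools both meiosis types).
    """
    true_lg = truth.true_map.lg_of()
    df = truth.true_map.df
    if sexavg_truth:
        pos = dict(zip(df["marker_id"], (df["pos_f"] + df["pos_m"]) / 2.0))
    else:
        pos = dict(zip(df["marker_id"], df["pos_cM"]))
    correct = total = 0
    taus: list[float] = []
    built_len = true_len = 0.0
    for g in gmap.groups:
        labels = [true_lg[m] for m in g.marker_ids]
        majority = max(set(labels), key=labels.count)
        correct += sum(lab == majority for lab in labels)
        total += len(labels)
        tpos = np.array([pos[m] for m in g.marker_ids])
        tau = kendalltau(g.positions(), tpos).statistic
        taus.append(abs(float(tau)))
        built_len += g.length_cM
        true_len += float(tpos.max() - tpos.min())
    return MapRecovery(total, len(truth.true_map.marker_ids),
                       correct / total if total else float("nan"),
                       taus, built_len, true_len)


def fm_genome_ratio_recovery(gmap: GeneticMap) -> float:
    """Genome-wide female:male ratio of totals from a sexed map."""
    from .stats import fm_ratios

    genome = {r.label: r for r in fm_ratios(gmap) if r.scope == "genome"}
    return genome["totals"].ratio


@dataclass
class LODERecovery:
    n_orphans: int
    n_assigned: int
    n_correct: int
    position_errors_cM: list[float]   # for correctly assigned orphans

    @property
    def correct_rate(self) -> float:
        return self.n_correct / self.n_assigned if self.n_assigned else float("nan")

    @property
    def median_position_error(self) -> float:
        return float(np.median(self.position_errors_cM)) if self.position_errors_cM \
            else float("nan")


def lode_recovery(placements, gmap: GeneticMap, truth: TruthBundle) -> LODERecovery:
    """Score LODE placements: correct-group rate and cM position error.

    Built coordinates are translated to truth coordinates by interpolating
    over the group's mapped markers, so the error is measured on the true
    map scale.
    """
    true_lg = truth.true_map.lg_of()
    true_pos = truth.true_map.positions()
    labels = group_truth_labels(gmap, truth)
    n_assigned = n_correct = 0
    errors: list[float] = []
    for p in placements:
        if not p.assigned:
            continue
        n_assigned += 1
        if labels.get(p.lg) != true_lg[p.marker_id]:
            continue
        n_correct += 1
        g = next(g for g in gmap.groups if g.name == p.lg)
        bpos = np.asarray(g.positions())
        tpos = np.array([true_pos[m] for m in g.marker_ids])
        order = np.argsort(bpos)
        est = float(np.interp(p.position_cM, bpos[order], tpos[order]))
        errors.append(abs(est - true_pos[p.marker_id]))
    return LODERecovery(len(placements), n_assigned, n_correct, errors)


def sex_test_type1_error(n_intervals: int = 1000, n_per_sex: int = 200,
                         theta: float = 0.2, alpha: float = 0.05,
                         seed: int = 0) -> float:
    """Empirical size of the sex-heterogeneity test under equal recombination."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_intervals):
        rm = int(rng.binomial(n_per_sex, theta))
        rf = int(rng.binomial(n_per_sex, theta))
        tp = TwoPointResult("a", "b", 2 * n_per_sex, rm + rf,
                            (rm + rf) / (2 * n_per_sex), 0.0,
                            n_m=n_per_sex, r_m=rm, n_f=n_per_sex, r_f=rf)
        if sex_heterogeneity_test(tp).p < alpha:
            rejections += 1
    return rejections / n_intervals
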