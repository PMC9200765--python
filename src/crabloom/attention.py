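"""Discriminating attention mechanisms from escape and spike data.

Behaviour.  With two simultaneous looming stimuli, selective attention
predicts a bimodal escape distribution with one mode directly away from
each stimulus, while divided attention predicts a single mode in the
direction that maximises distance from both.  In the stimulus frame used
throughout (one stimulus approaching from 0 deg, the other from 270 or
180 deg) the multimodal transform (angles x4 mod 360 for 90-deg
separation, x2 for 180-deg/axial) maps the selective modes onto 0 deg
and the divided mode onto 180 deg, so a single post-transform mean
direction discriminates the hypotheses; single-stimulus data transformed
the same way (mode at 0 deg) provide the selective reference.

Neurons.  If a looming-sensitive neuron attends selectively, its
response to paired stimuli should match the stronger single-stimulus
response (a max rule); if it integrates, the paired response should be
the sum or average of the single responses.  The verdict is the rule
with the smallest median absolute prediction error across neurons,
declared only when a bootstrap interval separates it from the runner-up.

The repeated-measures structure of both experiments is honoured by
stratifying permutation tests within subject.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations, product
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import circstats as cs
from .circstats import InvalidInputError
from .spikes import SpikeTrain, analyze_train
from .synth import TreatmentSpec, divided_modes

logger = logging.getLogger("crabloom")


# ---------------------------------------------------------------------------
# predictions


@dataclass(frozen=True)
class HypothesisPrediction:
    treatment: TreatmentSpec
    hypothesis: str  # selective | divided
    predicted_modes: tuple[float, ...]


def predict_directions(
    treatment: TreatmentSpec, hypothesis: str
) -> HypothesisPrediction:
    """Escape mode(s) predicted for a treatment under a hypothesis.

    Selective: one mode opposite each stimulus.  Divided: the circular
    mean of the away-directions (for opposed stimuli, the two orthogonal
    solutions).
    """
    if hypothesis == "selective":
        modes = tuple(
            (a + 180.0) % 360.0 for a in treatment.stimulus_azimuths
        )
    elif hypothesis == "divided":
        modes = tuple(divided_modes(treatment))
    else:
        raise InvalidInputError(f"unknown hypothesis {hypothesis!r}")
    return HypothesisPrediction(treatment, hypothesis, modes)


@dataclass
class AttentionReport:
    """Verdicts plus the statistics that produced them."""

    behavioral_verdict: str = "inconclusive"
    neural_verdict: str = "inconclusive"
    statistics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "behavioral_verdict": self.behavioral_verdict,
            "neural_verdict": self.neural_verdict,
            "statistics": self.statistics,
        }


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds shared across the analysis stages."""

    alpha: float = 0.05
    n_perm: int = 9999
    n_boot: int = 2000
    fwhm: float = 0.2
    dt: float = 0.001
    min_duration: float | None = 0.4
    min_responders: int = 10
    seed: int = 0


# ---------------------------------------------------------------------------
# behavioural pipeline


def _relative_directions(group: pd.DataFrame) -> tuple[np.ndarray, int | None]:
    """Escape directions rotated into the canonical stimulus frame.

    Stimulus 1 is rotated to 0 deg; for paired treatments the frame is
    reflected if needed so the second stimulus sits at 270 (90-deg
    separation) or 180 deg.  Returns (directions, multiplier) where the
    multiplier is 4 / 2 for paired treatments and None for singles.
    """
    resp = group[group["responded"] == 1]
    az1 = resp["stim_azimuth_1"].to_numpy(float)
    d = (resp["escape_direction_deg"].to_numpy(float) - az1) % 360.0
    az2 = resp["stim_azimuth_2"].to_numpy(float)
    if np.isnan(az2).all():
        return d, None
    rel2 = (az2 - az1) % 360.0
    # mirror frames where the second stimulus sits at +90 instead of -90
    d = np.where(np.isclose(rel2, 90.0), (-d) % 360.0, d)
    sep = np.where(np.isclose(rel2, 180.0), 180.0, 90.0)
    m = 2 if np.isclose(float(sep[0]), 180.0) else 4
    return d, m


def behavioral_decision(
    trials: pd.DataFrame, config: AnalysisConfig | None = None
) -> AttentionReport:
    """Selective-vs-divided verdict from a behavioural trial table.

    Per paired treatment: transform both the paired and the single
    escape directions to unimodal form, Rayleigh-test them, compare the
    transformed mean direction against the selective (0 deg) and divided
    (180 deg) poles, compare dispersions (Rao test), and -- for 90-deg
    separation -- run the green/red sector permutation test against the
    combined-and-rotated single distribution.  The overall verdict is
    the consensus of the per-treatment classifications; treatments whose
    transformed distribution is not significantly directional, and
    datasets with conflicting classifications, are inconclusive.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    groups = {t: g for t, g in trials.groupby("treatment", sort=False)}
    singles = [
        t for t, g in groups.items()
        if np.isnan(g["stim_azimuth_2"].to_numpy(float)).all()
    ]
    paired = [t for t in groups if t not in singles]
    if not paired or not singles:
        raise InvalidInputError(
            "need at least one single and one paired treatment"
        )
    single_dirs, _ = _relative_directions(
        pd.concat([groups[t] for t in singles])
    )
    stats: dict = {"treatments": {}}
    verdicts = []
    for t in paired:
        dirs, m = _relative_directions(groups[t])
        entry: dict = {"n_responding": int(dirs.size), "multiplier": m}
        if dirs.size < config.min_responders or (
            single_dirs.size < config.min_responders
        ):
            logger.warning(
                "treatment %s: fewer than %d responding trials; inconclusive",
                t,
                config.min_responders,
            )
            entry["classification"] = "inconclusive"
            entry["reason"] = "too few responding trials"
            stats["treatments"][t] = entry
            verdicts.append("inconclusive")
            continue
        t_paired = cs.transform_multimodal(dirs, m)
        t_single = cs.transform_multimodal(single_dirs, m)
        z_raw, p_raw = cs.rayleigh_test(dirs)
        z_tp, p_tp = cs.rayleigh_test(t_paired)
        z_ts, p_ts = cs.rayleigh_test(t_single)
        sum_p = cs.circ_summary(t_paired)
        sum_s = cs.circ_summary(t_single)
        ci_p = cs.bootstrap_direction_ci(
            t_paired, n_boot=config.n_boot, seed=int(rng.integers(2**31))
        )
        ci_s = cs.bootstrap_direction_ci(
            t_single, n_boot=config.n_boot, seed=int(rng.integers(2**31))
        )
        chi2, df, p_rao = cs.rao_dispersion_test([t_single, t_paired])
        entry.update(
            rayleigh_raw={"Z": z_raw, "p": p_raw},
            rayleigh_transformed={"Z": z_tp, "p": p_tp},
            rayleigh_single_transformed={"Z": z_ts, "p": p_ts},
            mean_transformed=sum_p.mean_direction,
            rho_transformed=sum_p.rho,
            mean_single_transformed=sum_s.mean_direction,
            ci_transformed=ci_p,
            ci_single_transformed=ci_s,
            means_indistinguishable=cs.arcs_overlap(ci_p, ci_s),
            rao_dispersion={"chi2": chi2, "df": df, "p": p_rao},
        )
        if m == 4:
            entry["sector_test"] = _sector_entry(
                single_dirs, dirs, config, rng
            )
        if p_tp >= config.alpha or not sum_p.mean_defined:
            entry["classification"] = "inconclusive"
        else:
            to_selective = abs(cs.angular_difference(sum_p.mean_direction, 0.0))
            entry["classification"] = (
                "selective" if to_selective <= 90.0 else "divided"
            )
        stats["treatments"][t] = entry
        verdicts.append(entry["classification"])
    informative = [v for v in verdicts if v != "inconclusive"]
    if informative and len(set(informative)) == 1:
        verdict = informative[0]
    else:
        verdict = "inconclusive"
    return AttentionReport(behavioral_verdict=verdict, statistics=stats)


def _sector_entry(
    single_dirs: np.ndarray,
    paired_dirs: np.ndarray,
    config: AnalysisConfig,
    rng: np.random.Generator,
) -> dict:
    """Green/red sector comparison for the 90-deg paired treatment.

    The single-treatment escapes are combined with a copy rotated by
    -90 deg, emulating the second stimulus position, then both groups
    are classified into the green / white / red sectors and the green
    proportions compared by permutation.  If either group has no escape
    outside the white sectors (perfectly concentrated data) the test
    carries no evidence towards the divided mode and p = 1 is recorded.
    """
    combined_single = np.concatenate(
        [single_dirs, (single_dirs - 90.0) % 360.0]
    )
    scheme = cs.paired90_sector_scheme()
    labels_s = cs.sector_classify(combined_single, scheme)
    labels_p = cs.sector_classify(paired_dirs, scheme)
    try:
        ps, pp, pval = cs.sector_proportion_test(
            labels_s,
            labels_p,
            n_perm=config.n_perm,
            seed=int(rng.integers(2**31)),
        )
    except InvalidInputError:
        return {
            "prop_green_single": None,
            "prop_green_paired": None,
            "p": 1.0,
            "note": "no escapes outside the white sectors",
        }
    return {"prop_green_single": ps, "prop_green_paired": pp, "p": pval}


def orientation_effect(
    trials: pd.DataFrame,
    config: AnalysisConfig | None = None,
    min_bin_n: int = 5,
) -> pd.DataFrame:
    """Per-orientation-bin circular summaries of escape direction.

    Trials are grouped by treatment and by the 90-deg body-orientation
    bin (lateral vs anterior/posterior alignment with the reference
    stimulus).  Per bin: circular mean, resultant length, bootstrap CI
    and Rayleigh p (axial for 180-deg-separated treatments).  Bins with
    fewer than ``min_bin_n`` responding trials are flagged, not tested.
    """
    config = config or AnalysisConfig()
    rng = np.random.default_rng(config.seed)
    rows = []
    for treatment, group in trials.groupby("treatment", sort=False):
        resp = group[group["responded"] == 1]
        if resp.empty:
            continue
        dirs, m = _relative_directions(resp)
        axial = m == 2
        az1 = resp["stim_azimuth_1"].to_numpy(float)
        orient = (
            resp["body_orientation_deg"].to_numpy(float) - az1
        ) % 360.0
        bins = cs.bin_orientation(orient)
        for label in np.unique(bins):
            d = dirs[bins == label]
            row = {
                "treatment": treatment,
                "orientation_bin": label,
                "n": int(d.size),
                "tested": d.size >= min_bin_n,
            }
            if d.size >= min_bin_n:
                summary = cs.circ_summary(d, axial=axial)
                row.update(
                    mean_direction=summary.mean_direction,
                    rho=summary.rho,
                )
                if d.size >= 8:
                    lo, hi = cs.bootstrap_direction_ci(
                        d,
                        n_boot=config.n_boot,
                        seed=int(rng.integers(2**31)),
                        axial=axial,
                    )
                    row.update(ci_lo=lo, ci_hi=hi)
                row["rayleigh_p"] = cs.rayleigh_test(d, axial=axial)[1]
                row["rayleigh_p_raw"] = cs.rayleigh_test(d)[1]
            else:
                logger.info(
                    "orientation bin %s/%s has n=%d < %d; not tested",
                    treatment,
                    label,
                    d.size,
                    min_bin_n,
                )
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# neural pipeline


_RULE_FUNCS = {
    "select_stronger": lambda a, b: np.maximum(a, b),
    "sum": lambda a, b: a + b,
    "average": lambda a, b: (a + b) / 2.0,
}


def ephys_metrics_table(
    trains: list[SpikeTrain], config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Response metrics for a list of spike trains, one row per train."""
    config = config or AnalysisConfig()
    rows = []
    for train in trains:
        metrics = analyze_train(
            train,
            fwhm=config.fwhm,
            dt=config.dt,
            min_duration=config.min_duration,
        )
        rows.append(
            {
                "neuron_id": train.neuron_id,
                "crab_id": train.crab_id,
                "trial_id": train.trial_id,
                "treatment": train.treatment,
                "responded": metrics.responded,
                "onset_time_to_collision_s": metrics.onset_time_to_collision,
                "peak_rate_hz": metrics.peak_rate,
                "mean_rate_hz": metrics.mean_rate_during_response,
            }
        )
    return pd.DataFrame(rows)


def neural_decision(
    metrics: pd.DataFrame,
    config: AnalysisConfig | None = None,
    paired_treatment: str = "Paired",
    single_treatments: tuple[str, str] = ("Primary", "Secondary"),
) -> AttentionReport:
    """Integration-rule verdict from per-neuron response metrics.

    For every neuron with complete Primary / Secondary / Paired metrics
    (trial-averaged), the paired peak rate predicted under the
    select-stronger (max), sum and average rules is compared with the
    observed paired peak; the verdict is the rule with the smallest
    median relative error across neurons, declared only if the paired
    bootstrap 95% CI of the median-error difference with the runner-up
    excludes zero; otherwise inconclusive.

    The peak rate drives the verdict because it is measured identically
    under every treatment; the average rate during response is windowed
    by each treatment's own onset, so blends of single-stimulus averages
    do not predict the paired average and its errors are reported as
    supporting statistics only.
    """
    config = config or AnalysisConfig()
    responded = metrics[metrics["responded"].astype(bool)]
    cells = responded.groupby(["neuron_id", "treatment"])[
        ["peak_rate_hz", "mean_rate_hz"]
    ].mean()
    wanted = [*single_treatments, paired_treatment]
    errors: dict[str, list[float]] = {r: [] for r in _RULE_FUNCS}
    mean_rate_errors: dict[str, list[float]] = {r: [] for r in _RULE_FUNCS}
    used = []
    for neuron in cells.index.get_level_values(0).unique():
        have = cells.loc[neuron]
        if not all(t in have.index for t in wanted):
            logger.info(
                "neuron %s lacks a complete treatment set; excluded", neuron
            )
            continue
        used.append(neuron)
        a = have.loc[single_treatments[0]]
        b = have.loc[single_treatments[1]]
        obs = have.loc[paired_treatment]
        for rule, f in _RULE_FUNCS.items():
            for col, store in (
                ("peak_rate_hz", errors),
                ("mean_rate_hz", mean_rate_errors),
            ):
                store[rule].append(
                    float(
                        abs(f(a[col], b[col]) - obs[col])
                        / max(obs[col], 1e-9)
                    )
                )
    n = len(used)
    report = AttentionReport()
    report.statistics["n_neurons"] = n
    if n < 5:
        logger.warning("only %d complete neurons; verdict inconclusive", n)
        report.statistics["reason"] = "fewer than 5 complete neurons"
        return report
    med = {r: float(np.median(e)) for r, e in errors.items()}
    order = sorted(med, key=med.get)
    best, runner = order[0], order[1]
    err_b = np.asarray(errors[best])
    err_r = np.asarray(errors[runner])
    rng = np.random.default_rng(config.seed)
    idx = rng.integers(0, n, size=(config.n_boot, n))
    diffs = np.median(err_b[idx], axis=1) - np.median(err_r[idx], axis=1)
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    report.statistics.update(
        median_error_by_rule=med,
        median_mean_rate_error_by_rule={
            r: float(np.median(e)) for r, e in mean_rate_errors.items()
        },
        best_rule=best,
        runner_up=runner,
        median_error_diff_ci=[float(lo), float(hi)],
    )
    if hi < 0.0:
        report.neural_verdict = best
    return report


# ---------------------------------------------------------------------------
# timing contrasts


def _stratified_permutation_p(
    values: np.ndarray,
    is_group_a: np.ndarray,
    subjects: np.ndarray,
    n_perm: int | None,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Two-sided permutation p for a difference of group means,
    permuting group labels only within subject."""

    def stat(mask_a: np.ndarray) -> float:
        return values[mask_a].mean() - values[~mask_a].mean()

    observed = stat(is_group_a)
    subject_idx = {s: np.nonzero(subjects == s)[0] for s in np.unique(subjects)}
    arrangements = [
        comb(idx.size, int(is_group_a[idx].sum()))
        for idx in subject_idx.values()
    ]
    total = int(np.prod(arrangements, dtype=float))
    if n_perm is None or total <= (n_perm or 0):
        per_subject = []
        for idx in subject_idx.values():
            k = int(is_group_a[idx].sum())
            opts = []
            for pos in combinations(range(idx.size), k):
                labels = np.zeros(idx.size, dtype=bool)
                labels[list(pos)] = True
                opts.append(labels)
            per_subject.append(opts)
        count = 0
        for combo in product(*per_subject):
            mask = is_group_a.copy()
            for idx, labels in zip(subject_idx.values(), combo):
                mask[idx] = labels
            if abs(stat(mask)) >= abs(observed) - 1e-12:
                count += 1
        return observed, count / total
    count = 0
    mask = is_group_a.copy()
    for _ in range(int(n_perm)):
        for idx in subject_idx.values():
            mask[idx] = rng.permutation(mask[idx])
        if abs(stat(mask)) >= abs(observed) - 1e-12:
            count += 1
    return observed, (1 + count) / (1 + int(n_perm))


def timing_comparison(
    data: pd.DataFrame,
    value_col: str = "time_to_collision_s",
    group_col: str = "treatment",
    subject_col: str = "crab_id",
    transform: str | None = "sqrt",
    n_perm: int | None = 9999,
    seed: int | None = None,
    min_subjects: int = 3,
) -> pd.DataFrame:
    """Subject-stratified permutation tests on response timing.

    All pairwise contrasts between the levels of ``group_col`` are
    tested on (optionally square-root-transformed) values; within-subject
    permutation preserves the repeated-measures dependence.  P-values
    are Holm-adjusted across contrasts; contrasts with fewer than
    ``min_subjects`` subjects represented in both groups are skipped.
    When the number of distinct within-subject label arrangements is at
    most ``n_perm`` the permutation distribution is enumerated exactly;
    ``n_perm=None`` forces enumeration.
    """
    rng = np.random.default_rng(seed)
    df = data.dropna(subset=[value_col]).copy()
    if transform == "sqrt":
        df[value_col] = np.sqrt(df[value_col])
    elif transform == "log":
        df[value_col] = np.log(df[value_col])
    elif transform is not None:
        raise InvalidInputError(f"unknown transform {transform!r}")
    levels = list(df[group_col].unique())
    if len(levels) < 2:
        raise InvalidInputError("need at least 2 groups to compare")
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            sub = df[df[group_col].isin([a, b])]
            counts = sub.groupby(group_col)[subject_col].nunique()
            if counts.reindex([a, b]).fillna(0).min() < min_subjects:
                logger.info(
                    "contrast %s vs %s skipped: fewer than %d subjects",
                    a,
                    b,
                    min_subjects,
                )
                continue
            obs, p = _stratified_permutation_p(
                sub[value_col].to_numpy(float),
                (sub[group_col] == a).to_numpy(),
                sub[subject_col].to_numpy(),
                n_perm,
                rng,
            )
            rows.append(
                {
                    "group_a": a,
                    "group_b": b,
                    "mean_diff": obs,
                    "p_raw": p,
                    "n_obs": int(len(sub)),
                    "n_subjects": int(sub[subject_col].nunique()),
                }
            )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["p_holm"] = multipletests(
            result["p_raw"].to_numpy(), method="holm"
        )[1]
    return result
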