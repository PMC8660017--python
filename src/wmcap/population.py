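"""Population-level information analyses.

Window-pooled PEV tables (early/late sample, early/late delay), one-way
load-effect ANOVAs with Bonferroni post hocs, one-sample above-zero tests,
correct-trial subsampling against error trials, and hierarchical clustering
of per-neuron PEV timecourses with a (1 - Pearson correlation) distance and
average (UPGMA) linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage
from scipy.spatial.distance import pdist

from .information import color_labels, omega_squared, select_load_trials
from .task import DELAY_S, SAMPLE_S, DomainError, SpikeTable, as_trial_list

#: Analysis windows in seconds from sample onset; the sample splits into
#: two 400-ms halves and the delay into two 500-ms halves.
WINDOWS: dict[str, tuple[float, float]] = {
    "early_sample": (0.0, 0.4),
    "late_sample": (0.4, SAMPLE_S),
    "early_delay": (SAMPLE_S, SAMPLE_S + 0.5),
    "late_delay": (SAMPLE_S + 0.5, SAMPLE_S + DELAY_S),
}


def _check_windows(windows: dict[str, tuple[float, float]]) -> None:
    spans = sorted(windows.values())
    edges = [0.0]
    for a, b in spans:
        if abs(a - edges[-1]) > 1e-9 or b <= a:
            raise DomainError("windows must tile the sample and delay exactly")
        edges.append(b)
    if abs(edges[-1] - (SAMPLE_S + DELAY_S)) > 1e-9:
        raise DomainError("windows must end at the end of the delay")


def window_pev(spikes: SpikeTable, trials, neurons: dict[int, int],
               loads: tuple[int, ...] = (1, 2, 3),
               windows: dict[str, tuple[float, float]] | None = None
               ) -> pd.DataFrame:
    """One omega^2 per (neuron, window, load) from window-pooled counts.

    ``neurons`` maps neuron_id to favorite location.  Counts are pooled
    over each whole window and a single one-way decomposition by color
    identity is computed per cell.  Returns a long-format DataFrame with
    columns neuron_id, window, load, omega2, n_trials.
    """
    windows = dict(WINDOWS) if windows is None else windows
    _check_windows(windows)
    trials = as_trial_list(trials)
    rows = []
    for nid, fav in neurons.items():
        for load in loads:
            sel = select_load_trials(trials, fav, load, axis="ipsi")
            if not sel:
                continue
            labels = color_labels(sel, fav)
            if np.unique(labels).size < 2 or min(
                np.sum(labels == g) for g in np.unique(labels)
            ) < 2:
                continue
            tids = [t.trial_id for t in sel]
            for name, (a, b) in windows.items():
                vals = spikes.counts(nid, tids, a, b)
                om = omega_squared(vals, labels).omega_squared
                rows.append((nid, name, load, om, len(sel)))
    return pd.DataFrame(
        rows, columns=["neuron_id", "window", "load", "omega2", "n_trials"]
    )


@dataclass
class LoadAnova:
    """One-way ANOVA of window PEV across loads, with Bonferroni post hocs."""

    f: float
    df_between: int
    df_within: int
    p: float
    omega_squared: float
    pairwise_p: dict[tuple[int, int], float]
    loads: tuple[int, ...]


def load_effect_anova(window_table: pd.DataFrame, window: str) -> LoadAnova:
    """Test the load effect on per-neuron window PEV values.

    The effect size is the same omega^2 decomposition used for spike
    counts, applied to this ANOVA.  Pairwise load comparisons use
    independent two-sample t-tests with Bonferroni correction (m = number
    of pairs, capped at 1).
    """
    sub = window_table[window_table["window"] == window].dropna(subset=["omega2"])
    groups = {}
    for load, g in sub.groupby("load"):
        vals = g["omega2"].to_numpy(dtype=float)
        if vals.size < 2:
            warnings.warn(f"load {load} has <2 neurons; excluded from ANOVA")
            continue
        groups[int(load)] = vals
    if len(groups) < 2:
        raise DomainError("need at least two loads with >= 2 neurons")
    loads = tuple(sorted(groups))
    values = np.concatenate([groups[l] for l in loads])
    labels = np.concatenate([np.full(groups[l].size, l) for l in loads])
    dec = omega_squared(values, labels)
    df_b = dec.df_effect
    df_w = values.size - len(loads)
    ms_between = dec.ss_effect / df_b
    if dec.ms_error == 0:
        f = 0.0 if dec.ss_effect == 0 else np.inf
    else:
        f = ms_between / dec.ms_error
    p = float(stats.f.sf(f, df_b, df_w)) if np.isfinite(f) else 0.0
    m = len(loads) * (len(loads) - 1) // 2
    pairwise = {}
    for i, a in enumerate(loads):
        for b in loads[i + 1:]:
            if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0:
                praw = 1.0 if groups[a].mean() == groups[b].mean() else 0.0
            else:
                praw = float(stats.ttest_ind(groups[a], groups[b]).pvalue)
            pairwise[(a, b)] = min(1.0, m * praw)
    return LoadAnova(
        f=float(f), df_between=df_b, df_within=df_w, p=p,
        omega_squared=dec.omega_squared, pairwise_p=pairwise, loads=loads,
    )


def above_zero_test(values) -> tuple[float, int, float]:
    """One-sample t-test of the mean against zero: (t, df, p).

    Constant nonzero samples have zero variance; they are flagged with an
    infinite t (p = 0) rather than raising.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DomainError("need at least two values")
    df = values.size - 1
    if np.ptp(values) == 0:
        if values[0] == 0:
            return 0.0, df, 1.0
        return float(np.sign(values[0]) * np.inf), df, 0.0
    res = stats.ttest_1samp(values, 0.0)
    return float(res.statistic), df, float(res.pvalue)


# ---------------------------------------------------------------------------
# Correct-trial subsampling against error trials

@dataclass
class SubsampleResult:
    """Per-neuron subsampled correct PEV versus error PEV, paired t-test."""

    neuron_ids: list[int]
    correct_subsampled: np.ndarray
    error_omega2: np.ndarray
    t: float
    df: int
    p: float
    cohens_d: float
    excluded: list[int]


def subsample_omega(correct_values, correct_groups, error_counts: dict,
                    n_rep: int = 1000, seed: int = 0) -> float:
    """Average omega^2 of correct trials subsampled to the error counts.

    Each repetition draws, per color label and without replacement, as many
    correct trials as there are error trials of that label, computes the
    one-way omega^2, and the repetitions are averaged.
    """
    correct_values = np.asarray(correct_values, dtype=float)
    correct_groups = np.asarray(correct_groups)
    rng = np.random.default_rng(seed)
    idx_by_label = {
        lab: np.flatnonzero(correct_groups == lab)
        for lab in np.unique(correct_groups)
    }
    for lab, k in error_counts.items():
        if lab not in idx_by_label or k > idx_by_label[lab].size:
            raise DomainError(
                f"cannot subsample {k} correct trials of label {lab!r}"
            )
    vals = []
    for _ in range(n_rep):
        take = np.concatenate([
            rng.choice(idx_by_label[lab], size=k, replace=False)
            for lab, k in sorted(error_counts.items())
        ])
        om = omega_squared(
            correct_values[take], correct_groups[take]
        ).omega_squared
        if np.isfinite(om):
            vals.append(om)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def subsample_correct(per_neuron: dict, n_rep: int = 1000, seed: int = 0,
                      min_errors_per_color: int = 2) -> SubsampleResult:
    """Compare correct-trial information to error-trial information.

    ``per_neuron`` maps neuron_id to a 4-tuple
    (correct_values, correct_groups, error_values, error_groups) of spike
    counts and color labels.  For each neuron the correct trials are
    subsampled to the error-trial counts ``n_rep`` times and averaged; the
    paired (dependent) t-test then compares the per-neuron averages to the
    per-neuron error omega^2.  Neurons with fewer than
    ``min_errors_per_color`` error trials of any color, or with more error
    than correct trials of a color, are excluded and reported.
    """
    ids, subs, errs, excluded = [], [], [], []
    for j, (nid, (cv, cg, ev, eg)) in enumerate(sorted(per_neuron.items())):
        ev = np.asarray(ev, dtype=float)
        eg = np.asarray(eg)
        cg = np.asarray(cg)
        labels = np.unique(np.concatenate([np.unique(cg), np.unique(eg)]))
        counts = {lab: int(np.sum(eg == lab)) for lab in labels}
        ok = all(
            counts[lab] >= min_errors_per_color
            and counts[lab] <= int(np.sum(cg == lab))
            for lab in labels
        )
        if not ok or labels.size < 2:
            excluded.append(nid)
            continue
        err_om = omega_squared(ev, eg).omega_squared
        sub_om = subsample_omega(
            cv, cg, counts, n_rep=n_rep,
            seed=int(np.random.SeedSequence([seed, j]).generate_state(1)[0]),
        )
        if not (np.isfinite(err_om) and np.isfinite(sub_om)):
            excluded.append(nid)
            continue
        ids.append(nid)
        subs.append(sub_om)
        errs.append(err_om)
    if len(ids) < 2:
        raise DomainError("need at least two neurons with usable error trials")
    subs_arr = np.array(subs)
    errs_arr = np.array(errs)
    diff = subs_arr - errs_arr
    res = stats.ttest_rel(subs_arr, errs_arr)
    d = float(diff.mean() / diff.std(ddof=1)) if diff.std(ddof=1) > 0 else 0.0
    return SubsampleResult(
        neuron_ids=ids,
        correct_subsampled=subs_arr,
        error_omega2=errs_arr,
        t=float(res.statistic),
        df=len(ids) - 1,
        p=float(res.pvalue),
        cohens_d=d,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Hierarchical clustering of PEV timecourses

@dataclass
class ClusterResult:
    """Agglomerative clustering of z-normalized PEV traces."""

    neuron_ids: list[int]
    traces: np.ndarray  # z-normalized, rows align with neuron_ids
    linkage: np.ndarray
    labels: np.ndarray
    k: int
    wcss: dict[int, float]
    cluster_order: list[int]
    excluded: list[int]


def _zscore_rows(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return (x - mu) / sd


def within_cluster_ss(traces: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        sub = traces[labels == lab]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def cluster_timecourses(traces: np.ndarray, neuron_ids=None, k: int = 7,
                        k_max: int = 10) -> ClusterResult:
    """Cluster per-neuron PEV traces by response shape.

    Traces are z-normalized per neuron (inert under the correlation
    distance, but it makes the stored traces comparable), distances are
    1 - Pearson correlation, linkage is average (UPGMA).  The within-
    cluster sum-of-squares is reported for k = 1..k_max so the elbow can
    be inspected; the cut defaults to seven clusters.  Clusters are
    numbered 1..k and ordered by dendrogram leaf order, which minimizes
    the average distance between adjacent clusters.  Constant traces have
    undefined correlation and are excluded with a warning.
    """
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2:
        raise DomainError("traces must be a 2-D array (neurons x bins)")
    if neuron_ids is None:
        neuron_ids = list(range(traces.shape[0]))
    neuron_ids = list(neuron_ids)
    keep = []
    excluded = []
    for i in range(traces.shape[0]):
        row = traces[i]
        if not np.all(np.isfinite(row)) or np.ptp(row) == 0:
            excluded.append(neuron_ids[i])
        else:
            keep.append(i)
    if excluded:
        warnings.warn(
            f"{len(excluded)} constant or non-finite traces excluded from "
            "clustering"
        )
    if len(keep) < k:
        raise DomainError(f"need at least k={k} usable traces")
    ids = [neuron_ids[i] for i in keep]
    z = _zscore_rows(traces[keep])
    dist = pdist(z, metric="correlation")
    Z = linkage(dist, method="average")
    labels_raw = fcluster(Z, t=k, criterion="maxclust")
    wcss = {}
    for kk in range(1, k_max + 1):
        lab_k = fcluster(Z, t=kk, criterion="maxclust")
        wcss[kk] = within_cluster_ss(z, lab_k)
    # renumber clusters by leaf order so adjacent clusters are most similar
    leaf_order = leaves_list(Z)
    seen: list[int] = []
    for leaf in leaf_order:
        c = int(labels_raw[leaf])
        if c not in seen:
            seen.append(c)
    remap = {old: new + 1 for new, old in enumerate(seen)}
    labels = np.array([remap[int(c)] for c in labels_raw])
    return ClusterResult(
        neuron_ids=ids,
        traces=z,
        linkage=Z,
        labels=labels,
        k=k,
        wcss=wcss,
        cluster_order=list(range(1, len(seen) + 1)),
        excluded=excluded,
    )
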