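"""Color-identity information in spike counts: omega-squared PEV,
permutation significance, favorite-location selection, and neuron
classification by load.

The information measure is the percent explained variance (PEV) from a
one-way decomposition of spike counts by color identity,

    omega^2 = (SS_effect - df_effect * MS_error) / (SS_total + MS_error),

an (nearly) unbiased effect size that can go negative when the effect is
absent.  Significance per bin comes from a label-permutation test (1000
permutations by default, criterion p < 0.05, no multiple-comparison
correction across bins; a stricter two-consecutive-bins criterion is
available).  Neurons are classified by which ipsilateral loads (1-3) show
significant information in the sample and delay phases, yielding seven
groups and three pooled (per-load) groups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .task import (
    BIN_WIDTH_S,
    DELAY_S,
    SAMPLE_S,
    DomainError,
    SpikeTable,
    TrialRecord,
    as_trial_list,
    hemifield,
    hemifield_locations,
)

ALPHA = 0.05
N_PERM_DEFAULT = 1000

#: Truth table mapping (sig at load 1, 2, 3) to group labels.
GROUP_TABLE: dict[tuple[bool, bool, bool], str] = {
    (True, False, False): "I",
    (False, True, False): "II",
    (False, False, True): "III",
    (True, True, False): "IV",
    (True, False, True): "V",
    (False, True, True): "VI",
    (True, True, True): "VII",
}


# ---------------------------------------------------------------------------
# Binning

@dataclass
class BinnedCounts:
    """Spike counts per (neuron, trial, bin) over half-open bins."""

    neuron_ids: list[int]
    trial_ids: list[int]
    edges: np.ndarray
    counts: np.ndarray  # shape (n_neurons, n_trials, n_bins)


def analysis_bin_edges(bin_width: float = BIN_WIDTH_S,
                       sample_s: float = SAMPLE_S,
                       delay_s: float = DELAY_S) -> np.ndarray:
    """Non-overlapping bin edges spanning sample then delay from t=0."""
    for name, dur in (("sample", sample_s), ("delay", delay_s)):
        k = dur / bin_width
        if abs(k - round(k)) > 1e-9:
            raise DomainError(
                f"bin width {bin_width} s does not divide the {name} "
                f"duration {dur} s (partial bins are not allowed)"
            )
    n = round((sample_s + delay_s) / bin_width)
    return np.linspace(0.0, sample_s + delay_s, n + 1)


def n_sample_bins(bin_width: float = BIN_WIDTH_S,
                  sample_s: float = SAMPLE_S) -> int:
    return round(sample_s / bin_width)


def bin_spikes(spikes: SpikeTable, trials, bin_width: float = BIN_WIDTH_S
               ) -> BinnedCounts:
    """Count spikes of every neuron on every trial in 200-ms default bins."""
    trials = as_trial_list(trials)
    edges = analysis_bin_edges(bin_width)
    trial_ids = [t.trial_id for t in trials]
    counts = np.stack([
        spikes.binned(nid, trial_ids, edges) for nid in spikes.neuron_ids
    ]) if spikes.neuron_ids else np.zeros((0, len(trial_ids), len(edges) - 1))
    return BinnedCounts(list(spikes.neuron_ids), trial_ids, edges, counts)


# ---------------------------------------------------------------------------
# omega-squared PEV

@dataclass
class AnovaDecomposition:
    """One-way sums of squares and the omega-squared effect size."""

    ss_effect: float
    ss_total: float
    ms_error: float
    df_effect: int
    omega_squared: float
    group_sizes: tuple[int, ...]

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.omega_squared)


def _group_arrays(values, groups) -> tuple[np.ndarray, list[np.ndarray]]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise DomainError("values and groups must have the same length")
    labels = np.unique(groups)
    if labels.size < 2:
        raise DomainError("need at least two groups")
    parts = [values[groups == g] for g in labels]
    if any(p.size < 2 for p in parts):
        raise DomainError("every group needs at least two observations")
    return values, parts


def omega_squared(values, groups) -> AnovaDecomposition:
    """Exact one-way omega-squared decomposition of ``values`` by ``groups``.

    Constant data (zero total variance) yields an undefined effect size,
    flagged as NaN rather than raising.
    """
    values, parts = _group_arrays(values, groups)
    grand = values.mean()
    ss_effect = sum(p.size * (p.mean() - grand) ** 2 for p in parts)
    ss_within = sum(((p - p.mean()) ** 2).sum() for p in parts)
    ss_total = ss_effect + ss_within
    df_effect = len(parts) - 1
    df_within = values.size - len(parts)
    ms_error = ss_within / df_within
    if ss_total <= 0:
        om = np.nan
    else:
        om = (ss_effect - df_effect * ms_error) / (ss_total + ms_error)
    return AnovaDecomposition(
        ss_effect=float(ss_effect),
        ss_total=float(ss_total),
        ms_error=float(ms_error),
        df_effect=df_effect,
        omega_squared=float(om),
        group_sizes=tuple(p.size for p in parts),
    )


def _omega_many(values: np.ndarray, perm_index: np.ndarray,
                sizes: np.ndarray) -> np.ndarray:
    """omega^2 for many label permutations at once.

    ``perm_index`` has shape (P, n); row p permutes ``values``, and the
    first sizes[0] columns form group 1, the next sizes[1] group 2, etc.
    """
    n = values.size
    k = sizes.size
    vp = values[perm_index]  # (P, n)
    total = values.sum()
    c = total * total / n
    ss_all = float((values ** 2).sum()) - c
    starts = np.concatenate([[0], np.cumsum(sizes)])
    ss_eff = np.full(perm_index.shape[0], -c)
    for g in range(k):
        s = vp[:, starts[g]:starts[g + 1]].sum(axis=1)
        ss_eff += s * s / sizes[g]
    ss_within = ss_all - ss_eff
    ms_error = ss_within / (n - k)
    return (ss_eff - (k - 1) * ms_error) / (ss_all + ms_error)


def permutation_pev_test(values, groups, n_perm: int = N_PERM_DEFAULT,
                         seed: int = 0) -> float:
    """Permutation p-value for omega-squared exceeding chance.

    p = (1 + #{permuted omega^2 >= observed}) / (n_perm + 1); ties count
    against significance.  Constant data returns p = 1 (every relabeling
    ties the observed value).
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    values, parts = _group_arrays(values, groups)
    if np.ptp(values) == 0:
        return 1.0
    observed = omega_squared(values, groups).omega_squared
    sizes = np.array([p.size for p in parts])
    order = np.concatenate(parts)  # values reordered by group blocks
    rng = np.random.default_rng(seed)
    perm_index = rng.permuted(
        np.tile(np.arange(order.size), (n_perm, 1)), axis=1
    )
    perms = _omega_many(order, perm_index, sizes)
    exceed = int(np.sum(perms >= observed - 1e-12))
    return (1 + exceed) / (n_perm + 1)


# ---------------------------------------------------------------------------
# Trial selection relative to a neuron's favorite location

def select_load_trials(trials: list[TrialRecord], favorite_location: int,
                       load: int, axis: str = "ipsi",
                       outcomes: tuple[str, ...] = ("correct",),
                       fixed_ipsi: int = 1) -> list[TrialRecord]:
    """Trials entering a load-``load`` condition for one neuron.

    ``axis='ipsi'``: the favorite location is displayed and its hemifield
    holds exactly ``load`` items (contra load pooled).  ``axis='contra'``:
    the favorite location is displayed with ipsilateral load held at
    ``fixed_ipsi`` while the opposite hemifield holds ``load`` items.
    """
    side = hemifield(favorite_location)
    other = "right" if side == "left" else "left"
    out = []
    for t in trials:
        if outcomes and (t.outcome not in outcomes):
            continue
        if favorite_location not in t.colors_shown:
            continue
        if axis == "ipsi":
            if t.load(side) == load:
                out.append(t)
        elif axis == "contra":
            if t.load(side) == fixed_ipsi and t.load(other) == load:
                out.append(t)
        else:
            raise DomainError(f"unknown axis {axis!r}")
    return out


def color_labels(trials: list[TrialRecord], location: int) -> np.ndarray:
    return np.array([t.colors_shown[location] for t in trials])


# ---------------------------------------------------------------------------
# Favorite location

def favorite_location(spikes: SpikeTable, trials, neuron_id: int,
                      candidates: tuple[int, ...] = hemifield_locations("right"),
                      bin_width: float = BIN_WIDTH_S) -> int:
    """Location with the highest cumulative sample-phase PEV.

    For each candidate location, load-1 trials of its hemifield (the
    candidate displayed alone on its side) are grouped by the candidate's
    color, omega^2 is computed in each of the non-overlapping sample bins
    (four 200-ms bins for the default timing), and the candidate with the
    largest sum wins; exact ties break toward the lowest location index.
    """
    trials = as_trial_list(trials)
    n_bins = n_sample_bins(bin_width)
    edges = np.linspace(0.0, SAMPLE_S, n_bins + 1)
    best: tuple[float, int] | None = None
    any_candidate = False
    for loc in candidates:
        sel = select_load_trials(trials, loc, load=1, axis="ipsi")
        if not sel:
            continue
        labels = color_labels(sel, loc)
        if np.unique(labels).size < 2:
            continue
        counts = spikes.binned(neuron_id, [t.trial_id for t in sel], edges)
        if min(np.sum(labels == g) for g in np.unique(labels)) < 2:
            continue
        any_candidate = True
        cum = 0.0
        for b in range(n_bins):
            om = omega_squared(counts[:, b], labels).omega_squared
            if np.isfinite(om):
                cum += om
        if best is None or cum > best[0] + 1e-12:
            best = (cum, loc)
    if not any_candidate or best is None:
        raise DomainError(
            f"neuron {neuron_id}: no candidate location has usable load-1 trials"
        )
    return best[1]


# ---------------------------------------------------------------------------
# Timecourses and classification

@dataclass
class PevTimecourse:
    """Per-bin omega-squared and permutation significance for one neuron
    at one load condition."""

    neuron_id: int
    load: int
    axis: str  # 'ipsi' or 'contra'
    edges: np.ndarray
    omega2: np.ndarray
    p: np.ndarray
    n_trials: int

    @property
    def significant(self) -> np.ndarray:
        return self.p < ALPHA


def pev_timecourse(spikes: SpikeTable, trials, neuron_id: int,
                   favorite_loc: int, load: int, axis: str = "ipsi",
                   n_perm: int = N_PERM_DEFAULT, seed: int = 0,
                   bin_width: float = BIN_WIDTH_S) -> PevTimecourse:
    """omega^2 and permutation p per 200-ms bin across sample and delay.

    The permutation seed for each bin is derived from
    (seed, neuron_id, axis, load, bin), so results are reproducible and
    independent of evaluation order.
    """
    trials = as_trial_list(trials)
    sel = select_load_trials(trials, favorite_loc, load, axis=axis)
    edges = analysis_bin_edges(bin_width)
    n_bins = len(edges) - 1
    if not sel:
        return PevTimecourse(neuron_id, load, axis, edges,
                             np.full(n_bins, np.nan), np.ones(n_bins), 0)
    labels = color_labels(sel, favorite_loc)
    counts = spikes.binned(neuron_id, [t.trial_id for t in sel], edges)
    om = np.full(n_bins, np.nan)
    p = np.ones(n_bins)
    axis_code = 0 if axis == "ipsi" else 1
    for b in range(n_bins):
        vals = counts[:, b]
        om[b] = omega_squared(vals, labels).omega_squared
        bin_seed = np.random.SeedSequence(
            [seed, neuron_id, axis_code, load, b]
        ).generate_state(1)[0]
        p[b] = permutation_pev_test(vals, labels, n_perm=n_perm,
                                    seed=int(bin_seed))
    return PevTimecourse(neuron_id, load, axis, edges, om, p, len(sel))


def phase_flags(tc: PevTimecourse, bin_width: float = BIN_WIDTH_S,
                strict: bool = False) -> tuple[bool, bool]:
    """(sample significant, delay significant) for one timecourse.

    Default criterion: at least one significant bin in the phase.  Strict
    criterion: at least two consecutive significant bins.
    """
    ns = n_sample_bins(bin_width)
    sig = tc.significant
    def crit(flags: np.ndarray) -> bool:
        if not strict:
            return bool(flags.any())
        return bool(np.any(flags[1:] & flags[:-1]))
    return crit(sig[:ns]), crit(sig[ns:])


@dataclass
class NeuronClassification:
    """Significance profile of one neuron across ipsilateral loads.

    ``sample_sig``/``delay_sig`` map load (1-3) to a significance flag, or
    None when the load condition was unavailable.  Group labels follow the
    seven-group truth table; a neuron with no significant load has group
    None.  Pooled group g (1-3) contains the neurons significant at load g.
    """

    neuron_id: int
    favorite_location: int
    sample_sig: dict[int, bool | None]
    delay_sig: dict[int, bool | None]

    def group(self, phase: str) -> str | None:
        flags = self.sample_sig if phase == "sample" else self.delay_sig
        triple = tuple(bool(flags.get(g)) for g in (1, 2, 3))
        return GROUP_TABLE.get(triple)

    def pooled_groups(self, phase: str) -> set[int]:
        flags = self.sample_sig if phase == "sample" else self.delay_sig
        return {g for g in (1, 2, 3) if flags.get(g)}

    @property
    def in_sample_population(self) -> bool:
        return bool(self.pooled_groups("sample"))

    @property
    def in_delay_population(self) -> bool:
        return bool(self.pooled_groups("delay"))


def classify_significance(neuron_id: int, favorite_loc: int,
                          timecourses: dict[int, PevTimecourse],
                          strict: bool = False,
                          bin_width: float = BIN_WIDTH_S
                          ) -> NeuronClassification:
    """Classify one neuron from its load-1/2/3 ipsilateral timecourses."""
    sample: dict[int, bool | None] = {}
    delay: dict[int, bool | None] = {}
    for load in (1, 2, 3):
        tc = timecourses.get(load)
        if tc is None or tc.n_trials == 0:
            sample[load] = None
            delay[load] = None
            continue
        s, d = phase_flags(tc, bin_width=bin_width, strict=strict)
        sample[load] = s
        delay[load] = d
    return NeuronClassification(neuron_id, favorite_loc, sample, delay)


def binomial_proportion_test(k: int, n: int, p0: float = ALPHA) -> float:
    """Exact binomial upper tail P(X >= k) for X ~ Binomial(n, p0).

    Used to ask whether ``k`` significant neurons out of ``n`` exceed the
    false-positive rate ``p0`` expected by chance.
    """
    if not (0 <= k <= n):
        raise DomainError("need 0 <= k <= n")
    if not (0 < p0 < 1):
        raise DomainError("p0 must lie strictly between 0 and 1")
    return float(stats.binom.sf(k - 1, n, p0))


# ---------------------------------------------------------------------------
# Whole-phase (single-bin) significance, used by the normalization analysis

def whole_phase_significance(spikes: SpikeTable, trials, neuron_id: int,
                             favorite_loc: int, phase: str, load: int,
                             n_perm: int = N_PERM_DEFAULT,
                             seed: int = 0) -> bool | None:
    """Permutation significance of color information over an entire phase.

    The sample (800 ms) or delay (1000 ms) is treated as a single bin.
    Returns None when the load condition has too few trials.
    """
    trials = as_trial_list(trials)
    window = (0.0, SAMPLE_S) if phase == "sample" else (SAMPLE_S, SAMPLE_S + DELAY_S)
    sel = select_load_trials(trials, favorite_loc, load, axis="ipsi")
    if not sel:
        return None
    labels = color_labels(sel, favorite_loc)
    if np.unique(labels).size < 2 or min(
        np.sum(labels == g) for g in np.unique(labels)
    ) < 2:
        return None
    vals = spikes.counts(neuron_id, [t.trial_id for t in sel], *window)
    phase_code = 0 if phase == "sample" else 1
    s = np.random.SeedSequence([seed, neuron_id, 5, phase_code, load]
                               ).generate_state(1)[0]
    p = permutation_pev_test(vals, labels, n_perm=n_perm, seed=int(s))
    return bool(p < ALPHA)
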