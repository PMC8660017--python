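"""Divisive-normalization analysis via selectivity and sensory-interaction
indices.

For each neuron three kinds of whole-phase conditions are measured at its
favorite location and the two other ipsilateral locations: the reference
color alone (REF_i), a probe color alone at another location (PROBE_j), and
both together (PAIR_ij).  After normalizing all condition means by the
neuron-phase maximum,

    SE_i   = PROBE_j - REF_i        (selectivity, in [-1, 1])
    SI_ij  = PAIR_ij - REF_i        (sensory interaction, in [-1, 1])

With two reference colors, two probe locations, and two probe colors there
are eight (SE, SI) pairs per neuron and phase.  Under weighted-mean divisive
normalization, PAIR = (w_ref*REF + w_probe*PROBE)/(w_ref + w_probe), so
SI = [w_probe/(w_ref + w_probe)] * SE: the pooled ordinary-least-squares
slope of SI on SE identifies the normalization weighting, with slope 0.5
meaning the reference and probe items contribute equally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .information import whole_phase_significance
from .task import (
    COLORS,
    DELAY_S,
    SAMPLE_S,
    DomainError,
    SpikeTable,
    as_trial_list,
    hemifield,
    hemifield_locations,
)

PHASES = ("sample", "delay")


def phase_window(phase: str) -> tuple[float, float]:
    if phase == "sample":
        return (0.0, SAMPLE_S)
    if phase == "delay":
        return (SAMPLE_S, SAMPLE_S + DELAY_S)
    raise DomainError(f"unknown phase {phase!r}")


@dataclass
class ConditionRates:
    """Whole-phase mean rates per stimulus condition for one neuron.

    ``raw`` maps condition keys to (mean rate Hz, n_trials); ``normalized``
    divides every mean by the maximum condition mean, so normalized rates
    lie in [0, 1] with the maximum at exactly 1.  Keys:
    ("REF", i), ("PROBE", loc, c), and ("PAIR", i, loc, c).
    """

    neuron_id: int
    phase: str
    favorite_location: int
    probe_locations: tuple[int, int]
    raw: dict[tuple, tuple[float, int]]
    normalized: dict[tuple, float]


def condition_rates(spikes: SpikeTable, trials, neuron_id: int,
                    favorite_loc: int, phase: str,
                    outcomes: tuple[str, ...] = ("correct",),
                    normalize: str = "max") -> ConditionRates:
    """Measure REF/PROBE/PAIR condition rates for one neuron and phase.

    REF_i: load-1 ipsilateral trials with color i at the favorite location.
    PROBE_(j,c): load-1 ipsilateral trials with the single item at probe
    location j showing color c.  PAIR_(i,j,c): load-2 ipsilateral trials
    displaying exactly the favorite location (color i) and probe location j
    (color c).  Contralateral items are ignored throughout (hemifield
    independence).  Conditions without trials are simply absent from the
    maps.  Normalization: 'max' divides by the largest condition mean
    (guaranteeing indices in [-1, 1]); 'minmax' additionally subtracts the
    smallest mean first.
    """
    trials = as_trial_list(trials)
    t0, t1 = phase_window(phase)
    dur = t1 - t0
    side = hemifield(favorite_loc)
    probe_locs = tuple(
        loc for loc in hemifield_locations(side) if loc != favorite_loc
    )
    sums: dict[tuple, list[int]] = {}
    for t in trials:
        if outcomes and t.outcome not in outcomes:
            continue
        ipsi_items = {
            loc: col for loc, col in t.colors_shown.items()
            if hemifield(loc) == side
        }
        key: tuple | None = None
        if len(ipsi_items) == 1:
            (loc, col), = ipsi_items.items()
            if loc == favorite_loc:
                key = ("REF", col)
            else:
                key = ("PROBE", loc, col)
        elif len(ipsi_items) == 2 and favorite_loc in ipsi_items:
            probe_loc = next(l for l in ipsi_items if l != favorite_loc)
            key = ("PAIR", ipsi_items[favorite_loc], probe_loc,
                   ipsi_items[probe_loc])
        if key is None:
            continue
        sums.setdefault(key, []).append(
            spikes.count(neuron_id, t.trial_id, t0, t1)
        )
    raw = {
        key: (float(np.mean(counts)) / dur, len(counts))
        for key, counts in sums.items()
    }
    if not raw:
        raise DomainError(
            f"neuron {neuron_id}: no usable condition trials in {phase}"
        )
    means = np.array([m for m, _ in raw.values()])
    lo = means.min() if normalize == "minmax" else 0.0
    hi = means.max()
    if hi - lo <= 0:
        raise DomainError(
            f"neuron {neuron_id}: all condition rates equal "
            f"({hi:.3f} Hz); cannot normalize"
        )
    normalized = {key: (m - lo) / (hi - lo) for key, (m, _) in raw.items()}
    return ConditionRates(
        neuron_id=neuron_id,
        phase=phase,
        favorite_location=favorite_loc,
        probe_locations=probe_locs,  # type: ignore[arg-type]
        raw=raw,
        normalized=normalized,
    )


def se_index(ref: float, probe: float) -> float:
    """Selectivity index SE = PROBE - REF on normalized rates."""
    for v in (ref, probe):
        if not (0.0 <= v <= 1.0):
            raise DomainError("normalized rates must lie in [0, 1]")
    return probe - ref


def si_index(ref: float, pair: float) -> float:
    """Sensory-interaction index SI = PAIR - REF on normalized rates."""
    for v in (ref, pair):
        if not (0.0 <= v <= 1.0):
            raise DomainError("normalized rates must lie in [0, 1]")
    return pair - ref


@dataclass
class NormalizationIndexPair:
    """One (SE, SI) observation: a reference color against one probe."""

    neuron_id: int
    phase: str
    ref_color: str
    probe_location: int
    probe_color: str
    se: float
    si: float


def build_index_set(rates: ConditionRates) -> list[NormalizationIndexPair]:
    """All available (SE, SI) pairs for one neuron and phase.

    A complete design (every condition observed) yields exactly eight
    pairs: 2 reference colors x 2 probe locations x 2 probe colors.  Pairs
    whose REF, PROBE, or PAIR condition is missing are skipped.
    """
    out = []
    for i in COLORS:
        ref = rates.normalized.get(("REF", i))
        if ref is None:
            continue
        for loc in rates.probe_locations:
            for c in COLORS:
                probe = rates.normalized.get(("PROBE", loc, c))
                pair = rates.normalized.get(("PAIR", i, loc, c))
                if probe is None or pair is None:
                    continue
                out.append(
                    NormalizationIndexPair(
                        neuron_id=rates.neuron_id,
                        phase=rates.phase,
                        ref_color=i,
                        probe_location=loc,
                        probe_color=c,
                        se=se_index(ref, probe),
                        si=si_index(ref, pair),
                    )
                )
    return out


@dataclass
class SlopeFit:
    """Pooled OLS regression of SI on SE for a neuron group."""

    slope: float
    intercept: float
    r2_adj: float
    f: float
    df_model: int
    df_resid: int
    p: float
    ci_low: float
    ci_high: float
    n: int
    group: str = ""

    @property
    def consistent_with_half(self) -> bool:
        """True when the 95% CI for the slope contains 0.5."""
        return self.ci_low <= 0.5 <= self.ci_high

    @property
    def below_half(self) -> bool:
        """True when the entire 95% CI lies below 0.5."""
        return self.ci_high < 0.5


def fit_se_si_regression(pairs: list[NormalizationIndexPair],
                         group: str = "") -> SlopeFit:
    """Ordinary least squares of SI on SE over pooled index pairs."""
    if len(pairs) < 3:
        raise DomainError("need at least three index pairs")
    se = np.array([p.se for p in pairs])
    si = np.array([p.si for p in pairs])
    if np.ptp(se) == 0:
        raise DomainError("SE has zero variance; slope is unidentifiable")
    res = sm.OLS(si, sm.add_constant(se)).fit()
    ci = res.conf_int(alpha=0.05)
    fval = float(res.fvalue) if np.isfinite(res.fvalue) else np.inf
    return SlopeFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        f=fval,
        df_model=int(res.df_model),
        df_resid=int(res.df_resid),
        p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 0.0,
        ci_low=float(ci[1][0]),
        ci_high=float(ci[1][1]),
        n=len(pairs),
        group=group,
    )


DNR_GROUPS = ("information-carrying", "information-gaining", "non-informative")


def group_neurons_for_dnr(spikes: SpikeTable, trials,
                          neurons: dict[int, int], phase: str,
                          n_perm: int = 1000, seed: int = 0
                          ) -> dict[str, list[int]]:
    """Partition neurons by whole-phase information at loads 1 and 2.

    information-carrying: significant color information at load 1;
    information-gaining: not at load 1 but significant at load 2;
    non-informative: at neither.  Significance uses the permutation test
    with the entire phase as a single bin.  Groups are disjoint.
    """
    trials = as_trial_list(trials)
    out: dict[str, list[int]] = {g: [] for g in DNR_GROUPS}
    for nid, fav in sorted(neurons.items()):
        sig1 = whole_phase_significance(
            spikes, trials, nid, fav, phase, load=1, n_perm=n_perm, seed=seed
        )
        if sig1:
            out["information-carrying"].append(nid)
            continue
        sig2 = whole_phase_significance(
            spikes, trials, nid, fav, phase, load=2, n_perm=n_perm, seed=seed
        )
        if sig2:
            out["information-gaining"].append(nid)
        elif sig1 is not None or sig2 is not None:
            out["non-informative"].append(nid)
    return out


def dnr_analysis(spikes: SpikeTable, trials, neurons: dict[int, int],
                 phase: str, n_perm: int = 1000, seed: int = 0
                 ) -> dict[str, SlopeFit | None]:
    """Grouped SE/SI regressions for one phase.

    Returns one pooled SlopeFit per DNR group (None where a group has too
    few index pairs or degenerate SE variance).
    """
    groups = group_neurons_for_dnr(
        spikes, trials, neurons, phase, n_perm=n_perm, seed=seed
    )
    fits: dict[str, SlopeFit | None] = {}
    for gname, nids in groups.items():
        pairs: list[NormalizationIndexPair] = []
        for nid in nids:
            try:
                rates = condition_rates(
                    spikes, trials, nid, neurons[nid], phase
                )
            except DomainError:
                continue
            pairs.extend(build_index_set(rates))
        try:
            fits[gname] = fit_se_si_regression(pairs, group=gname)
        except DomainError:
            fits[gname] = None
    return fits
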