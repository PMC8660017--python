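"""Synthetic task and spike-train generator.

Generates balanced change-localization trials, load-dependent behavioral
outcomes, and Poisson spike trains whose rates follow a weighted divisive
normalization of the single-item responses within a neuron's favorite
hemifield:

    r_display = sum_j w_j * r_j / sum_j w_j

with weight ``w_ref`` on the item at the neuron's favorite location and
``w_probe`` on the other ipsilateral items.  Equal weights make the display
rate the arithmetic mean of the single-item rates, which at the population
level produces a sensory-interaction (SI) versus selectivity (SE) slope of
exactly ``w_probe / (w_ref + w_probe)`` = 0.5; reference-biased weights
lower that slope.  Contralateral items never enter the rate law (hemifield
independence).

All randomness flows from explicit integer seeds; per-neuron streams are
derived from a master seed by fixed offsets, so results do not depend on
iteration order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .task import (
    BIN_WIDTH_S,
    CHOICE_S,
    COLORS,
    DELAY_S,
    FIXATION_S,
    SAMPLE_S,
    ConfigurationError,
    SpikeTrain,
    TrialRecord,
    hemifield,
    hemifield_locations,
)

#: All load combinations (n_left, n_right) allowed by the 2-5 item design.
VALID_LOAD_COMBOS: tuple[tuple[int, int], ...] = tuple(
    (l, r)
    for l in (1, 2, 3)
    for r in (1, 2, 3)
    if 2 <= l + r <= 5
)

# Per-ipsilateral-load correct probabilities used as generator defaults.
# These are the observed median performances of the study conditions the
# generator emulates (load 1 through 3 in the changing hemifield).
DEFAULT_P_CORRECT: tuple[float, float, float] = (0.9588, 0.7831, 0.5821)


@dataclass
class GenerativeConfig:
    """All simulator parameters.

    Rates are in Hz.  ``tuning_gain`` is the firing-rate difference between
    color A and color B at a selective neuron's favorite location.
    ``w_ref``/``w_probe`` are the normalization weights of the favorite-
    location item and of other ipsilateral items.  ``p_correct`` gives the
    probability of a correct response at ipsilateral loads 1-3;
    ``interaction`` optionally couples ipsi and contra load
    (p += interaction * (ipsi-1) * (contra-1), clipped to [0, 1]).
    """

    n_sessions: int = 10
    trials_per_session: int = 480
    baseline_rate: float = 5.0
    tuning_gain: float = 8.0
    probe_rate: float = 5.0
    w_ref: float = 1.0
    w_probe: float = 1.0
    p_correct: tuple[float, float, float] = DEFAULT_P_CORRECT
    interaction: float = 0.0
    fixation_s: float = FIXATION_S
    sample_s: float = SAMPLE_S
    delay_s: float = DELAY_S
    choice_s: float = CHOICE_S
    #: post-delay window in which baseline spikes are synthesized
    choice_spike_window_s: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise ConfigurationError("need at least one session and one trial")
        for name in ("baseline_rate", "tuning_gain", "probe_rate"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.w_ref < 0 or self.w_probe < 0 or self.w_ref + self.w_probe <= 0:
            raise ConfigurationError(
                "normalization weights must be nonnegative with positive sum"
            )
        for d in (self.fixation_s, self.sample_s, self.delay_s, self.choice_s):
            if d <= 0:
                raise ConfigurationError("epoch durations must be positive")
        n_bins = self.sample_s / BIN_WIDTH_S
        if abs(n_bins - round(n_bins)) > 1e-9:
            raise ConfigurationError(
                f"sample duration {self.sample_s} s is not a multiple of the "
                f"{BIN_WIDTH_S} s analysis bin"
            )
        if len(self.p_correct) != 3:
            raise ConfigurationError("p_correct needs one entry per ipsi load 1-3")
        for load, p in enumerate(self.p_correct, start=1):
            # chance performance at the smallest array containing `load`
            # ipsilateral items is 1/(load+1) under random guessing
            chance = 1.0 / (load + 1)
            if not (chance <= p <= 1.0):
                raise ConfigurationError(
                    f"p_correct[{load}] = {p} outside [chance={chance:.3f}, 1]"
                )


@dataclass
class NeuronSpec:
    """Single-neuron generative parameters.

    ``rate_a``/``rate_b`` are the single-item rates for colors A/B at the
    favorite location; ``probe_rate_a``/``probe_rate_b`` the single-item
    rates for items at the other ipsilateral locations.  ``pair_weights``,
    when given, overrides the probe weight as a function of (reference
    color, probe color): equal single-item rates combined with
    color-dependent pair weights produce neurons whose color selectivity
    appears only at load 2 ("information-gaining").  ``delay_tuned`` keeps
    the normalized display rate through the memory delay; otherwise the
    delay reverts to baseline.
    """

    neuron_id: int
    favorite_location: int
    rate_a: float
    rate_b: float
    probe_rate_a: float
    probe_rate_b: float
    baseline_rate: float = 5.0
    w_ref: float = 1.0
    w_probe: float = 1.0
    pair_weights: dict[tuple[str, str], float] | None = None
    delay_tuned: bool = True

    def single_rate(self, location: int, color: str) -> float:
        if location == self.favorite_location:
            return self.rate_a if color == "A" else self.rate_b
        return self.probe_rate_a if color == "A" else self.probe_rate_b

    def display_rate(self, colors_shown: dict[int, str]) -> float:
        """Weight-normalized rate for one stimulus display (sample epoch)."""
        side = hemifield(self.favorite_location)
        items = [
            (loc, col)
            for loc, col in colors_shown.items()
            if hemifield(loc) == side
        ]
        if not items:
            return self.baseline_rate
        ref_color = colors_shown.get(self.favorite_location)
        num = 0.0
        den = 0.0
        for loc, col in items:
            if loc == self.favorite_location:
                w = self.w_ref
            elif self.pair_weights is not None and ref_color is not None:
                w = self.pair_weights[(ref_color, col)]
            else:
                w = self.w_probe
            num += w * self.single_rate(loc, col)
            den += w
        if den <= 0:
            return self.baseline_rate
        return num / den


def gen_trials(config: GenerativeConfig, n: int, seed: int,
               session_id: int = 0) -> list[TrialRecord]:
    """Generate ``n`` trials with balanced load combinations.

    Load combinations are cycled so each appears ``n // len(combos)`` or one
    more time; displayed locations, colors, and the target location are
    drawn uniformly.  Deterministic given (config, n, seed).
    """
    config.validate()
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng([seed, session_id])
    combos = list(
        itertools.islice(itertools.cycle(VALID_LOAD_COMBOS), n)
    )
    rng.shuffle(combos)
    trials = []
    for i, (nl, nr) in enumerate(combos):
        left = rng.choice(hemifield_locations("left"), size=nl, replace=False)
        right = rng.choice(hemifield_locations("right"), size=nr, replace=False)
        locs = sorted(int(x) for x in np.concatenate([left, right]))
        colors = {loc: COLORS[rng.integers(2)] for loc in locs}
        target = int(rng.choice(locs))
        trials.append(
            TrialRecord(
                trial_id=i,
                session_id=session_id,
                colors_shown=colors,
                target_location=target,
            )
        )
    return trials


def gen_behavior(trials: list[TrialRecord], config: GenerativeConfig,
                 seed: int) -> list[TrialRecord]:
    """Assign outcomes with correct-probability set by ipsilateral load.

    Errors are placed uniformly over the non-target displayed locations.
    Returns new records; input trials must not carry outcomes yet.
    """
    config.validate()
    rng = np.random.default_rng([seed, 7919])
    out = []
    for t in trials:
        if t.outcome is not None:
            raise ConfigurationError(
                f"trial {t.trial_id} already has an outcome"
            )
        ipsi = t.ipsi_load()
        contra = t.contra_load()
        p = config.p_correct[ipsi - 1] + config.interaction * (ipsi - 1) * (contra - 1)
        p = float(np.clip(p, 0.0, 1.0))
        if rng.random() < p:
            out.append(replace(t, response_location=t.target_location,
                               outcome="correct"))
        else:
            others = [loc for loc in t.colors_shown if loc != t.target_location]
            resp = int(rng.choice(others))
            out.append(replace(t, response_location=resp, outcome="error"))
    return out


def _epoch_spikes(rng: np.random.Generator, rate: float,
                  t0: float, t1: float) -> np.ndarray:
    n = rng.poisson(rate * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def gen_spikes(trials: list[TrialRecord], neurons: list[NeuronSpec],
               config: GenerativeConfig, seed: int) -> list[SpikeTrain]:
    """Poisson spike trains per (neuron, trial).

    Piecewise-homogeneous Poisson process: baseline rate during fixation and
    a short post-delay window, the weight-normalized display rate during the
    sample (and during the delay for delay-tuned neurons).  Each neuron uses
    an independent stream derived from (seed, neuron_id), so adding neurons
    never perturbs existing ones.
    """
    config.validate()
    t_sample_end = config.sample_s
    t_delay_end = config.sample_s + config.delay_s
    t_post_end = t_delay_end + config.choice_spike_window_s
    trains = []
    for nrn in neurons:
        rng = np.random.default_rng([seed, 104729, nrn.neuron_id])
        for t in trials:
            disp = nrn.display_rate(t.colors_shown)
            delay_rate = disp if nrn.delay_tuned else nrn.baseline_rate
            ts = np.concatenate([
                _epoch_spikes(rng, nrn.baseline_rate, -config.fixation_s, 0.0),
                _epoch_spikes(rng, disp, 0.0, t_sample_end),
                _epoch_spikes(rng, delay_rate, t_sample_end, t_delay_end),
                _epoch_spikes(rng, nrn.baseline_rate, t_delay_end, t_post_end),
            ])
            trains.append(SpikeTrain(nrn.neuron_id, t.trial_id, ts))
    return trains


def make_neurons(config: GenerativeConfig, n_neurons: int,
                 kind: str = "carrying", seed: int = 0,
                 hemifield_side: str = "right",
                 delay_tuned: bool = True,
                 first_id: int = 0) -> list[NeuronSpec]:
    """Build a homogeneous population of generative neurons.

    kinds:
      ``carrying``  -- color-selective at the favorite location
                       (rate_a - rate_b = tuning_gain): informative at load 1.
      ``gaining``   -- equal single-item rates but reference-color-dependent
                       pair weights: selectivity emerges only at load 2.
      ``nonselective`` -- equal rates, plain weights: never informative.

    Favorite locations cycle through the requested hemifield.
    """
    config.validate()
    locs = hemifield_locations(hemifield_side)
    rng = np.random.default_rng([seed, 7717, first_id])
    out = []
    for i in range(n_neurons):
        nid = first_id + i
        fav = locs[i % len(locs)]
        common = dict(
            neuron_id=nid,
            favorite_location=fav,
            baseline_rate=config.baseline_rate,
            w_ref=config.w_ref,
            w_probe=config.w_probe,
            delay_tuned=delay_tuned,
        )
        # per-neuron heterogeneity of the non-reference rates: real
        # populations never share a single probe response, and the SE/SI
        # regression needs selectivity spread across index pairs
        jitter = lambda lo=0.3, hi=1.7: float(rng.uniform(lo, hi))
        if kind == "carrying":
            spec = NeuronSpec(
                rate_a=config.baseline_rate + config.tuning_gain,
                rate_b=config.baseline_rate,
                probe_rate_a=config.probe_rate * jitter(),
                probe_rate_b=config.probe_rate * jitter(),
                **common,
            )
        elif kind == "gaining":
            # equal single-item responses; the reference color only matters
            # through how strongly the probe item is weighted into the pair
            r0 = config.baseline_rate + config.tuning_gain
            spec = NeuronSpec(
                rate_a=r0,
                rate_b=r0,
                probe_rate_a=config.baseline_rate * jitter(0.2, 1.0),
                probe_rate_b=config.baseline_rate * jitter(0.2, 1.0),
                **{**common, "pair_weights": {
                    ("A", "A"): 1.0, ("A", "B"): 1.0,
                    ("B", "A"): 0.05, ("B", "B"): 0.05,
                }},
            )
        elif kind == "nonselective":
            spec = NeuronSpec(
                rate_a=config.baseline_rate,
                rate_b=config.baseline_rate,
                probe_rate_a=config.baseline_rate,
                probe_rate_b=config.baseline_rate,
                **common,
            )
        else:
            raise ConfigurationError(f"unknown neuron kind {kind!r}")
        out.append(spec)
    return out


def simulate_index_pairs(n_neurons: int, w_ref: float = 1.0,
                         w_probe: float = 1.0,
                         n_trials: int | None = 30,
                         duration: float = SAMPLE_S, seed: int = 0,
                         rate_range: tuple[float, float] = (2.0, 20.0),
                         probe_locations: tuple[int, int] = (5, 6),
                         favorite_location: int = 4):
    """Condition-level simulation of the SE/SI index design.

    For each neuron, single-item rates for the reference colors and the
    four probe conditions are drawn uniformly from ``rate_range``; each
    pair-display rate is the weighted mean
    (w_ref*REF + w_probe*PROBE)/(w_ref + w_probe).  Condition means are
    estimated from Poisson spike counts over ``n_trials`` trials of
    ``duration`` seconds (or taken as the exact rates when ``n_trials`` is
    None), max-normalized, and expanded into the 8 (SE, SI) pairs per
    neuron.  With exact rates the pooled SI-on-SE slope equals
    w_probe/(w_ref + w_probe) identically.
    """
    from .normalization import ConditionRates, build_index_set

    if w_ref < 0 or w_probe < 0 or w_ref + w_probe <= 0:
        raise ConfigurationError(
            "normalization weights must be nonnegative with positive sum"
        )
    rng = np.random.default_rng([seed, 9973])
    pairs = []
    for nid in range(n_neurons):
        true: dict[tuple, float] = {}
        for c in COLORS:
            true[("REF", c)] = rng.uniform(*rate_range)
        for loc in probe_locations:
            for c in COLORS:
                true[("PROBE", loc, c)] = rng.uniform(*rate_range)
        for i in COLORS:
            for loc in probe_locations:
                for c in COLORS:
                    true[("PAIR", i, loc, c)] = (
                        w_ref * true[("REF", i)]
                        + w_probe * true[("PROBE", loc, c)]
                    ) / (w_ref + w_probe)
        if n_trials is None:
            meas = dict(true)
            n_obs = 0
        else:
            meas = {
                key: rng.poisson(r * duration, size=n_trials).mean() / duration
                for key, r in true.items()
            }
            n_obs = n_trials
        hi = max(meas.values())
        if hi <= 0:
            continue
        rates = ConditionRates(
            neuron_id=nid,
            phase="sample",
            favorite_location=favorite_location,
            probe_locations=probe_locations,
            raw={k: (m, n_obs) for k, m in meas.items()},
            normalized={k: m / hi for k, m in meas.items()},
        )
        pairs.extend(build_index_set(rates))
    return pairs


def gen_experiment(config: GenerativeConfig, neurons: list[NeuronSpec],
                   seed: int | None = None
                   ) -> tuple[list[TrialRecord], list[SpikeTrain]]:
    """All sessions end-to-end: trials with outcomes, plus spike trains.

    Trial ids are globally unique across sessions.  Spikes are generated for
    every trial (the recording does not know the outcome in advance).
    """
    seed = config.rng_seed if seed is None else seed
    all_trials: list[TrialRecord] = []
    next_id = 0
    for s in range(config.n_sessions):
        trials = gen_trials(config, config.trials_per_session, seed, session_id=s)
        trials = [replace(t, trial_id=next_id + t.trial_id) for t in trials]
        next_id += len(trials)
        all_trials.extend(gen_behavior(trials, config, seed + s + 1))
    spikes = gen_spikes(all_trials, neurons, config, seed)
    return all_trials, spikes
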