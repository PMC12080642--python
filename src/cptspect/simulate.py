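"""Synthetic cohort generation for an A→K letter continuous performance task.

The default task geometry is 480 trials at a stimulus-onset asynchrony of
985 ms (85 ms letter + 900 ms blank), with 100 target pairs ("A" followed by
"K") balanced across 4 placement blocks of 120 trials. Per-participant
reaction times are composed additively from a baseline, a linear
time-on-task trend, a sinusoidal infraslow component, Gaussian noise with a
(optionally) block-varying SD, and an optional exponential tail; miss and
commission processes are Bernoulli.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

ALPHABET = np.array(list(string.ascii_uppercase))

#: Minimum plausible motor latency; simulated RTs below it are resampled.
RT_FLOOR_MS = 100.0

#: Extension of the response window into the following trial.
WINDOW_EXTENSION_MS = 150.0

#: Number of equal blocks over which the noise SD may drift linearly.
N_COV_BLOCKS = 8


class ConfigurationError(ValueError):
    """Raised when a task or cohort configuration is infeasible."""


@dataclass(frozen=True)
class TaskSpec:
    """Geometry of one CPT session.

    ``soa`` (stimulus onset asynchrony) is derived as
    ``stim_duration + isi`` and is the spacing between consecutive trial
    onsets in milliseconds.
    """

    n_trials: int = 480
    stim_duration: float = 85.0
    isi: float = 900.0
    n_targets: int = 100
    n_placement_blocks: int = 4

    @property
    def soa(self) -> float:
        """Stimulus-onset asynchrony in milliseconds."""
        return self.stim_duration + self.isi

    @property
    def soa_seconds(self) -> float:
        return self.soa / 1000.0

    @property
    def block_length(self) -> int:
        return self.n_trials // self.n_placement_blocks

    @property
    def targets_per_block(self) -> int:
        return self.n_targets // self.n_placement_blocks

    @property
    def default_response_window(self) -> float:
        """Extended hit window in ms: one SOA plus the into-next-trial extension."""
        return self.soa + WINDOW_EXTENSION_MS

    def validate(self) -> None:
        if self.n_trials <= 0:
            raise ConfigurationError("n_trials must be positive")
        if self.stim_duration <= 0 or self.isi < 0:
            raise ConfigurationError("stimulus timing must be positive")
        if self.n_targets < 0:
            raise ConfigurationError("n_targets must be non-negative")
        if self.n_placement_blocks <= 0:
            raise ConfigurationError("n_placement_blocks must be positive")
        if self.n_trials % self.n_placement_blocks:
            raise ConfigurationError(
                "n_trials must be divisible by n_placement_blocks"
            )
        if self.n_targets % self.n_placement_blocks:
            raise ConfigurationError(
                "n_targets must be divisible by n_placement_blocks"
            )
        # each target pair occupies two consecutive trials; pairs are disjoint
        if 2 * self.targets_per_block > self.block_length:
            raise ConfigurationError(
                f"cannot place {self.targets_per_block} disjoint target pairs "
                f"in a block of {self.block_length} trials"
            )


@dataclass
class ParticipantSim:
    """Generative parameters for one simulated participant.

    The target-trial RT model is::

        rt = rt_mu + trend_slope * trial_index
             + osc_amplitude * sin(2*pi*osc_freq*onset_time + osc_phase)
             + Normal(0, sd(trial_index)) + Exponential(rt_tau)

    truncated to ``[RT_FLOOR_MS, response_window]``, where
    ``sd(trial) = rt_sigma + cov_trend * rt_mu * (block - mean block)`` varies
    linearly over :data:`N_COV_BLOCKS` equal blocks so the simulator can
    express a drift in the coefficient of variation of about ``cov_trend``
    per block.
    """

    participant_id: str
    group: str
    age: float = 40.0
    sex: str = "F"
    rt_mu: float = 450.0
    rt_sigma: float = 50.0
    rt_tau: float = 0.0
    trend_slope: float = 0.0
    cov_trend: float = 0.0
    osc_amplitude: float = 0.0
    osc_freq: float = 0.05
    osc_phase: float = 0.0
    p_miss: float = 0.0
    p_commission: float = 0.0
    seed: int = 0

    def validate(self, spec: TaskSpec) -> None:
        if not (0.0 <= self.p_miss <= 1.0 and 0.0 <= self.p_commission <= 1.0):
            raise ConfigurationError("probabilities must lie in [0, 1]")
        if self.rt_mu <= 0:
            raise ConfigurationError("rt_mu must be positive")
        if self.rt_sigma < 0 or self.rt_tau < 0:
            raise ConfigurationError("rt_sigma and rt_tau must be non-negative")
        nyquist = 0.5 / spec.soa_seconds
        if not (0.0 < self.osc_freq <= nyquist):
            raise ConfigurationError(
                f"osc_freq must lie in (0, {nyquist:.4f}] Hz for this task"
            )


def generate_trial_sequence(
    spec: TaskSpec, seed: int | np.random.SeedSequence
) -> tuple[list[str], np.ndarray]:
    """Generate a letter stream with exactly ``spec.n_targets`` A→K pairs.

    Targets are balanced across placement blocks: each block of
    ``n_trials / n_placement_blocks`` trials holds exactly
    ``n_targets / n_placement_blocks`` pairs. Pairs never share a trial.
    Filler letters are uniform over the alphabet, with redraws that would
    create an unintended A→K bigram rejected, so an exhaustive bigram scan
    of the emitted stream finds exactly ``n_targets`` targets.

    Returns
    -------
    letters : list of str
        One uppercase letter per trial.
    is_target : ndarray of bool
        True on the "K" completing each scheduled pair.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    letters = np.empty(spec.n_trials, dtype="<U1")
    letters[:] = ""
    is_target = np.zeros(spec.n_trials, dtype=bool)

    k = spec.targets_per_block
    block_len = spec.block_length
    for b in range(spec.n_placement_blocks):
        if k == 0:
            continue
        # pair starts within the block at offsets 0..block_len-2 with a
        # minimum gap of 2 (disjoint pairs); sampled uniformly over such
        # sets via the standard gap bijection
        m = block_len - 1
        combo = np.sort(rng.choice(m - (k - 1), size=k, replace=False))
        starts = b * block_len + combo + np.arange(k)
        letters[starts] = "A"
        letters[starts + 1] = "K"
        is_target[starts + 1] = True

    scheduled = letters != ""
    for j in range(spec.n_trials):
        if scheduled[j]:
            continue
        nxt = letters[j + 1] if j + 1 < spec.n_trials and scheduled[j + 1] else ""
        prev = letters[j - 1] if j > 0 else ""
        while True:
            draw = ALPHABET[rng.integers(26)]
            if prev == "A" and draw == "K":
                continue  # would create a spurious A→K
            if draw == "A" and nxt == "K":
                continue  # defensive; scheduled K is always preceded by its A
            break
        letters[j] = draw

    return list(letters), is_target


def simulate_session(
    sequence: tuple[Sequence[str], np.ndarray],
    sim: ParticipantSim,
    spec: TaskSpec | None = None,
    response_window: float | None = None,
) -> pd.DataFrame:
    """Simulate one participant's responses over a generated sequence.

    Returns a tidy trial table with one row per trial and columns
    ``participant_id, group, age, sex, trial_index, onset_time_s, stimulus,
    is_target, rt_ms`` (NaN where no response occurred). Deterministic for a
    fixed ``sim.seed``.
    """
    spec = spec or TaskSpec()
    sim.validate(spec)
    letters, is_target = sequence
    letters = np.asarray(letters)
    is_target = np.asarray(is_target, dtype=bool)
    n = len(letters)
    if response_window is None:
        response_window = spec.default_response_window

    rng = np.random.default_rng(sim.seed)
    idx = np.arange(n)
    onset_s = idx * spec.soa_seconds

    block = idx // max(1, n // N_COV_BLOCKS)
    sd = sim.rt_sigma + sim.cov_trend * sim.rt_mu * (block + 1 - (N_COV_BLOCKS + 1) / 2)
    sd = np.clip(sd, 0.0, None)

    base = (
        sim.rt_mu
        + sim.trend_slope * idx
        + sim.osc_amplitude
        * np.sin(2.0 * math.pi * sim.osc_freq * onset_s + sim.osc_phase)
    )

    rt = np.full(n, np.nan)
    tgt = np.flatnonzero(is_target)
    if tgt.size:
        responded = rng.random(tgt.size) >= sim.p_miss
        live = tgt[responded]
        draws = base[live] + sd[live] * rng.standard_normal(live.size)
        if sim.rt_tau > 0:
            draws = draws + rng.exponential(sim.rt_tau, live.size)
        # resample out-of-range draws; after many tries fall back to clipping
        bad = (draws < RT_FLOOR_MS) | (draws > response_window)
        tries = 0
        while bad.any() and tries < 1000 and (sim.rt_sigma > 0 or sim.rt_tau > 0):
            redo = np.flatnonzero(bad)
            new = base[live[redo]] + sd[live[redo]] * rng.standard_normal(redo.size)
            if sim.rt_tau > 0:
                new = new + rng.exponential(sim.rt_tau, redo.size)
            draws[redo] = new
            bad = (draws < RT_FLOOR_MS) | (draws > response_window)
            tries += 1
        rt[live] = np.clip(draws, RT_FLOOR_MS, response_window)

    ntg = np.flatnonzero(~is_target)
    if ntg.size and sim.p_commission > 0:
        pressed = rng.random(ntg.size) < sim.p_commission
        hot = ntg[pressed]
        rt[hot] = rng.uniform(RT_FLOOR_MS, spec.soa, hot.size)

    return pd.DataFrame(
        {
            "participant_id": sim.participant_id,
            "group": sim.group,
            "age": sim.age,
            "sex": sim.sex,
            "trial_index": idx,
            "onset_time_s": onset_s,
            "stimulus": letters,
            "is_target": is_target,
            "rt_ms": rt,
        }
    )


@dataclass
class GroupSpec:
    """Parameter distributions for one simulated group.

    Each entry of ``params`` configures a :class:`ParticipantSim` field.
    A value may be a scalar (shared by all members), ``{"mean": m, "sd": s}``
    for a normal draw, or ``{"low": a, "high": b}`` for a uniform draw;
    optional ``"min"``/``"max"`` keys clip the draw. ``osc_phase`` defaults
    to a uniform draw on [0, 2π) unless given.
    """

    name: str
    n: int
    params: dict = field(default_factory=dict)
    age: dict | float = field(default_factory=lambda: {"mean": 40.0, "sd": 12.0, "min": 18.0, "max": 65.0})
    p_female: float = 0.5


def _draw_param(rng: np.random.Generator, value) -> float:
    if isinstance(value, dict):
        if "mean" in value:
            x = rng.normal(value["mean"], value.get("sd", 0.0))
        elif "low" in value:
            x = rng.uniform(value["low"], value["high"])
        else:
            raise ConfigurationError(f"unrecognized distribution spec: {value!r}")
        lo = value.get("min", -np.inf)
        hi = value.get("max", np.inf)
        return float(np.clip(x, lo, hi))
    return float(value)


def generate_cohort(
    groups: Sequence[GroupSpec],
    seed: int,
    spec: TaskSpec | None = None,
    response_window: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-group cohort over a single shared trial sequence.

    Per-participant parameters are drawn reproducibly from each group's
    distributions using independent substreams spawned from the master
    seed, so the same configuration and seed always produce byte-identical
    tables.

    Returns ``(trials, covariates)``: a long trial table (one row per trial
    per participant) and a participant covariate table.
    """
    spec = spec or TaskSpec()
    if not groups:
        raise ConfigurationError("at least one group is required")
    for g in groups:
        if g.n <= 0:
            raise ConfigurationError(f"group {g.name!r} is empty")

    master = np.random.SeedSequence(seed)
    seq_ss, *rest = master.spawn(1 + sum(g.n for g in groups))
    sequence = generate_trial_sequence(spec, seq_ss)

    trial_frames = []
    cov_rows = []
    child_iter = iter(rest)
    for g in groups:
        for i in range(g.n):
            child = next(child_iter)
            param_ss, session_ss = child.spawn(2)
            prng = np.random.default_rng(param_ss)
            pid = f"{g.name}-{i:03d}"
            kwargs = {}
            for key, value in g.params.items():
                kwargs[key] = _draw_param(prng, value)
            if "osc_phase" not in kwargs:
                kwargs["osc_phase"] = float(prng.uniform(0.0, 2.0 * math.pi))
            age = _draw_param(prng, g.age)
            sex = "F" if prng.random() < g.p_female else "M"
            sim = ParticipantSim(
                participant_id=pid,
                group=g.name,
                age=age,
                sex=sex,
                seed=int(session_ss.generate_state(1, np.uint64)[0]),
                **kwargs,
            )
            trial_frames.append(
                simulate_session(sequence, sim, spec, response_window=response_window)
            )
            cov_rows.append(
                {"participant_id": pid, "group": g.name, "age": age, "sex": sex}
            )

    trials = pd.concat(trial_frames, ignore_index=True)
    covariates = pd.DataFrame(cov_rows)
    return trials, covariates
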