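"""Neurovascular coupling: stimulus-locked functional-hyperemia metrics.

A whisker-stimulation session alternates 30 s baseline, 30 s stimulation
and 30 s post-stimulation recording, repeated seven times, while
functional ultrasound records relative cerebral blood volume (rCBV) in
the contralateral barrel cortex at 0.2 s resolution.  Each repetition is
one "response": the trial is normalized to its own baseline mean and
summarized by the average rCBV change over the stimulation window, the
peak change, and the time from stimulus onset to that peak.

The statistical unit is the individual response (trial), not the animal:
group comparisons pool every recorded response per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StimSchedule:
    """Timing of the repeated stimulation protocol (seconds)."""

    baseline_s: float = 30.0
    stim_s: float = 30.0
    post_s: float = 30.0
    n_trials: int = 7
    dt_s: float = 0.2

    def __post_init__(self) -> None:
        if min(self.baseline_s, self.stim_s, self.post_s, self.dt_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.n_trials < 1:
            raise ValueError("need at least one trial")
        if self.dt_s > self.stim_s:
            raise ValueError("dt must not exceed the stimulation window")

    @property
    def trial_s(self) -> float:
        return self.baseline_s + self.stim_s + self.post_s

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_s / self.dt_s))

    @property
    def baseline_samples(self) -> int:
        return int(round(self.baseline_s / self.dt_s))

    @property
    def stim_samples(self) -> int:
        return int(round(self.stim_s / self.dt_s))

    @property
    def total_samples(self) -> int:
        return self.n_trials * self.samples_per_trial

    def trial_onsets_s(self) -> np.ndarray:
        """Stimulus onset times from the start of the trace."""
        starts = np.arange(self.n_trials) * self.trial_s
        return starts + self.baseline_s


@dataclass
class NvcTrace:
    """Relative-CBV time series bound to its stimulation schedule."""

    samples: np.ndarray
    schedule: StimSchedule
    animal_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace must be 1-D")


@dataclass
class Trial:
    """One stimulation cycle with labeled sub-windows (sample indices)."""

    samples: np.ndarray
    schedule: StimSchedule
    index: int

    @property
    def baseline(self) -> np.ndarray:
        return self.samples[: self.schedule.baseline_samples]

    @property
    def stim_slice(self) -> slice:
        b = self.schedule.baseline_samples
        return slice(b, b + self.schedule.stim_samples)


@dataclass(frozen=True)
class NvcMetrics:
    average_response_pct: float
    peak_pct: float
    time_to_peak_s: float | None


def segment_trials(trace: NvcTrace) -> list[Trial]:
    """Cut a session trace into its non-overlapping stimulation cycles."""
    sched = trace.schedule
    needed = sched.total_samples
    if trace.samples.size < needed:
        raise ValueError(
            f"trace has {trace.samples.size} samples; "
            f"{needed} needed for {sched.n_trials} trials"
        )
    per = sched.samples_per_trial
    return [
        Trial(samples=trace.samples[i * per : (i + 1) * per], schedule=sched, index=i)
        for i in range(sched.n_trials)
    ]


def baseline_normalize(trial: Trial) -> np.ndarray:
    """Percent change from the trial's own baseline mean.

    dCBV%(t) = 100 * (s(t) - b) / b with b the mean over the pre-stimulus
    window.  Scale-invariant by construction.
    """
    b = trial.baseline.mean()
    if not b > 0:
        raise ValueError("baseline mean must be positive for % normalization")
    return 100.0 * (trial.samples - b) / b


def trial_metrics(normalized: np.ndarray, schedule: StimSchedule) -> NvcMetrics:
    """Average response, peak and time-to-peak over the stimulation window.

    The peak is searched within the stimulation window only; the first
    stimulated sample carries time dt after onset.  A trial that never
    rises above baseline reports peak 0 and a missing time-to-peak.
    """
    b = schedule.baseline_samples
    stim = normalized[b : b + schedule.stim_samples]
    avg = float(stim.mean())
    peak = float(stim.max())
    if peak <= 0:
        return NvcMetrics(average_response_pct=avg, peak_pct=0.0, time_to_peak_s=None)
    ttp = (int(np.argmax(stim)) + 1) * schedule.dt_s
    return NvcMetrics(average_response_pct=avg, peak_pct=peak, time_to_peak_s=ttp)


def analyze_trace(trace: NvcTrace) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-response metrics table plus the stack of normalized trials."""
    trials = segment_trials(trace)
    rows = []
    curves = []
    for tr in trials:
        norm = baseline_normalize(tr)
        m = trial_metrics(norm, trace.schedule)
        rows.append(
            {
                "animal_id": trace.animal_id,
                "group": trace.group,
                "trial": tr.index,
                "average_response_pct": m.average_response_pct,
                "peak_pct": m.peak_pct,
                "time_to_peak_s": m.time_to_peak_s,
            }
        )
        curves.append(norm)
    return pd.DataFrame(rows), np.vstack(curves)


def aggregate_responses(
    tables: list[pd.DataFrame],
    curves: list[np.ndarray],
    schedule: StimSchedule,
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    """Pool per-response tables and build time-locked group mean curves.

    Returns the concatenated response table and, per group, a DataFrame
    with columns time_s (from trial start), mean_pct and sem_pct
    (SEM = SD/sqrt(n) over pooled responses at each time point).
    """
    if not tables:
        raise ValueError("no response tables to aggregate")
    table = pd.concat(tables, ignore_index=True)
    by_group: dict[str, list[np.ndarray]] = {}
    for tab, cur in zip(tables, curves):
        g = tab["group"].iloc[0] if len(tab) else ""
        by_group.setdefault(g, []).append(cur)
    out: dict[str, pd.DataFrame] = {}
    for g, stacks in by_group.items():
        allc = np.vstack(stacks)
        n = allc.shape[0]
        out[g] = pd.DataFrame(
            {
                "time_s": np.arange(allc.shape[1]) * schedule.dt_s,
                "mean_pct": allc.mean(axis=0),
                "sem_pct": allc.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else 0.0,
            }
        )
    return table, out
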