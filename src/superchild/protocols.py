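"""Sampling protocols and composite (geometric-mean) population data sets.

Three designs are supported:

* protocol 1 -- every child sampled on an extensive 36-time schedule
  spanning 0.25-56 d (proof of concept);
* protocol 2 -- every child sampled on the reduced 11-time schedule used in
  field studies (6, 9 and 12 h and 1, 2, 4, 7, 11, 16, 22 and 28 d);
* protocol 3 ("super-child") -- two samples per child: everyone at 4 d and
  five children at each of the ten remaining reduced times, with the
  assignment randomized; several independent randomizations (scenarios) can
  be generated to probe the influence of the assignment.

Composite values are geometric means of the contributing children's FD_p at
each time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Child, Cohort, child_truth_curve
from .kinetics import TracerCurve

__all__ = [
    "SamplingSchedule",
    "Assignment",
    "REDUCED11",
    "EXTENSIVE36",
    "DAY4",
    "geometric_mean_fdp",
    "build_protocol1",
    "build_protocol2",
    "build_protocol3",
    "simulate_cohort_curves",
]

DAY4 = 4.0

_REDUCED_TIMES = np.array(
    [0.25, 0.375, 0.5, 1.0, 2.0, 4.0, 7.0, 11.0, 16.0, 22.0, 28.0]
)
# the reduced schedule plus 25 further times, dense in the absorptive phase
# and through the terminal slope, extending to 56 d
_EXTENSIVE_TIMES = np.sort(np.concatenate([
    _REDUCED_TIMES,
    np.array([0.75, 1.5, 2.5, 3.0, 3.5, 5.0, 6.0, 8.0, 9.0, 10.0, 12.0,
              14.0, 18.0, 20.0, 24.0, 26.0, 30.0, 32.0, 35.0, 38.0, 42.0,
              46.0, 50.0, 53.0, 56.0]),
]))


@dataclass(frozen=True)
class SamplingSchedule:
    name: str
    times: np.ndarray

    def __len__(self) -> int:
        return len(self.times)


REDUCED11 = SamplingSchedule("reduced11", _REDUCED_TIMES)
EXTENSIVE36 = SamplingSchedule("extensive36", _EXTENSIVE_TIMES)


@dataclass
class Assignment:
    """Randomized second-sample times of one super-child scenario.

    Every child is sampled at 4 d; ``second_time`` maps child id to the
    child's other sampling time (one of the ten non-4-d reduced times, five
    children per time).
    """

    scenario_id: int
    second_time: dict[int, float]

    def validate(self, n_per_slot: int = 5) -> None:
        times, counts = np.unique(list(self.second_time.values()),
                                  return_counts=True)
        non4 = [t for t in REDUCED11.times if t != DAY4]
        if sorted(times) != sorted(non4) or not np.all(counts == n_per_slot):
            raise ValueError("assignment must place exactly "
                             f"{n_per_slot} children at each non-4-d time")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scenario": self.scenario_id,
             "child_id": list(self.second_time),
             "second_time_d": list(self.second_time.values())}
        )


def geometric_mean_fdp(values) -> float:
    """Antilog of the mean log FD_p (the composite value at one time)."""
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric mean undefined for FD_p <= 0")
    return float(np.exp(np.mean(np.log(values))))


def simulate_cohort_curves(cohort: Cohort,
                           schedule: SamplingSchedule = EXTENSIVE36
                           ) -> dict[int, TracerCurve]:
    """Per-child truth curves on a schedule, keyed by child id."""
    return {c.id: child_truth_curve(c, schedule.times) for c in cohort.children}


def _composite(curves: dict[int, TracerCurve], schedule: SamplingSchedule,
               contributors: dict[float, list[int]]) -> TracerCurve:
    fdp, n = [], []
    for k, t in enumerate(schedule.times):
        ids = contributors[t]
        vals = []
        for cid in ids:
            curve = curves[cid]
            j = int(np.argmin(np.abs(curve.times - t)))
            if abs(curve.times[j] - t) > 1e-9:
                raise ValueError(f"child {cid} has no sample at t={t}")
            vals.append(curve.fdp[j])
        fdp.append(geometric_mean_fdp(vals))
        n.append(len(ids))
    return TracerCurve(schedule.times, np.array(fdp), np.array(n))


def build_protocol1(cohort: Cohort,
                    curves: dict[int, TracerCurve] | None = None) -> TracerCurve:
    """Composite of all children at all 36 extensive times."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    curves = curves or simulate_cohort_curves(cohort, EXTENSIVE36)
    ids = [c.id for c in cohort.children]
    return _composite(curves, EXTENSIVE36, {t: ids for t in EXTENSIVE36.times})


def build_protocol2(cohort: Cohort,
                    curves: dict[int, TracerCurve] | None = None) -> TracerCurve:
    """Composite of all children at the 11 reduced times."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    curves = curves or simulate_cohort_curves(cohort, REDUCED11)
    ids = [c.id for c in cohort.children]
    return _composite(curves, REDUCED11, {t: ids for t in REDUCED11.times})


def build_protocol3(cohort: Cohort, n_scenarios: int = 5,
                    seed: int | None = None,
                    curves: dict[int, TracerCurve] | None = None
                    ) -> list[tuple[Assignment, TracerCurve]]:
    """Randomized super-child scenarios.

    Each scenario's composite uses every child at 4 d and the five assigned
    children at each remaining reduced time.  Randomization permutes the
    child ids and deals consecutive blocks of five to the ten non-4-d times.
    """
    if seed is None:
        raise ValueError("a seed is required for scenario randomization")
    non4 = [t for t in REDUCED11.times if t != DAY4]
    n_slot, rem = divmod(len(cohort), len(non4))
    if rem != 0 or n_slot == 0:
        raise ValueError(
            f"cohort size {len(cohort)} does not divide into "
            f"{len(non4)} equal second-time groups")
    curves = curves or simulate_cohort_curves(cohort, REDUCED11)
    ids = np.array([c.id for c in cohort.children])
    out = []
    for k in range(n_scenarios):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        perm = rng.permutation(ids)
        second = {}
        for slot, t in enumerate(non4):
            for cid in perm[slot * n_slot:(slot + 1) * n_slot]:
                second[int(cid)] = float(t)
        assignment = Assignment(scenario_id=k + 1, second_time=second)
        assignment.validate(n_per_slot=n_slot)
        contributors: dict[float, list[int]] = {DAY4: [int(i) for i in ids]}
        for t in non4:
            contributors[t] = [cid for cid, tt in second.items() if tt == t]
        out.append((assignment, _composite(curves, REDUCED11, contributors)))
    return out
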