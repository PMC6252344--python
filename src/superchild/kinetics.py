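"""Delay-containing linear compartmental models of whole-body retinol kinetics.

The system follows an oral dose of stable-isotope-labeled retinyl acetate
through gastrointestinal processing (compartments 1 and 2), a discrete
transit delay (component 3, the site of loss of the unabsorbed fraction of
the dose), hepatic processing of newly absorbed retinol (compartment 4), the
plasma retinol pool (compartment 5, the sampling site), a slowly
turning-over extravascular storage pool (compartment 6, identified with
vitamin A total body stores and the site of irreversible disposal to sink
10), and optionally a faster turning-over extravascular pool
(compartment 7).

Two topologies are supported:

* ``full`` -- oral input into compartment 1; used to generate per-child
  "observed" data and to analyse extensive sampling schedules.
* ``simplified`` -- oral input directly into delay component 3; used to
  analyse reduced sampling schedules, where the early (< 1 d) data cannot
  identify the pre-hepatic chain.

Fractional transfer coefficients ``L(I,J)`` (fraction of compartment J's
content moved to compartment I per day) and the delay time ``DT(3)`` (days)
parameterise the system.  Tracer quantities are expressed as fractions of
the administered dose; ``FD_p`` denotes the fraction of the dose in plasma.

The delay is realised exactly: everything upstream of the delay is
feed-forward, so for times past ``DT(3)`` the whole system (upstream chain
time-shifted by the delay) is linear time-invariant and is solved with a
matrix exponential; an adaptive ODE integrator serves as an independent
numerical cross-check in the test-suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.linalg import expm

__all__ = [
    "ModelSpec",
    "TracerCurve",
    "SteadyState",
    "ModelValidationError",
    "SingularSteadyStateError",
    "simulate_tracer",
    "simulate_tracer_all_compartments",
    "steady_state",
    "mst_rbp",
    "conservation_residual",
]

PLASMA = 5
STORES = 6

_FULL_REQUIRED = ((2, 1), (3, 2), (5, 4), (6, 5), (5, 6), (10, 6))
_SIMPLIFIED_REQUIRED = ((5, 4), (6, 5), (5, 6), (10, 6))
_TWO_POOL = ((7, 5), (5, 7))

#: if the eigenvector matrix is worse conditioned than this, fall back from
#: the eigendecomposition fast path to per-time matrix exponentials (the
#: generating models deliberately use L(2,1) = L(3,2), a defective matrix).
_EIG_COND_MAX = 1e6


class ModelValidationError(ValueError):
    """A model specification violates a structural requirement."""


class SingularSteadyStateError(ValueError):
    """The tracee steady state is singular (no route out of stores)."""


def _lkey(pair: tuple[int, int]) -> str:
    return f"L({pair[0]},{pair[1]})"


@dataclass(frozen=True)
class ModelSpec:
    """Topology and parameters of the retinol compartmental system.

    Parameters
    ----------
    variant
        ``"full"`` (oral input into compartment 1) or ``"simplified"``
        (input directly into delay component 3).
    n_extravascular
        1 (storage pool 6 only) or 2 (pools 6 and 7).
    L
        Mapping from ordered compartment-index pairs ``(I, J)`` to
        fractional transfer coefficients, per day.
    dt3
        Delay time DT(3) of component 3, days.
    absorption
        Fraction of the oral dose absorbed, applied at delay exit
        (default 0.80).
    """

    variant: str
    n_extravascular: int
    L: Mapping[tuple[int, int], float]
    dt3: float
    absorption: float = 0.80

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "L", {(int(i), int(j)): float(v) for (i, j), v in self.L.items()}
        )
        self.validate()

    # -- structural validation -------------------------------------------
    def validate(self) -> None:
        if self.variant not in ("full", "simplified"):
            raise ModelValidationError(f"unknown variant {self.variant!r}")
        if self.n_extravascular not in (1, 2):
            raise ModelValidationError(
                f"n_extravascular must be 1 or 2, got {self.n_extravascular}"
            )
        if not self.dt3 > 0:
            raise ModelValidationError("DT(3) must be positive")
        if not 0 < self.absorption <= 1:
            raise ModelValidationError("absorption must be in (0, 1]")
        required = _FULL_REQUIRED if self.variant == "full" else _SIMPLIFIED_REQUIRED
        for pair in required:
            if pair not in self.L:
                raise ModelValidationError(f"missing required coefficient {_lkey(pair)}")
            if not self.L[pair] > 0:
                raise ModelValidationError(f"{_lkey(pair)} must be positive")
        if self.n_extravascular == 2:
            for pair in _TWO_POOL:
                if pair not in self.L or not self.L[pair] > 0:
                    raise ModelValidationError(
                        f"two-pool model requires positive {_lkey(pair)}"
                    )
        else:
            for pair in _TWO_POOL:
                if self.L.get(pair, 0.0) != 0.0:
                    raise ModelValidationError(
                        f"one-pool model must not carry {_lkey(pair)}"
                    )

    @property
    def input_site(self) -> int:
        return 1 if self.variant == "full" else 3

    def l(self, i: int, j: int) -> float:
        """L(i,j), returning 0 for an absent (one-pool) coefficient."""
        return self.L.get((i, j), 0.0)

    # -- serialization ----------------------------------------------------
    def to_text(self) -> str:
        lines = [
            f"variant = {self.variant}",
            f"n_extravascular = {self.n_extravascular}",
            f"absorption = {float(self.absorption)!r}",
            f"DT(3) = {float(self.dt3)!r}",
        ]
        for (i, j), v in sorted(self.L.items()):
            lines.append(f"L({i},{j}) = {float(v)!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelSpec":
        fields: dict[str, str] = {}
        L: dict[tuple[int, int], float] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            m = re.fullmatch(r"L\((\d+),(\d+)\)", key)
            if m:
                L[(int(m.group(1)), int(m.group(2)))] = float(value)
            else:
                fields[key] = value
        return cls(
            variant=fields["variant"],
            n_extravascular=int(fields["n_extravascular"]),
            L=L,
            dt3=float(fields["DT(3)"]),
            absorption=float(fields.get("absorption", 0.80)),
        )


@dataclass
class TracerCurve:
    """Fraction of an oral dose in plasma versus time.

    Represents either one subject's simulated response or a composite
    (geometric-mean) population data set; ``n_per_time`` records how many
    subjects contributed at each time (1 for an individual curve).
    """

    times: np.ndarray
    fdp: np.ndarray
    n_per_time: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fdp = np.asarray(self.fdp, dtype=float)
        if self.n_per_time is None:
            self.n_per_time = np.ones(len(self.times), dtype=int)
        self.n_per_time = np.asarray(self.n_per_time, dtype=int)
        if not (len(self.times) == len(self.fdp) == len(self.n_per_time)):
            raise ValueError("times, fdp and n_per_time must have equal length")
        if len(self.times) and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.fdp < 0) or np.any(self.fdp >= 1):
            raise ValueError("fdp must satisfy 0 <= fdp < 1")
        if np.any(self.n_per_time < 1):
            raise ValueError("n_per_time must be >= 1")

    def __len__(self) -> int:
        return len(self.times)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_d": self.times, "fdp": self.fdp, "n": self.n_per_time}
        )

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TracerCurve":
        return cls(
            df["time_d"].to_numpy(), df["fdp"].to_numpy(), df["n"].to_numpy()
        )

    @classmethod
    def read_tsv(cls, path) -> "TracerCurve":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


@dataclass
class SteadyState:
    """Tracee (unlabeled vitamin A) steady state of the system.

    ``masses`` maps compartment index to vitamin A mass M(I) in µmol;
    ``dietary_input`` is the pre-absorption intake U in µmol/d;
    ``disposal_rate`` is L(10,6) x M(6) in µmol/d; ``fluxes`` maps (I, J)
    to the transfer rate from J to I in µmol/d.
    """

    masses: dict[int, float]
    dietary_input: float
    disposal_rate: float
    fluxes: dict[tuple[int, int], float]


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _augmented_system(spec: ModelSpec, track_disposal: bool = False):
    """Matrix ``B``, initial state ``z0`` and index map of the delayed system.

    The state is taken at the shifted clock tau = t - DT(3): for the full
    model, compartments 1 and 2 enter time-shifted by the delay (so the flux
    leaving compartment 2 reappears, scaled by the absorbed fraction, in
    compartment 4 exactly DT(3) later); for the simplified model the
    absorbed share of the bolus starts in compartment 4 at tau = 0.
    """
    two = spec.n_extravascular == 2
    states: list = []
    if spec.variant == "full":
        states += [1, 2]
    states += [4, 5, 6]
    if two:
        states.append(7)
    if track_disposal:
        states.append("disposal")
    idx = {s: k for k, s in enumerate(states)}
    n = len(states)
    B = np.zeros((n, n))
    z0 = np.zeros(n)
    a = spec.absorption
    if spec.variant == "full":
        l21, l32 = spec.l(2, 1), spec.l(3, 2)
        B[idx[1], idx[1]] = -l21
        B[idx[2], idx[1]] = l21
        B[idx[2], idx[2]] = -l32
        B[idx[4], idx[2]] = a * l32
        z0[idx[1]] = 1.0
    else:
        z0[idx[4]] = a
    B[idx[4], idx[4]] -= spec.l(5, 4)
    B[idx[5], idx[4]] = spec.l(5, 4)
    B[idx[5], idx[5]] = -(spec.l(6, 5) + spec.l(7, 5))
    B[idx[6], idx[5]] = spec.l(6, 5)
    B[idx[6], idx[6]] = -(spec.l(5, 6) + spec.l(10, 6))
    B[idx[5], idx[6]] = spec.l(5, 6)
    if two:
        B[idx[7], idx[5]] = spec.l(7, 5)
        B[idx[7], idx[7]] = -spec.l(5, 7)
        B[idx[5], idx[7]] = spec.l(5, 7)
    if track_disposal:
        B[idx["disposal"], idx[6]] = spec.l(10, 6)
    return B, z0, idx


def _propagate(B: np.ndarray, z0: np.ndarray, taus: np.ndarray) -> np.ndarray:
    """exp(B tau) z0 for each tau; zeros for tau < 0, z0 at tau = 0."""
    taus = np.asarray(taus, dtype=float)
    out = np.zeros((len(taus), len(z0)))
    out[taus == 0] = z0
    pos = taus > 0
    if not np.any(pos):
        return out
    tp = taus[pos]
    try:
        w, V = np.linalg.eig(B)
        if np.linalg.cond(V) < _EIG_COND_MAX:
            c = np.linalg.solve(V, z0.astype(complex))
            E = np.exp(np.multiply.outer(tp, w))
            out[pos] = np.real((E * c) @ V.T)
            return out
    except np.linalg.LinAlgError:
        pass
    vals = np.empty((len(tp), len(z0)))
    for k, tau in enumerate(tp):
        vals[k] = expm(B * tau) @ z0
    out[pos] = vals
    return out


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D sequence")
    if not np.all(times > 0):
        raise ValueError("times must all be positive")
    if not np.all(np.diff(times) > 0):
        raise ValueError("times must be strictly increasing")
    return times


def simulate_tracer(spec: ModelSpec, times: Iterable[float]) -> TracerCurve:
    """Simulate FD_p for a unit oral bolus given at t = 0.

    FD_p is identically zero until the delay has elapsed; the unabsorbed
    fraction ``1 - absorption`` of the dose is removed at delay exit.
    """
    times = _check_times(np.asarray(list(times) if not isinstance(times, np.ndarray) else times))
    B, z0, idx = _augmented_system(spec)
    Z = _propagate(B, z0, times - spec.dt3)
    fdp = np.clip(Z[:, idx[PLASMA]], 0.0, None)
    return TracerCurve(times, fdp, np.ones(len(times), dtype=int))


def _chain12(spec: ModelSpec, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Analytic contents of compartments 1 and 2 of the full model.

    Negative times mean "before dosing": the dose still sits in
    compartment 1.  Handles the deliberately equal-rate case L(2,1)=L(3,2).
    """
    l21, l32 = spec.l(2, 1), spec.l(3, 2)
    tt = np.maximum(np.asarray(t, dtype=float), 0.0)
    x1 = np.exp(-l21 * tt)
    if abs(l21 - l32) < 1e-12 * max(l21, l32):
        x2 = l21 * tt * np.exp(-l21 * tt)
    else:
        x2 = l21 / (l32 - l21) * (np.exp(-l21 * tt) - np.exp(-l32 * tt))
    return x1, x2


def simulate_tracer_all_compartments(
    spec: ModelSpec, times: Iterable[float]
) -> dict:
    """Tracer fraction F(I)(t) in every compartment, plus bookkeeping terms.

    Returns a mapping with integer keys for the compartments present
    (1, 2 for the full model; 3 is the delay content; 4, 5, 6 and, for
    two-pool models, 7) and string keys ``"disposal"`` (cumulative
    irreversible loss via L(10,6)) and ``"unabsorbed"`` (dose discarded at
    delay exit).  All entries sum to 1 at every time (dose conservation).
    """
    times = _check_times(np.asarray(list(times) if not isinstance(times, np.ndarray) else times))
    B, z0, idx = _augmented_system(spec, track_disposal=True)
    taus = times - spec.dt3
    Z = _propagate(B, z0, taus)
    out: dict = {}
    a = spec.absorption
    if spec.variant == "full":
        x1, x2 = _chain12(spec, times)
        y1, y2 = _chain12(spec, taus)  # delay-shifted chain
        out[1] = x1
        out[2] = x2
        out[3] = (y1 + y2) - (x1 + x2)  # content of the delay line
        out["unabsorbed"] = (1.0 - a) * (1.0 - y1 - y2)
    else:
        exited = (taus >= 0).astype(float)
        out[3] = 1.0 - exited
        out["unabsorbed"] = (1.0 - a) * exited
    for comp in (4, 5, 6, 7):
        if comp in idx:
            out[comp] = np.clip(Z[:, idx[comp]], 0.0, None)
    out["disposal"] = np.clip(Z[:, idx["disposal"]], 0.0, None)
    return out


def conservation_residual(compartments: dict) -> np.ndarray:
    """|sum of all tracked fractions - 1| at each time."""
    total = sum(v for v in compartments.values())
    return np.abs(total - 1.0)


# ---------------------------------------------------------------------------
# tracee steady state and sojourn time
# ---------------------------------------------------------------------------

def steady_state(spec: ModelSpec, M5: float) -> SteadyState:
    """Solve the tracee steady state given the plasma pool size M(5).

    With M(5) fixed, per-compartment flux balance gives
    M(6) = L(6,5) M(5) / (L(5,6) + L(10,6)),
    M(7) = L(7,5) M(5) / L(5,7) (zero for a one-pool model), and the
    pre-absorption dietary input U = L(10,6) M(6) / absorption, so that the
    absorbed input exactly balances irreversible disposal.
    """
    if not M5 > 0:
        raise ValueError("M5 must be positive")
    denom = spec.l(5, 6) + spec.l(10, 6)
    if denom == 0:
        raise SingularSteadyStateError("L(5,6) + L(10,6) = 0: stores have no exit")
    M6 = spec.l(6, 5) * M5 / denom
    two = spec.n_extravascular == 2
    M7 = spec.l(7, 5) * M5 / spec.l(5, 7) if two else 0.0
    disposal = spec.l(10, 6) * M6
    U = disposal / spec.absorption
    a = spec.absorption
    masses = {3: U * spec.dt3, 4: a * U / spec.l(5, 4), 5: M5, 6: M6, 7: M7}
    fluxes = {
        (4, 3): a * U,
        (5, 4): a * U,
        (6, 5): spec.l(6, 5) * M5,
        (5, 6): spec.l(5, 6) * M6,
        (10, 6): disposal,
        (7, 5): spec.l(7, 5) * M5 if two else 0.0,
        (5, 7): spec.l(5, 7) * M7 if two else 0.0,
    }
    if spec.variant == "full":
        masses[1] = U / spec.l(2, 1)
        masses[2] = U / spec.l(3, 2)
        fluxes[(2, 1)] = U
        fluxes[(3, 2)] = U
    return SteadyState(
        masses=masses, dietary_input=U, disposal_rate=disposal, fluxes=fluxes
    )


def mst_rbp(spec: ModelSpec) -> float:
    """Mean sojourn time (days) from oral intake to secretion into plasma
    bound to retinol-binding protein.

    Sum of the turnover times of the pre-plasma compartments plus the delay:
    L(2,1)^-1 + L(3,2)^-1 + DT(3) + L(5,4)^-1 for the full model and
    DT(3) + L(5,4)^-1 for the simplified model.
    """
    t = spec.dt3 + 1.0 / spec.l(5, 4)
    if spec.variant == "full":
        t += 1.0 / spec.l(2, 1) + 1.0 / spec.l(3, 2)
    return t
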