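"""Forward dynamics of the recirculation model.

The state vector tracks percentages of the injected label::

    [blood, lung, liver_live, liver_dead, spleen,
     scln_1..k, mln_1..k, pp_1..k, removed, duct_collected]

All flows are first order, so the system is linear; outside cannulation
mode (or with ``nu = 0``) it is also time-invariant and is propagated
exactly with the matrix exponential.  With a nonzero cannulation decline
rate the LN/PP rates depend on time and a stiff-capable ODE integrator is
used instead.  Label is conserved: the bookkeeping pools (``removed`` and
``duct_collected``) absorb every outflow, so the state always sums to the
injected 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from .params import CHAIN_ORGANS, ModelParameters, ParameterError

__all__ = [
    "Trajectory",
    "SimulationError",
    "simulate",
    "steady_state",
    "mean_residence_time",
    "residence_time_distribution",
    "state_labels",
]

RTOL = 1e-9
ATOL = 1e-12


class SimulationError(RuntimeError):
    """Raised when the integrator fails to meet tolerance."""


def state_labels(k: int) -> list[str]:
    """Labels of the state vector for a model with ``k`` sub-compartments."""
    labels = ["blood", "lung", "liver_live", "liver_dead", "spleen"]
    for organ in CHAIN_ORGANS:
        labels += [f"{organ}_{i + 1}" for i in range(k)]
    labels += ["removed", "duct_collected"]
    return labels


def _indices(k: int) -> dict[str, slice | int]:
    idx: dict[str, slice | int] = {
        "blood": 0,
        "lung": 1,
        "liver_live": 2,
        "liver_dead": 3,
        "spleen": 4,
    }
    pos = 5
    for organ in CHAIN_ORGANS:
        idx[organ] = slice(pos, pos + k)
        pos += k
    idx["removed"] = pos
    idx["duct_collected"] = pos + 1
    return idx


def system_matrix(params: ModelParameters, ln_rate_scale: float = 1.0) -> np.ndarray:
    """Rate matrix A with the LN/PP chain rates multiplied by ``ln_rate_scale``.

    ``dy/dt = A @ y``.  Column sums are zero (conservation of label).
    """
    k = params.k
    idx = _indices(k)
    n = 5 + 3 * k + 2
    A = np.zeros((n, n))
    s = params.entry_rates
    m = params.exit_rates
    f = params.thoracic_fraction
    mu = params.removal_rate
    phi = params.dying_fraction
    b = idx["blood"]

    # blood outflows
    A[b, b] = -(sum(s.values()) + mu)
    A[idx["lung"], b] = s["lung"]
    A[idx["liver_live"], b] = s["liver"]
    A[idx["spleen"], b] = s["spleen"]
    A[idx["liver_dead"], b] = phi * mu
    A[idx["removed"], b] = (1.0 - phi) * mu

    # simple organs return to blood
    for organ, row in (("lung", idx["lung"]), ("liver", idx["liver_live"]), ("spleen", idx["spleen"])):
        A[row, row] -= m[organ]
        A[b, row] += m[organ]

    # LN/PP chains
    for organ in CHAIN_ORGANS:
        sl: slice = idx[organ]  # type: ignore[assignment]
        first, last = sl.start, sl.stop - 1
        rate = m[organ] * ln_rate_scale
        A[first, b] += s[organ]
        for i in range(sl.start, sl.stop):
            A[i, i] -= rate
            if i > first:
                A[i, i - 1] += rate
        # terminal efflux routing
        if organ == "pp":
            mln_first = idx["mln"].start  # type: ignore[union-attr]
            A[mln_first, last] += rate
        elif organ == "mln":
            if params.cannulation_mode:
                A[idx["duct_collected"], last] += rate
            else:
                A[b, last] += rate
        else:  # scln
            if params.cannulation_mode:
                A[idx["duct_collected"], last] += f * rate
                A[b, last] += (1.0 - f) * rate
            else:
                A[b, last] += rate
    return A


@dataclass
class Trajectory:
    """Simulated time course of the label distribution.

    Attributes
    ----------
    times
        Minutes since transfer.
    states
        Array of shape (n_times, n_states); columns follow
        :func:`state_labels`.
    params
        The parameter set that produced the trajectory.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters

    def __post_init__(self) -> None:
        self._idx = _indices(self.params.k)

    @property
    def labels(self) -> list[str]:
        return state_labels(self.params.k)

    def pool(self, name: str) -> np.ndarray:
        """Raw pool content by state label or chain-organ total."""
        sel = self._idx[name]
        out = self.states[:, sel]
        return out.sum(axis=1) if out.ndim == 2 else out

    def observable(self, organ: str) -> np.ndarray:
        """The percent of label an experiment would recover from ``organ``.

        The liver observable includes dead cells deposited by removal;
        chain organs report the sum over sub-compartments.
        """
        if organ == "liver":
            return self.pool("liver_live") + self.pool("liver_dead")
        if organ in ("blood", "lung", "spleen") or organ in CHAIN_ORGANS:
            return self.pool(organ)
        raise KeyError(f"unknown observable organ {organ!r}")

    @property
    def removed(self) -> np.ndarray:
        return self.pool("removed")

    @property
    def duct_collected(self) -> np.ndarray:
        return self.pool("duct_collected")

    @property
    def duct_rate(self) -> np.ndarray:
        """Instantaneous thoracic-duct output, percent of bolus per hour."""
        p = self.params
        if not p.cannulation_mode:
            return np.zeros_like(self.times, dtype=float)
        rate = p.exit_rates["mln"] * np.exp(-p.exit_decline_rate * self.times)
        scln_last = self.states[:, self._idx["scln"].stop - 1]  # type: ignore[union-attr]
        mln_last = self.states[:, self._idx["mln"].stop - 1]  # type: ignore[union-attr]
        return 60.0 * rate * (p.thoracic_fraction * scln_last + mln_last)

    @property
    def total(self) -> np.ndarray:
        """Total accounted label (should equal the injected 100%)."""
        return self.states.sum(axis=1)


def simulate(
    params: ModelParameters,
    times: np.ndarray,
    initial_blood: float = 100.0,
    method: str = "auto",
) -> Trajectory:
    """Integrate the model forward from a bolus of label in the blood.

    Parameters
    ----------
    params
        Model parameters.
    times
        Strictly increasing output times in minutes, ``times[0] >= 0``.
    initial_blood
        Size of the injected bolus (percent); all other pools start empty.
    method
        ``"expm"`` propagates the (time-invariant) system exactly with the
        matrix exponential, ``"lsoda"`` uses a stiff-capable integrator,
        ``"auto"`` picks ``expm`` whenever the system is time-invariant.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0:
        raise ValueError("times must be a nonempty 1-D array")
    if times[0] < 0:
        raise ValueError("times must be nonnegative")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    time_varying = params.cannulation_mode and params.exit_decline_rate > 0
    if method == "auto":
        method = "lsoda" if time_varying else "expm"
    if method == "expm" and time_varying:
        raise ValueError(
            "matrix-exponential propagation requires a time-invariant system "
            "(exit_decline_rate == 0 or cannulation_mode off)"
        )

    n = 5 + 3 * params.k + 2
    y0 = np.zeros(n)
    y0[0] = initial_blood

    if method == "expm":
        A = system_matrix(params)
        states = np.empty((times.size, n))
        y = y0
        prev_t = 0.0
        for i, t in enumerate(times):
            dt = t - prev_t
            if dt > 0:
                y = expm(A * dt) @ y
            states[i] = y
            prev_t = t
    elif method == "lsoda":
        nu = params.exit_decline_rate if params.cannulation_mode else 0.0
        A0 = system_matrix(params, ln_rate_scale=0.0)
        A1 = system_matrix(params, ln_rate_scale=1.0) - A0

        def rhs(t: float, y: np.ndarray) -> np.ndarray:
            return A0 @ y + float(np.exp(-nu * t)) * (A1 @ y)

        t_span = (0.0, float(times[-1]) if times[-1] > 0 else 1e-9)
        sol = solve_ivp(
            rhs,
            t_span,
            y0,
            t_eval=times,
            method="LSODA",
            rtol=RTOL,
            atol=ATOL,
        )
        if not sol.success:
            raise SimulationError(f"ODE solver failed: {sol.message}")
        states = sol.y.T
        if not np.all(np.isfinite(states)):
            raise SimulationError("ODE solver produced non-finite values")
    else:
        raise ValueError(f"unknown method {method!r}")

    return Trajectory(times=times, states=states, params=params)


def steady_state(params: ModelParameters) -> dict[str, float]:
    """Closed-form long-run distribution of label over the seven organs.

    Removal is forced to zero (the long-run balance assumes no further
    loss) and cannulation must be off.  At steady state each simple organ
    holds ``s_i / m_i`` cells per unit of blood content; each of the ``k``
    sub-compartments of a chain organ holds ``throughput / m``, where the
    MLN throughput includes the PP efflux it receives.  The result is
    normalized so the seven organ percentages sum to 100.
    """
    if params.cannulation_mode:
        raise ParameterError("steady state is defined for the non-cannulation model")
    s = params.entry_rates
    m = params.exit_rates
    k = params.k
    content = {"blood": 1.0}
    for organ in ("lung", "liver", "spleen"):
        if s[organ] > 0 and m[organ] == 0:
            raise ParameterError(f"organ {organ!r}: entry > 0 with exit 0")
        content[organ] = s[organ] / m[organ] if s[organ] > 0 else 0.0
    throughput = {"scln": s["scln"], "mln": s["mln"] + s["pp"], "pp": s["pp"]}
    for organ in CHAIN_ORGANS:
        if throughput[organ] > 0 and m[organ] == 0:
            raise ParameterError(f"organ {organ!r}: entry > 0 with exit 0")
        content[organ] = k * throughput[organ] / m[organ] if throughput[organ] > 0 else 0.0
    total = sum(content.values())
    return {organ: 100.0 * v / total for organ, v in content.items()}


def mean_residence_time(params: ModelParameters, organ: str) -> float:
    """Mean time (minutes) a cell spends in ``organ`` per visit.

    Simple organs and blood are exponential stages (``1 / rate``); chain
    organs traverse ``k`` stages (``k / m``).  The blood rate is the total
    exit rate, entries plus removal.
    """
    if organ == "blood":
        rate = params.total_blood_exit_rate
        if rate == 0:
            raise ParameterError("blood has zero total exit rate")
        return 1.0 / rate
    if organ in ("lung", "liver", "spleen"):
        rate = params.exit_rates[organ]
        if rate == 0:
            raise ParameterError(f"organ {organ!r} has zero exit rate")
        return 1.0 / rate
    if organ in CHAIN_ORGANS:
        rate = params.exit_rates[organ]
        if rate == 0:
            raise ParameterError(f"organ {organ!r} has zero exit rate")
        return params.k / rate
    raise KeyError(f"unknown organ {organ!r}")


def residence_time_distribution(
    params: ModelParameters, organ: str, t_grid: np.ndarray
) -> np.ndarray:
    """Density of the single-visit residence time in ``organ``.

    Chain organs have gamma-distributed transit times (shape ``k``, rate
    ``m``); single-compartment organs are the ``k = 1`` special case, an
    exponential density.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be nonempty")
    rate = params.exit_rates[organ]
    if rate <= 0:
        raise ParameterError(f"organ {organ!r} has zero exit rate")
    shape = params.k if organ in CHAIN_ORGANS else 1
    return stats.gamma.pdf(t_grid, a=shape, scale=1.0 / rate)
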