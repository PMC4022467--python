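"""Synthetic dataset generation.

Generates migration, cannulation and stimulated-node datasets with the
statistical structure the fitting machinery assumes: model-generated
trajectories sampled on the experimental grids, plus i.i.d. additive
normal noise with dataset-specific standard deviations.  Negative noisy
values are clamped at zero (percent data cannot be negative) and the
number of clamped points is recorded on the returned dataset; with
``clamp_negative=False`` a negative draw raises instead.

The default sampling grids reproduce the source experiments: thirteen
time points between one minute and 24 hours for the migration data, and
90-minute collection intervals over 45 hours for the cannulation data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CannulationDataset, MigrationDataset, StimulatedNodeData
from .experiments import _node_unit_response
from .model import simulate
from .params import ORGANS, ModelParameters

__all__ = [
    "NoiseSpec",
    "MIGRATION_TIMES_MIN",
    "CANNULATION_TIMES_MIN",
    "generate_migration_dataset",
    "generate_cannulation_dataset",
    "generate_stimulated_node_dataset",
]

#: The experimental sampling grid: 1, 2, 5, 10, 30 min and 1, 2.5, 6, 9,
#: 12, 15, 18, 24 h after transfer, in minutes.
MIGRATION_TIMES_MIN = np.array(
    [1.0, 2.0, 5.0, 10.0, 30.0, 60.0, 150.0, 360.0, 540.0, 720.0, 900.0, 1080.0, 1440.0]
)

#: 90-minute thoracic-duct collection intervals over 45 hours, in minutes.
CANNULATION_TIMES_MIN = np.arange(90.0, 45 * 60.0 + 1.0, 90.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Additive-normal error model for synthetic datasets.

    ``sd_migration`` is in percent units, ``sd_cannulation`` in percent of
    the bolus per hour.  The default migration SD is calibrated so that
    fitting a synthetic dataset yields parameter uncertainties on the
    scale of the published confidence intervals (the data being emulated
    are averages over >= 5 animals, hence the small scatter); the
    cannulation SD is ~5% of the peak duct output.  See the methods note.
    """

    sd_migration: float = 0.5
    sd_cannulation: float = 0.1
    seed: int = 0
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if self.sd_migration < 0 or self.sd_cannulation < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _clamp(values: np.ndarray, spec: NoiseSpec) -> tuple[np.ndarray, int]:
    negative = values < 0
    if not spec.clamp_negative:
        if negative.any():
            raise ValueError(
                f"{int(negative.sum())} noisy values fell below zero "
                "(clamping disabled)"
            )
        return values, 0
    return np.where(negative, 0.0, values), int(negative.sum())


def generate_migration_dataset(
    params: ModelParameters,
    times: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> MigrationDataset:
    """Simulate a migration dataset (percent recovered per organ and time).

    The liver record is the measured total (live plus dead cells), as in
    the real assay.  With ``sd_migration = 0`` the output equals the model
    trajectory exactly.
    """
    times = MIGRATION_TIMES_MIN if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseSpec()
    traj = simulate(params.replace(cannulation_mode=False, exit_decline_rate=0.0), times)
    rng = noise.rng()
    rows = []
    clamped = 0
    for organ in ("blood",) + ORGANS:
        clean = traj.observable(organ)
        noisy = clean + rng.normal(0.0, noise.sd_migration, size=clean.size) \
            if noise.sd_migration > 0 else clean.copy()
        noisy, n_neg = _clamp(noisy, noise)
        clamped += n_neg
        for t, v in zip(times, noisy):
            rows.append({"organ": organ, "time_min": t, "percent": v})
    ds = MigrationDataset(pd.DataFrame(rows))
    ds.n_clamped = clamped  # type: ignore[attr-defined]
    return ds


def generate_cannulation_dataset(
    params: ModelParameters,
    f: float | None = None,
    nu: float | None = None,
    times: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
) -> CannulationDataset:
    """Simulate a thoracic-duct cannulation dataset (percent/h output)."""
    times = CANNULATION_TIMES_MIN if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseSpec()
    p = params.replace(
        cannulation_mode=True,
        thoracic_fraction=params.thoracic_fraction if f is None else f,
        exit_decline_rate=params.exit_decline_rate if nu is None else nu,
    )
    traj = simulate(p, times)
    clean = traj.duct_rate
    rng = noise.rng()
    noisy = clean + rng.normal(0.0, noise.sd_cannulation, size=clean.size) \
        if noise.sd_cannulation > 0 else clean.copy()
    noisy, clamped = _clamp(noisy, noise)
    ds = CannulationDataset(pd.DataFrame({"time_min": times, "rate_pct_per_h": noisy}))
    ds.n_clamped = clamped  # type: ignore[attr-defined]
    return ds


def generate_stimulated_node_dataset(
    params: ModelParameters,
    entry_rate_control: float = 3e-4,
    entry_ratio: float = 4.0,
    exit_ratio: float = 1.0,
    times: np.ndarray | None = None,
    noise: NoiseSpec | None = None,
    k: int | None = None,
) -> StimulatedNodeData:
    """Simulate percent-recovered curves for a stimulated vs control node.

    The control node is an auxiliary chain with entry rate
    ``entry_rate_control`` and the shared LN exit rate of ``params``; the
    stimulated node's entry and exit rates are multiplied by
    ``entry_ratio`` and ``exit_ratio``.  The default control entry rate
    makes the node hold a fraction of a percent of the label, small enough
    not to perturb blood kinetics (a single popliteal node).
    """
    if entry_ratio <= 0 or exit_ratio <= 0:
        raise ValueError("entry_ratio and exit_ratio must be > 0")
    times = MIGRATION_TIMES_MIN if times is None else np.asarray(times, dtype=float)
    noise = noise or NoiseSpec()
    k = params.k if k is None else k
    base = params.replace(cannulation_mode=False, exit_decline_rate=0.0)
    m_control = params.exit_rates["scln"]
    spec = {
        "control": (entry_rate_control, m_control),
        "stimulated": (entry_rate_control * entry_ratio, m_control * exit_ratio),
    }
    rng = noise.rng()
    rows = []
    clamped = 0
    for node, (s_n, m_n) in spec.items():
        clean = s_n * _node_unit_response(base, m_n, times, k)
        noisy = clean + rng.normal(0.0, noise.sd_migration, size=clean.size) \
            if noise.sd_migration > 0 else clean.copy()
        noisy, n_neg = _clamp(noisy, noise)
        clamped += n_neg
        for t, v in zip(times, noisy):
            rows.append({"node": node, "time_min": t, "percent": v})
    ds = StimulatedNodeData(pd.DataFrame(rows))
    ds.n_clamped = clamped  # type: ignore[attr-defined]
    return ds
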