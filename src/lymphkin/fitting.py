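"""Parameter estimation for the recirculation model.

The public surface follows the convention of statistical modelling
packages: :class:`RecirculationModel` is built from one or two datasets and
``fit()`` returns a :class:`RecirculationResults` object carrying point
estimates, objective values, residuals, and (after bootstrapping)
confidence intervals.

Two estimation modes are provided:

* migration data alone: nonlinear least squares on the percent-recovered
  records;
* migration plus cannulation data: a generalized likelihood in which the
  two datasets have independent normal error variances.  With the error
  SDs profiled out analytically (``sigma_i^2 = SSR_i / n_i``), maximizing
  the log-likelihood is equivalent to minimizing
  ``(n1/2) log(SSR1/n1) + (n2/2) log(SSR2/n2)``, which is solved by
  iteratively reweighted least squares.

All rates are optimized on a log scale and fractions on a logit scale, so
every iterate respects positivity and the [0, 1] bounds by construction.
Multi-start jittering guards against local minima of the 12+ parameter
landscape.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .data import CannulationDataset, MigrationDataset
from .model import simulate
from .params import ORGANS, ModelParameters

__all__ = [
    "RecirculationModel",
    "RecirculationResults",
    "fit_migration",
    "joint_fit",
    "compare_models",
    "bootstrap_ci",
    "ModelComparison",
]

_RATE_START = {
    "s_lung": 1.0,
    "s_liver": 0.5,
    "s_spleen": 0.05,
    "s_scln": 0.02,
    "s_mln": 0.01,
    "s_pp": 0.005,
    "m_lung": 2.0,
    "m_liver": 1.0,
    "m_spleen": 0.01,
    "m_ln": 0.003,
    "m_scln": 0.003,
    "m_mln": 0.003,
    "m_pp": 0.003,
    "mu": 0.005,
    "nu": 5e-4,
}
_FRACTION_START = {"phi": 0.5, "f": 0.5}


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1 - p))


def _expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x)))


class RecirculationModel:
    """Recirculation model bound to data, ready to be fitted.

    Parameters
    ----------
    migration
        Percent-recovered time courses for the seven observable organs.
    cannulation
        Optional thoracic-duct output time series; providing it switches
        ``fit`` to the joint generalized-likelihood mode and adds the exit
        decline rate ``nu`` (and optionally ``f``) to the free parameters.
    k
        Number of LN/PP sub-compartments.
    shared_ln_exit
        Fit a single exit rate for SCLN, MLN and PP (the default), or one
        per organ.
    fixed
        Mapping of parameter names to values held fixed during the fit
        (e.g. ``{"phi": 0.0}`` or ``{"f": 0.5}``).
    fit_thoracic_fraction
        Free the thoracic-duct routing fraction ``f`` in joint fits.
    """

    def __init__(
        self,
        migration: MigrationDataset,
        cannulation: CannulationDataset | None = None,
        k: int = 2,
        shared_ln_exit: bool = True,
        fixed: dict[str, float] | None = None,
        fit_thoracic_fraction: bool = False,
    ) -> None:
        if len(migration) == 0:
            raise ValueError("migration dataset is empty")
        missing = [o for o in ("blood",) + ORGANS if o not in migration.organs]
        if missing:
            raise ValueError(f"migration data missing organs: {missing}")
        if cannulation is not None and len(cannulation) == 0:
            raise ValueError("cannulation dataset is empty")
        self.migration = migration
        self.cannulation = cannulation
        self.k = int(k)
        self.shared_ln_exit = bool(shared_ln_exit)
        self.fixed = dict(fixed or {})

        names = ["s_lung", "s_liver", "s_spleen", "s_scln", "s_mln", "s_pp"]
        names += ["m_lung", "m_liver", "m_spleen"]
        names += ["m_ln"] if shared_ln_exit else ["m_scln", "m_mln", "m_pp"]
        names += ["mu", "phi"]
        if cannulation is not None:
            names.append("nu")
            if fit_thoracic_fraction:
                names.append("f")
            elif "f" not in self.fixed:
                self.fixed["f"] = 0.5
        else:
            self.fixed.setdefault("nu", 0.0)
            self.fixed.setdefault("f", 0.5)
        unknown = set(self.fixed) - set(names) - {"nu", "f"}
        if unknown:
            raise ValueError(f"cannot fix unknown parameters: {sorted(unknown)}")
        self.param_names = names
        self.free_names = [n for n in names if n not in self.fixed]

        # precompute the record -> (time index, organ) alignment
        self._mig_times = np.unique(migration.frame["time_min"].to_numpy(float))
        pos = {t: i for i, t in enumerate(self._mig_times)}
        self._mig_records = [
            (row["organ"], pos[row["time_min"]])
            for _, row in migration.frame.iterrows()
        ]
        self._mig_obs = migration.frame["percent"].to_numpy(float)

    # -- parameter plumbing ------------------------------------------------

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def nobs(self) -> int:
        n = len(self.migration)
        if self.cannulation is not None:
            n += len(self.cannulation)
        return n

    def start_params(self) -> dict[str, float]:
        """Order-of-magnitude physiological starting values."""
        out = {}
        for name in self.param_names:
            if name in self.fixed:
                continue
            out[name] = _FRACTION_START.get(name, _RATE_START.get(name, 0.01))
        return out

    def _transform(self, values: dict[str, float]) -> np.ndarray:
        x = np.empty(self.n_free)
        for i, name in enumerate(self.free_names):
            v = values[name]
            x[i] = _logit(v) if name in ("phi", "f") else math.log(max(v, 1e-12))
        return x

    def _untransform(self, x: np.ndarray) -> dict[str, float]:
        full = dict(self.fixed)
        for i, name in enumerate(self.free_names):
            full[name] = float(_expit(x[i])) if name in ("phi", "f") else float(np.exp(x[i]))
        return full

    def _build_params(self, full: dict[str, float], cannulation_mode: bool) -> ModelParameters:
        if self.shared_ln_exit:
            m_ln = {o: full["m_ln"] for o in ("scln", "mln", "pp")}
        else:
            m_ln = {o: full[f"m_{o}"] for o in ("scln", "mln", "pp")}
        return ModelParameters(
            entry_rates={o: full[f"s_{o}"] for o in ORGANS},
            exit_rates={"lung": full["m_lung"], "liver": full["m_liver"],
                        "spleen": full["m_spleen"], **m_ln},
            removal_rate=full["mu"],
            dying_fraction=full["phi"],
            thoracic_fraction=full.get("f", 0.5),
            n_subcompartments=self.k,
            cannulation_mode=cannulation_mode,
            exit_decline_rate=full.get("nu", 0.0) if cannulation_mode else 0.0,
        )

    # -- predictions -------------------------------------------------------

    def predict_migration(self, params: ModelParameters) -> np.ndarray:
        """Model values aligned with the migration records."""
        traj = simulate(params.replace(cannulation_mode=False, exit_decline_rate=0.0),
                        self._mig_times)
        cols = {o: traj.observable(o) for o in ("blood",) + ORGANS}
        return np.array([cols[organ][i] for organ, i in self._mig_records])

    def predict_cannulation(self, params: ModelParameters) -> np.ndarray:
        """Duct output rates (percent/h) aligned with the cannulation records."""
        assert self.cannulation is not None
        traj = simulate(params.replace(cannulation_mode=True), self.cannulation.times)
        return traj.duct_rate

    # -- fitting -----------------------------------------------------------

    def _residuals(self, x: np.ndarray, weights: tuple[float, float]) -> np.ndarray:
        full = self._untransform(x)
        try:
            params_m = self._build_params(full, cannulation_mode=False)
            r1 = (self.predict_migration(params_m) - self._mig_obs) / weights[0]
        except Exception:
            return np.full(self.nobs, 1e6)
        if self.cannulation is None:
            return r1
        try:
            params_c = self._build_params(full, cannulation_mode=True)
            r2 = (self.predict_cannulation(params_c) - self.cannulation.rates) / weights[1]
        except Exception:
            return np.full(self.nobs, 1e6)
        return np.concatenate([r1, r2])

    def _ssrs(self, x: np.ndarray) -> tuple[float, float]:
        r = self._residuals(x, (1.0, 1.0))
        n1 = len(self.migration)
        ssr1 = float(np.sum(r[:n1] ** 2))
        ssr2 = float(np.sum(r[n1:] ** 2)) if self.cannulation is not None else 0.0
        return ssr1, ssr2

    def _objective(self, x: np.ndarray) -> float:
        ssr1, ssr2 = self._ssrs(x)
        if self.cannulation is None:
            return ssr1
        n1, n2 = len(self.migration), len(self.cannulation)
        return 0.5 * (n1 * math.log(max(ssr1, 1e-300) / n1)
                      + n2 * math.log(max(ssr2, 1e-300) / n2))

    def fit(
        self,
        start: dict[str, float] | None = None,
        starts: int = 5,
        seed: int = 0,
        max_nfev: int | None = None,
        irls_iter: int = 8,
    ) -> "RecirculationResults":
        """Estimate the free parameters.

        ``starts`` independent optimizations are run from log-normally
        jittered versions of the starting point and the best is kept.
        Joint fits alternate weighted least squares with variance updates
        until the profiled log-likelihood stabilizes.
        """
        start_full = self.start_params()
        if start:
            start_full.update({k: v for k, v in start.items() if k in self.free_names})
        x0 = self._transform(start_full)
        rng = np.random.default_rng(seed)

        best_x, best_obj, converged = None, np.inf, False
        for attempt in range(max(starts, 1)):
            xs = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.3, size=x0.size)
            try:
                x_hat, ok = self._fit_once(xs, max_nfev=max_nfev, irls_iter=irls_iter)
            except Exception:
                continue
            obj = self._objective(x_hat)
            if obj < best_obj:
                best_x, best_obj, converged = x_hat, obj, ok
        if best_x is None:
            # every start failed: report the (unconverged) starting point
            best_x, converged = x0, False

        return self._make_results(best_x, converged)

    def _fit_once(self, x0: np.ndarray, max_nfev: int | None, irls_iter: int):
        weights = (1.0, 1.0)
        x = x0
        ok = False
        if self.cannulation is None:
            sol = optimize.least_squares(
                self._residuals, x, args=(weights,), method="trf",
                xtol=1e-12, ftol=1e-12, gtol=1e-10, max_nfev=max_nfev,
            )
            return sol.x, sol.status > 0
        n1, n2 = len(self.migration), len(self.cannulation)
        prev = np.inf
        for _ in range(irls_iter):
            sol = optimize.least_squares(
                self._residuals, x, args=(weights,), method="trf",
                xtol=1e-10, ftol=1e-10, gtol=1e-8, max_nfev=max_nfev,
            )
            x, ok = sol.x, sol.status > 0
            ssr1, ssr2 = self._ssrs(x)
            weights = (math.sqrt(max(ssr1 / n1, 1e-300)),
                       math.sqrt(max(ssr2 / n2, 1e-300)))
            obj = self._objective(x)
            if abs(prev - obj) < 1e-9:
                break
            prev = obj
        return x, ok

    def _make_results(self, x: np.ndarray, converged: bool) -> "RecirculationResults":
        full = self._untransform(x)
        params = self._build_params(full, cannulation_mode=False)
        ssr1, ssr2 = self._ssrs(x)
        n1 = len(self.migration)
        resid = {"migration": self._mig_obs - self.predict_migration(params)}
        fitted = {"migration": self.predict_migration(params)}
        sigma = {"migration": math.sqrt(ssr1 / n1)}
        loglike = None
        if self.cannulation is not None:
            params_c = self._build_params(full, cannulation_mode=True)
            pred2 = self.predict_cannulation(params_c)
            resid["cannulation"] = self.cannulation.rates - pred2
            fitted["cannulation"] = pred2
            n2 = len(self.cannulation)
            sigma["cannulation"] = math.sqrt(ssr2 / n2)
            loglike = -0.5 * (n1 * math.log(ssr1 / n1) + n2 * math.log(ssr2 / n2))
        return RecirculationResults(
            model=self,
            params=params,
            param_values=full,
            ssr=ssr1 + ssr2,
            ssr_migration=ssr1,
            ssr_cannulation=ssr2 if self.cannulation is not None else None,
            loglike=loglike,
            residuals=resid,
            fitted=fitted,
            sigma=sigma,
            converged=converged,
        )


@dataclass
class RecirculationResults:
    """Fit output: estimates, objective, residuals and (optional) CIs."""

    model: RecirculationModel
    params: ModelParameters
    param_values: dict[str, float]
    ssr: float
    ssr_migration: float
    ssr_cannulation: float | None
    loglike: float | None
    residuals: dict[str, np.ndarray]
    fitted: dict[str, np.ndarray]
    sigma: dict[str, float]
    converged: bool
    conf_int_: pd.DataFrame | None = None
    bootstrap_failures: int = 0
    bootstrap_warning: bool = False
    _bootstrap_draws: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def free_names(self) -> list[str]:
        return self.model.free_names

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_resid(self) -> int:
        return self.nobs - self.model.n_free

    def cannulation_params(self) -> ModelParameters:
        """Parameter set in cannulation mode (with the fitted ``nu``)."""
        return self.model._build_params(self.param_values, cannulation_mode=True)

    def aic(self) -> float:
        """Least-squares AIC, ``n log(SSR/n) + 2 p`` (additive constant dropped)."""
        n = self.nobs
        return n * math.log(self.ssr / n) + 2 * self.model.n_free

    def conf_int(self) -> pd.DataFrame:
        if self.conf_int_ is None:
            raise RuntimeError("run bootstrap() (or bootstrap_ci) first")
        return self.conf_int_

    def bootstrap(self, n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
        """Residual-resampling bootstrap; see :func:`bootstrap_ci`."""
        return bootstrap_ci(self, n_boot=n_boot, seed=seed)

    def compare(self, reduced: "RecirculationResults", method: str = "f_test"):
        return compare_models(self, reduced, method=method)

    def summary(self) -> str:
        lines = ["Recirculation model fit", "=" * 47]
        lines.append(f"observations: {self.nobs}   free parameters: {self.model.n_free}")
        lines.append(f"converged: {self.converged}")
        lines.append(f"SSR (migration): {self.ssr_migration:.5g}")
        if self.ssr_cannulation is not None:
            lines.append(f"SSR (cannulation): {self.ssr_cannulation:.5g}")
            lines.append(f"profiled log-likelihood: {self.loglike:.5g}")
        for name, sd in self.sigma.items():
            lines.append(f"error SD ({name}): {sd:.4g}")
        lines.append("-" * 47)
        lines.append(f"{'parameter':<12}{'estimate':>12}{'95% CI':>22}")
        for name in self.model.param_names:
            est = self.param_values[name]
            ci = ""
            if self.conf_int_ is not None and name in self.conf_int_.index:
                lo, hi = self.conf_int_.loc[name]
                ci = f"({lo:.4g}, {hi:.4g})"
            fixed = "  [fixed]" if name not in self.free_names else ""
            lines.append(f"{name:<12}{est:>12.5g}{ci:>22}{fixed}")
        return "\n".join(lines)


@dataclass
class ModelComparison:
    """Outcome of an F-test or AIC comparison between two fits."""

    method: str
    statistic: float
    p_value: float | None
    delta_aic: float | None
    df_num: int | None = None
    df_den: int | None = None

    @property
    def significant(self) -> bool:
        if self.p_value is not None:
            return self.p_value < 0.05
        return (self.delta_aic or 0.0) > 0.0


def compare_models(
    fit_full: RecirculationResults,
    fit_reduced: RecirculationResults,
    method: str = "f_test",
) -> ModelComparison:
    """Compare a full against a nested reduced fit on the same data.

    The F statistic is ``((SSR_r - SSR_f)/d) / (SSR_f/df_f)`` with
    ``d`` the difference in free-parameter counts and ``df_f`` the full
    model's residual degrees of freedom.  AIC uses the least-squares form
    ``n log(SSR/n) + 2p``; ``delta_aic`` is reduced minus full, so positive
    values favor the full model.
    """
    if fit_full.nobs != fit_reduced.nobs:
        raise ValueError("model comparison requires fits to the same data")
    if method == "f_test":
        p_full, p_red = fit_full.model.n_free, fit_reduced.model.n_free

        def effective(names: list[str]) -> set[str]:
            # a shared LN/PP exit rate is a constrained version of the
            # per-organ exit rates, hence nested inside them
            out = set()
            for name in names:
                out.update(("m_scln", "m_mln", "m_pp") if name == "m_ln" else (name,))
            return out

        if p_full <= p_red or not effective(fit_reduced.free_names) <= effective(
            fit_full.free_names
        ):
            raise ValueError("f_test requires the reduced model to be nested in the full")
        n = fit_full.nobs
        df_num = p_full - p_red
        df_den = n - p_full
        ssr_f, ssr_r = fit_full.ssr, fit_reduced.ssr
        F = max(ssr_r - ssr_f, 0.0) / df_num / (ssr_f / df_den)
        p = float(stats.f.sf(F, df_num, df_den))
        return ModelComparison("f_test", F, p, None, df_num, df_den)
    if method == "aic":
        delta = fit_reduced.aic() - fit_full.aic()
        return ModelComparison("aic", delta, None, delta)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_ci(
    results: RecirculationResults,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Residual-resampling bootstrap confidence intervals.

    Residuals are resampled with replacement *within* each dataset, added
    to the fitted values, and the model is refitted (warm-started at the
    point estimate).  Percentile intervals at ``alpha/2`` and
    ``1 - alpha/2`` are reported.  Refit failures are counted; more than
    10% flags a warning on the results object.
    """
    model = results.model
    rng = np.random.default_rng(seed)
    draws: list[dict[str, float]] = []
    failures = 0
    base_start = {n: results.param_values[n] for n in model.free_names}
    for _ in range(n_boot):
        try:
            boot_model = _resampled_model(model, results, rng)
            fit = boot_model.fit(start=base_start, starts=1, irls_iter=4)
            if not fit.converged:
                failures += 1
                continue
            draws.append({n: fit.param_values[n] for n in model.free_names})
        except Exception:
            failures += 1
    if not draws:
        raise RuntimeError("all bootstrap refits failed")
    table = pd.DataFrame(draws)
    lo = table.quantile(alpha / 2)
    hi = table.quantile(1 - alpha / 2)
    ci = pd.DataFrame({"lower": lo, "upper": hi})
    results.conf_int_ = ci
    results.bootstrap_failures = failures
    results.bootstrap_warning = failures > 0.1 * n_boot
    results._bootstrap_draws = table
    return ci


def _resampled_model(
    model: RecirculationModel, results: RecirculationResults, rng: np.random.Generator
) -> RecirculationModel:
    r1 = results.residuals["migration"]
    y1 = results.fitted["migration"] + rng.choice(r1, size=r1.size, replace=True)
    mig_frame = model.migration.frame.copy()
    mig_frame["percent"] = np.clip(y1, 0.0, None)
    mig = MigrationDataset(mig_frame)
    can = None
    if model.cannulation is not None:
        r2 = results.residuals["cannulation"]
        y2 = results.fitted["cannulation"] + rng.choice(r2, size=r2.size, replace=True)
        can_frame = model.cannulation.frame.copy()
        can_frame["rate_pct_per_h"] = np.clip(y2, 0.0, None)
        can = CannulationDataset(can_frame)
    return RecirculationModel(
        mig,
        can,
        k=model.k,
        shared_ln_exit=model.shared_ln_exit,
        fixed=dict(model.fixed),
        fit_thoracic_fraction="f" in model.free_names,
    )


def fit_migration(
    data: MigrationDataset,
    k: int = 2,
    shared_ln_exit: bool = True,
    fixed: dict[str, float] | None = None,
    **fit_kwargs,
) -> RecirculationResults:
    """Least-squares fit of the model to migration data alone."""
    return RecirculationModel(data, k=k, shared_ln_exit=shared_ln_exit, fixed=fixed).fit(
        **fit_kwargs
    )


def joint_fit(
    migration: MigrationDataset,
    cannulation: CannulationDataset,
    k: int = 2,
    shared_ln_exit: bool = True,
    fixed: dict[str, float] | None = None,
    fit_thoracic_fraction: bool = False,
    **fit_kwargs,
) -> RecirculationResults:
    """Generalized-likelihood fit to migration and cannulation data jointly."""
    return RecirculationModel(
        migration,
        cannulation,
        k=k,
        shared_ln_exit=shared_ln_exit,
        fixed=fixed,
        fit_thoracic_fraction=fit_thoracic_fraction,
    ).fit(**fit_kwargs)
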