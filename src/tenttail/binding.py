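"""Fluorescence-anisotropy binding models and nonlinear least-squares fits.

Two models are implemented:

* **Saturation** (one-site specific binding): a fluorescent nucleotide probe
  is titrated with protein; anisotropy rises hyperbolically,

      A(P) = A_free + (A_max - A_free) * P / (K_d + P)

* **Competition**: probe and protein are fixed, an unlabeled nucleotide
  competitor displaces the probe,

      A([NTP]) = A_free + (A_bound - A_free) / (1 + [NTP] / IC50)

  At zero competitor the probe is maximally bound (A = A_bound); at
  [NTP] = IC50 the anisotropy is halfway between the plateaus.  Several
  independent titration experiments are fitted *globally*: a single shared
  IC50 with per-experiment plateau pairs (A_free, A_bound), which absorbs
  day-to-day offsets of the raw anisotropy while pooling all information
  about the midpoint.

Both fits parameterize the midpoint (K_d or IC50) as log10(nM) — this
enforces positivity and conditions the problem across the decades spanned by
a titration — and use multi-start ordinary least squares.  Standard errors
come from the asymptotic covariance s^2 (J^T J)^-1; confidence intervals and
bands use Student-t quantiles and the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "AnisotropyMeasurement",
    "SaturationFit",
    "CompetitionFit",
    "saturation_model",
    "competition_model",
    "fit_saturation",
    "fit_competition_global",
    "UnderdeterminedError",
]

_LN10 = math.log(10.0)


class UnderdeterminedError(ValueError):
    """Raised when a dataset cannot pin down the model parameters."""


@dataclass(frozen=True)
class AnisotropyMeasurement:
    """One anisotropy observation.

    ``concentration_nm`` is the titrated species in nM: protein for a
    saturation experiment, unlabeled competitor for a competition experiment.
    """

    experiment_id: str
    concentration_nm: float
    anisotropy: float
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.concentration_nm < 0:
            raise ValueError(f"concentration must be >= 0, got {self.concentration_nm}")
        if not math.isfinite(self.anisotropy):
            raise ValueError("anisotropy must be finite")


def saturation_model(conc, kd: float, a_free: float, a_max: float):
    """One-site specific binding: A_free + (A_max - A_free) * c / (kd + c)."""
    if kd <= 0:
        raise ValueError(f"kd must be > 0, got {kd}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return a_free + (a_max - a_free) * c / (kd + c)


def competition_model(conc, ic50: float, a_free: float, a_bound: float):
    """Competitive displacement: A_free + (A_bound - A_free) / (1 + c / ic50)."""
    if ic50 <= 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    return a_free + (a_bound - a_free) / (1.0 + c / ic50)


@dataclass
class SaturationFit:
    """Result of a one-site saturation fit."""

    kd_nm: float
    a_free: float
    a_max: float
    kd_se_nm: float
    a_free_se: float
    a_max_se: float
    log10_kd: float
    log10_kd_se: float
    kd_ci_nm: tuple[float, float]
    residual_sum_of_squares: float
    n_points: int
    converged: bool
    message: str = ""

    def predict(self, conc):
        return saturation_model(conc, self.kd_nm, self.a_free, self.a_max)


@dataclass
class CompetitionFit:
    """Result of a global competition fit: one shared IC50, per-experiment plateaus."""

    ic50_nm: float
    ic50_se_nm: float
    ic50_ci_nm: tuple[float, float]
    log10_ic50: float
    log10_ic50_se: float
    plateaus: dict  # experiment_id -> {"a_free","a_bound","a_free_se","a_bound_se"}
    param_names: list
    covariance: np.ndarray
    residual_sum_of_squares: float
    n_points: int
    dof: int
    level: float
    identifiable: bool
    message: str = ""
    _param_index: dict = field(default_factory=dict, repr=False)

    def predict(self, conc, experiment_id: str):
        p = self.plateaus[experiment_id]
        return competition_model(conc, self.ic50_nm, p["a_free"], p["a_bound"])

    def confidence_band(self, conc, experiment_id: str, level: Optional[float] = None):
        """Delta-method pointwise confidence band (lower, upper) for the fitted curve."""
        level = self.level if level is None else level
        c = np.atleast_1d(np.asarray(conc, dtype=float))
        p = self.plateaus[experiment_id]
        ic50, af, ab = self.ic50_nm, p["a_free"], p["a_bound"]
        f = ic50 / (ic50 + c)  # bound fraction of the signal
        # gradient wrt [log10_ic50, a_free_e, a_bound_e]
        d_dt = (ab - af) * c * ic50 * _LN10 / (ic50 + c) ** 2
        grads = np.zeros((c.size, len(self.param_names)))
        grads[:, 0] = d_dt
        grads[:, self._param_index[(experiment_id, "a_free")]] = 1.0 - f
        grads[:, self._param_index[(experiment_id, "a_bound")]] = f
        var = np.einsum("ij,jk,ik->i", grads, self.covariance, grads)
        se = np.sqrt(np.clip(var, 0.0, None))
        tcrit = stats.t.ppf(0.5 + level / 2.0, max(self.dof, 1))
        fit = self.predict(c, experiment_id)
        return fit - tcrit * se, fit + tcrit * se


def _as_arrays(data: Iterable[AnisotropyMeasurement]):
    ms = list(data)
    conc = np.array([m.concentration_nm for m in ms], dtype=float)
    aniso = np.array([m.anisotropy for m in ms], dtype=float)
    exp = np.array([m.experiment_id for m in ms])
    return conc, aniso, exp


def _covariance(jac: np.ndarray, rss: float, dof: int) -> tuple[np.ndarray, bool]:
    """Asymptotic covariance s^2 (J^T J)^+; second value is full-rank flag."""
    jtj = jac.T @ jac
    svals = np.linalg.svd(jac, compute_uv=False)
    full_rank = svals.size > 0 and svals.min() > 1e-10 * max(svals.max(), 1e-300)
    s2 = rss / dof if dof > 0 else np.inf
    cov = s2 * np.linalg.pinv(jtj)
    return cov, full_rank


def fit_saturation(data: Iterable[AnisotropyMeasurement], n_starts: int = 7) -> SaturationFit:
    """Fit the one-site saturation model by multi-start least squares.

    Requires at least 3 distinct concentrations (3 free parameters).  K_d is
    fitted on the log10 scale over a grid spanning [min positive conc / 10,
    max conc * 10].  Degenerate data (no amplitude, rank-deficient Jacobian)
    yield ``converged=False`` rather than an exception.
    """
    conc, aniso, _ = _as_arrays(data)
    if np.unique(conc).size < 3:
        raise UnderdeterminedError(
            f"saturation fit needs >= 3 distinct concentrations, got {np.unique(conc).size}"
        )
    pos = conc[conc > 0]
    lo, hi = math.log10(pos.min() / 10.0), math.log10(conc.max() * 10.0)

    def residuals(x):
        kd = 10.0 ** x[0]
        return x[1] + (x[2] - x[1]) * conc / (kd + conc) - aniso

    a_free0 = float(aniso[np.argmin(conc)])
    a_max0 = float(aniso[np.argmax(conc)])
    best = None
    for t0 in np.linspace(lo, hi, n_starts):
        res = optimize.least_squares(residuals, x0=[t0, a_free0, a_max0], method="lm")
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2.0 * best.cost)
    n = conc.size
    dof = n - 3
    cov, full_rank = _covariance(best.jac, rss, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    t_hat, a_free, a_max = best.x
    kd = 10.0 ** t_hat
    kd_se = _LN10 * kd * se[0]
    tcrit = stats.t.ppf(0.975, max(dof, 1))
    ci = (10.0 ** (t_hat - tcrit * se[0]), 10.0 ** (t_hat + tcrit * se[0]))
    span = hi - lo
    near_bound = min(t_hat - lo, hi - t_hat) < 0.05 * span
    amplitude = abs(a_max - a_free)
    scale = max(np.ptp(aniso), 1e-12)
    degenerate = amplitude < 1e-6 or amplitude < 0.05 * scale
    converged = bool(best.success and full_rank and not degenerate and not near_bound)
    msg = "" if converged else (
        "degenerate amplitude (a_max ~ a_free)" if degenerate or not full_rank
        else "K_d estimate at search bound" if near_bound else best.message
    )
    return SaturationFit(
        kd_nm=float(kd), a_free=float(a_free), a_max=float(a_max),
        kd_se_nm=float(kd_se), a_free_se=float(se[1]), a_max_se=float(se[2]),
        log10_kd=float(t_hat), log10_kd_se=float(se[0]), kd_ci_nm=ci,
        residual_sum_of_squares=rss, n_points=n, converged=converged, message=msg,
    )


def fit_competition_global(
    data: Iterable[AnisotropyMeasurement],
    level: float = 0.95,
    n_starts: int = 8,
) -> CompetitionFit:
    """Globally fit competition titrations: shared IC50, per-experiment plateaus.

    Every experiment must contribute at least 2 distinct concentrations.  The
    shared log10(IC50) is multi-started on a grid spanning one decade beyond
    the titrated range.  Flat data (no displacement signal) are reported with
    ``identifiable=False``, not an exception; the same flag is cleared when
    the estimate sits within 5% (log scale) of the search bounds or the IC50
    confidence interval spans more than two orders of magnitude.
    """
    conc, aniso, exp = _as_arrays(data)
    if conc.size == 0:
        raise UnderdeterminedError("no measurements")
    exp_ids = sorted(set(exp.tolist()))
    masks = {e: exp == e for e in exp_ids}
    for e in exp_ids:
        if np.unique(conc[masks[e]]).size < 2:
            raise UnderdeterminedError(
                f"experiment {e!r} has fewer than 2 distinct concentrations"
            )
    pos = conc[conc > 0]
    if pos.size == 0:
        raise UnderdeterminedError("all concentrations are zero")
    lo = math.log10(pos.min()) - 1.0
    hi = math.log10(conc.max()) + 1.0

    param_names = ["log10_ic50"]
    param_index: dict = {}
    for e in exp_ids:
        param_index[(e, "a_free")] = len(param_names)
        param_names.append(f"a_free[{e}]")
        param_index[(e, "a_bound")] = len(param_names)
        param_names.append(f"a_bound[{e}]")
    n_params = len(param_names)

    def residuals(x):
        ic50 = 10.0 ** x[0]
        out = np.empty_like(aniso)
        for e in exp_ids:
            m = masks[e]
            af = x[param_index[(e, "a_free")]]
            ab = x[param_index[(e, "a_bound")]]
            out[m] = af + (ab - af) / (1.0 + conc[m] / ic50) - aniso[m]
        return out

    x0_plateaus = []
    for e in exp_ids:
        ce, ae = conc[masks[e]], aniso[masks[e]]
        x0_plateaus += [float(ae[np.argmax(ce)]), float(ae[np.argmin(ce)])]  # a_free, a_bound
    best = None
    for t0 in np.linspace(lo, hi, n_starts):
        res = optimize.least_squares(residuals, x0=[t0] + x0_plateaus, method="lm")
        if best is None or res.cost < best.cost:
            best = res

    rss = float(2.0 * best.cost)
    n = conc.size
    dof = n - n_params
    cov, full_rank = _covariance(best.jac, rss, dof)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    t_hat = float(best.x[0])
    ic50 = 10.0 ** t_hat
    se_t = float(se[0])
    ic50_se = _LN10 * ic50 * se_t
    tcrit = stats.t.ppf(0.5 + level / 2.0, max(dof, 1))
    ci = (10.0 ** (t_hat - tcrit * se_t), 10.0 ** (t_hat + tcrit * se_t))

    plateaus = {}
    for e in exp_ids:
        i_f, i_b = param_index[(e, "a_free")], param_index[(e, "a_bound")]
        plateaus[e] = {
            "a_free": float(best.x[i_f]),
            "a_bound": float(best.x[i_b]),
            "a_free_se": float(se[i_f]),
            "a_bound_se": float(se[i_b]),
        }

    span = hi - lo
    near_bound = min(t_hat - lo, hi - t_hat) < 0.05 * span
    ci_decades = 2.0 * tcrit * se_t
    identifiable = bool(best.success and full_rank and not near_bound and ci_decades <= 2.0)
    msg = "" if identifiable else (
        "rank-deficient Jacobian (flat data?)" if not full_rank
        else "IC50 estimate at search bound" if near_bound
        else f"IC50 CI spans {ci_decades:.1f} decades"
    )
    return CompetitionFit(
        ic50_nm=float(ic50), ic50_se_nm=float(ic50_se), ic50_ci_nm=ci,
        log10_ic50=t_hat, log10_ic50_se=se_t,
        plateaus=plateaus, param_names=param_names, covariance=cov,
        residual_sum_of_squares=rss, n_points=n, dof=dof, level=level,
        identifiable=identifiable, message=msg, _param_index=param_index,
    )
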