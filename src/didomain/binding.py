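"""Equilibrium binding-affinity fitting for BLI plateau responses.

Biolayer interferometry with an immobilised RNA ligand and protein analyte
in excess is described by the simple Langmuir isotherm

    R([P]) = Rmax · [P] / (Kd + [P]),

fit here by nonlinear least squares with a seeded parametric bootstrap for
confidence intervals.  A depletion-aware quadratic model is available for
cases where the analyte is not in excess.  Fold changes between constructs
or RNAs are ratios of fitted Kd values with CIs combined from the
bootstrap draws.

Concentrations are stored in molar internally; constructors accept µM/nM.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BindingSeries",
    "AffinityFit",
    "fit_isotherm",
    "fold_change",
    "normalize_series",
]


@dataclasses.dataclass(frozen=True)
class BindingSeries:
    """Plateau response vs analyte (protein) concentration."""

    conc_m: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        conc = np.asarray(self.conc_m, dtype=float)
        resp = np.asarray(self.response, dtype=float)
        if conc.shape != resp.shape:
            raise ValueError("conc and response must align")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise ValueError("need at least 4 unique concentrations")
        order = np.argsort(conc)
        object.__setattr__(self, "conc_m", conc[order])
        object.__setattr__(self, "response", resp[order])

    @classmethod
    def from_um(cls, conc_um, response, label: str = "") -> "BindingSeries":
        return cls(np.asarray(conc_um, float) * 1e-6, np.asarray(response, float), label)

    @classmethod
    def from_nm(cls, conc_nm, response, label: str = "") -> "BindingSeries":
        return cls(np.asarray(conc_nm, float) * 1e-9, np.asarray(response, float), label)


@dataclasses.dataclass(frozen=True)
class AffinityFit:
    kd_m: float
    rmax: float
    kd_ci95_m: tuple[float, float]
    rmax_ci95: tuple[float, float]
    model: str
    residual_rms: float
    poorly_determined: bool
    bootstrap_kd_m: np.ndarray
    label: str = ""

    @property
    def kd_um(self) -> float:
        return self.kd_m * 1e6

    @property
    def kd_nm(self) -> float:
        return self.kd_m * 1e9


def _hyperbola(conc: np.ndarray, kd: float, rmax: float) -> np.ndarray:
    return rmax * conc / (kd + conc)


def _depletion(conc: np.ndarray, kd: float, rmax: float, ligand_m: float) -> np.ndarray:
    s = conc + ligand_m + kd
    bound = (s - np.sqrt(s * s - 4.0 * conc * ligand_m)) / 2.0
    return rmax * bound / ligand_m


def _fit_once(conc: np.ndarray, resp: np.ndarray, model: str, ligand_m: float | None):
    # fit with concentrations rescaled by the top concentration so both
    # parameters are O(1) regardless of whether the series is nM or µM
    scale = conc.max()
    c_s = conc / scale
    p0 = [max(conc[np.argmin(np.abs(resp - resp.max() / 2))] / scale, c_s.min()), resp.max()]
    bounds = ([0.0, 0.0], [np.inf, np.inf])
    if model == "hyperbolic":
        fun_s = lambda c, kd, rmax: _hyperbola(c, kd, rmax)  # noqa: E731
    elif model == "depletion":
        if ligand_m is None:
            raise ValueError("depletion model requires ligand_m")
        fun_s = lambda c, kd, rmax: _depletion(c, kd, rmax, ligand_m / scale)  # noqa: E731
    else:
        raise ValueError(f"unknown model {model!r}")
    try:
        popt, _ = optimize.curve_fit(fun_s, c_s, resp, p0=p0, bounds=bounds, maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(
            f"isotherm fit failed to converge (start point Kd={p0[0] * scale:.3g} M, "
            f"Rmax={p0[1]:.3g}): {exc}"
        ) from exc
    kd, rmax = popt
    fun = lambda c, kd_m, rm: fun_s(c / scale, kd_m / scale, rm)  # noqa: E731
    return np.array([kd * scale, rmax]), fun


def fit_isotherm(
    series: BindingSeries,
    model: str = "hyperbolic",
    ligand_m: float | None = None,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
) -> AffinityFit:
    """Fit Kd and Rmax to a plateau-response series.

    The responses must broadly increase with concentration (Spearman ρ > 0);
    CIs come from a parametric bootstrap (``n_boot`` refits of the fitted
    curve plus Gaussian noise at the residual scale).  A Kd outside
    [min conc / 100, max conc × 100] is flagged poorly determined.
    """
    conc, resp = series.conc_m, series.response
    rho = stats.spearmanr(conc, resp)[0]
    if not rho > 0:
        raise ValueError(f"responses do not increase with concentration (Spearman rho={rho:.2f})")
    (kd, rmax), fun = _fit_once(conc, resp, model, ligand_m)
    fitted = fun(conc, kd, rmax)
    resid = resp - fitted
    sigma = float(np.sqrt(np.mean(resid**2)))
    # unbiased noise scale for the parametric bootstrap (2 fitted parameters)
    dof = max(len(conc) - 2, 1)
    sigma_boot = float(np.sqrt(np.sum(resid**2) / dof))

    rng = np.random.default_rng(0) if rng is None else rng
    kds, rmaxs = [], []
    for _ in range(n_boot):
        noisy = fitted + rng.normal(0.0, sigma_boot if sigma_boot > 0 else 1e-12, size=len(conc))
        try:
            (kd_b, rmax_b), _ = _fit_once(conc, noisy, model, ligand_m)
        except RuntimeError:
            continue
        kds.append(kd_b)
        rmaxs.append(rmax_b)
    kds_arr = np.asarray(kds)
    if len(kds_arr):
        ci_kd = (float(np.percentile(kds_arr, 2.5)), float(np.percentile(kds_arr, 97.5)))
        ci_rmax = (float(np.percentile(rmaxs, 2.5)), float(np.percentile(rmaxs, 97.5)))
    else:
        ci_kd = ci_rmax = (float("nan"), float("nan"))
    poorly = not (conc.min() / 100.0 <= kd <= conc.max() * 100.0)
    return AffinityFit(
        kd_m=float(kd),
        rmax=float(rmax),
        kd_ci95_m=ci_kd,
        rmax_ci95=ci_rmax,
        model=model,
        residual_rms=sigma,
        poorly_determined=poorly,
        bootstrap_kd_m=kds_arr,
        label=series.label,
    )


def fold_change(fit_a: AffinityFit, fit_b: AffinityFit) -> dict:
    """Kd ratio B/A with a CI from paired bootstrap draws."""
    import warnings

    if fit_a.poorly_determined or fit_b.poorly_determined:
        warnings.warn("fold change involves a poorly determined Kd", stacklevel=2)
    ratio = fit_b.kd_m / fit_a.kd_m
    n = min(len(fit_a.bootstrap_kd_m), len(fit_b.bootstrap_kd_m))
    if n > 0:
        draws = fit_b.bootstrap_kd_m[:n] / fit_a.bootstrap_kd_m[:n]
        ci = (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
    else:
        ci = (float("nan"), float("nan"))
    return {"ratio": float(ratio), "ci95": ci}


def normalize_series(series: BindingSeries, fit: AffinityFit) -> BindingSeries:
    """Responses divided by fitted Rmax; the normalised curve half-max sits at Kd."""
    return BindingSeries(
        conc_m=series.conc_m.copy(),
        response=series.response / fit.rmax,
        label=f"{series.label} (normalised)" if series.label else "(normalised)",
    )
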