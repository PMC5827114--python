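"""Chemical shift perturbation (CSP) analysis of NMR titrations.

Amide resonances move when a ligand binds in fast exchange; the combined
¹H/¹⁵N perturbation

    CSP = sqrt( ΔδH² + (α ΔδN)² ),   α = 0.154

maps the binding (or interaction) surface.  Residues with endpoint CSP
strictly above 0.02 ppm are classified as perturbed ("active" in
docking-input terms), compared against crystallographic contact residues
to test whether the solution interface matches the crystal, and a global
1:1 fast-exchange binding model can be fit across residues to extract a
shared Kd.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ShiftRecord",
    "TitrationSeries",
    "CspProfile",
    "NITROGEN_SCALE",
    "combined_csp",
    "csp_profile",
    "classify_perturbed",
    "surface_consistency",
    "bound_fraction",
    "fit_fast_exchange_kd",
]

#: ¹⁵N scaling factor in the combined CSP (Mulder/Williamson convention).
NITROGEN_SCALE = 0.154

#: docking-input activity threshold on the combined CSP (ppm, strict >).
ACTIVE_THRESHOLD_PPM = 0.02


@dataclasses.dataclass(frozen=True)
class ShiftRecord:
    residue: tuple[str, int]
    dh_ppm: float
    dn_ppm: float


@dataclasses.dataclass(frozen=True)
class TitrationSeries:
    """Amide shifts across ligand:protein ratios; point 0 is the free protein."""

    ratios: tuple[float, ...]
    shifts: tuple[Mapping[tuple[str, int], ShiftRecord], ...]
    protein_conc_um: float

    def __post_init__(self) -> None:
        r = self.ratios
        if len(r) != len(self.shifts):
            raise ValueError("one shift table per titration point")
        if any(b <= a for a, b in zip(r, r[1:])) or r[0] < 0:
            raise ValueError("ratios must be non-negative and strictly increasing")
        if r[0] != 0:
            raise ValueError("first titration point must be the free protein (ratio 0)")


@dataclasses.dataclass(frozen=True)
class CspProfile:
    """Endpoint and per-point combined CSPs (ppm) relative to the free protein."""

    endpoint: dict[tuple[str, int], float]
    trajectories: dict[tuple[str, int], np.ndarray]
    ratios: tuple[float, ...]
    alpha: float


def combined_csp(free: ShiftRecord, bound: ShiftRecord, alpha: float = NITROGEN_SCALE) -> float:
    """Combined amide CSP in ppm: sqrt(ΔδH² + (α ΔδN)²)."""
    if free.residue != bound.residue:
        raise ValueError(f"residue mismatch: {free.residue} vs {bound.residue}")
    return float(np.hypot(bound.dh_ppm - free.dh_ppm, alpha * (bound.dn_ppm - free.dn_ppm)))


def csp_profile(series: TitrationSeries, alpha: float = NITROGEN_SCALE) -> CspProfile:
    """Per-residue CSP trajectories; the endpoint is the highest-ratio point."""
    free = series.shifts[0]
    traj: dict[tuple[str, int], np.ndarray] = {}
    for rid, rec0 in free.items():
        values = []
        for table in series.shifts:
            rec = table.get(rid)
            values.append(combined_csp(rec0, rec, alpha) if rec is not None else np.nan)
        traj[rid] = np.asarray(values)
    endpoint = {rid: float(v[-1]) for rid, v in traj.items() if np.isfinite(v[-1])}
    return CspProfile(endpoint=endpoint, trajectories=traj, ratios=series.ratios, alpha=alpha)


def classify_perturbed(
    profile: CspProfile, threshold: float = ACTIVE_THRESHOLD_PPM
) -> set[tuple[str, int]]:
    """Residues with endpoint CSP strictly above the threshold."""
    return {rid for rid, v in profile.endpoint.items() if v > threshold}


def surface_consistency(
    active: Iterable[tuple[str, int]], contacts: Iterable[tuple[str, int]]
) -> dict:
    """Overlap between CSP-active residues and crystal-contact residues.

    A high Jaccard index supports the crystal interface being the dominant
    solution conformer; this is a printed consistency metric, not a verdict.
    """
    a, c = set(active), set(contacts)
    union = a | c
    inter = a & c
    return {
        "jaccard": len(inter) / len(union) if union else 0.0,
        "n_active": len(a),
        "n_contacts": len(c),
        "n_overlap": len(inter),
    }


def bound_fraction(ratio: np.ndarray, kd_um: float, protein_conc_um: float) -> np.ndarray:
    """Fraction of protein bound in a 1:1 equilibrium with ligand depletion.

    ``ratio`` is total ligand : total protein; the quadratic (exact mass
    balance) solution is used, so the stoichiometric Kd → 0 limit gives a
    piecewise-linear curve with a breakpoint at ratio 1.
    """
    p0 = protein_conc_um
    l0 = np.asarray(ratio, dtype=float) * p0
    s = p0 + l0 + kd_um
    return (s - np.sqrt(s * s - 4.0 * p0 * l0)) / (2.0 * p0)


def fit_fast_exchange_kd(
    series: TitrationSeries,
    residues: Sequence[tuple[str, int]] | None = None,
    alpha: float = NITROGEN_SCALE,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    monotonicity_tol: float = 0.25,
) -> dict:
    """Global fast-exchange fit: one shared Kd, one Δδmax per residue.

    In fast exchange the observed CSP of residue *i* at titration point *x*
    is ``Δδmax_i · f_bound(x; Kd)``.  For a fixed Kd the Δδmax are linear, so
    the fit profiles them out and minimises over Kd alone.  The confidence
    interval is a bootstrap over residues (resampling which residues inform
    the shared Kd).
    """
    if len(series.ratios) < 4:
        raise ValueError("need at least 4 titration points")
    profile = csp_profile(series, alpha)
    if residues is None:
        residues = sorted(classify_perturbed(profile))
    if not residues:
        raise ValueError("no residues to fit")
    csp = np.array([profile.trajectories[r] for r in residues])  # (n_res, n_points)
    ratios = np.asarray(series.ratios)
    for r, row in zip(residues, csp):
        drops = np.diff(row) < -monotonicity_tol * max(row.max(), 1e-12)
        if drops.any():
            warnings.warn(f"non-monotone CSP trajectory for residue {r}", stacklevel=2)

    p0 = series.protein_conc_um

    def sse_for(kd_um: float, rows: np.ndarray) -> float:
        fb = bound_fraction(ratios, kd_um, p0)
        denom = float(fb @ fb)
        if denom == 0:
            return float(np.sum(rows**2))
        dmax = rows @ fb / denom
        resid = rows - np.outer(dmax, fb)
        return float(np.sum(resid**2))

    def solve(rows: np.ndarray) -> float:
        res = optimize.minimize_scalar(
            lambda lk: sse_for(10.0**lk, rows),
            bounds=(-4.0, 5.0),
            method="bounded",
            options={"xatol": 1e-6},
        )
        if not res.success:
            raise RuntimeError(f"fast-exchange Kd fit failed: {res.message}")
        return 10.0**res.x

    kd = solve(csp)
    fb = bound_fraction(ratios, kd, p0)
    dmax = csp @ fb / float(fb @ fb)

    rng = np.random.default_rng(0) if rng is None else rng
    draws = []
    if len(residues) > 1:
        for _ in range(n_boot):
            idx = rng.integers(0, len(residues), size=len(residues))
            draws.append(solve(csp[idx]))
    ci = (
        (float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5)))
        if draws
        else (float("nan"), float("nan"))
    )
    return {
        "kd_um": float(kd),
        "kd_ci95_um": ci,
        "dmax_ppm": dict(zip(residues, map(float, dmax))),
        "n_residues": len(residues),
        "bootstrap_draws_um": np.asarray(draws),
    }
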