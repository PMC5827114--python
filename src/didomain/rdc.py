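"""Residual dipolar coupling back-calculation and alignment-tensor fitting.

An RDC measured for a backbone N–H bond reports the orientation of that bond
relative to the molecular alignment tensor.  For a unit bond vector *v* the
coupling is the quadratic form ``D = vᵀ A v`` with *A* a symmetric traceless
3×3 alignment tensor expressed directly in Hz.  In the tensor's principal
axis system this is the familiar

    D(θ, φ) = Da [ (3 cos²θ − 1) + (3/2) R sin²θ cos 2φ ]

with axial magnitude ``Da = Azz / 2`` and rhombicity
``R = (2/3)(Axx − Ayy)/Azz`` under the eigenvalue ordering
``|Azz| ≥ |Ayy| ≥ |Axx|`` (R ∈ [0, 2/3], sign carried by Da).

Because D is linear in the five independent tensor elements, fitting a
tensor to observed couplings is a linear least-squares problem solved by
SVD; the one- vs two-tensor comparison refits either a single tensor to all
residues or an independent tensor per rigid domain and contrasts the
observed/back-calculated correlation of the pooled predictions.  Two domains
that tumble as one unit share a tensor, so a large gain in correlation on
moving to two tensors is direct evidence that they do not.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.spatial.transform import Rotation
from scipy.stats import pearsonr

from .structures import DomainDefinition, StructureModel, nh_bond_vectors

__all__ = [
    "RdcRecord",
    "AlignmentTensor",
    "RdcFitResult",
    "DegenerateGeometryError",
    "back_calculate",
    "fit_tensor_svd",
    "tensor_parameters",
    "compare_tensor_models",
]

CONDITION_NUMBER_LIMIT = 1e4


class DegenerateGeometryError(ValueError):
    """Bond-vector geometry cannot determine the five tensor elements."""


@dataclasses.dataclass(frozen=True)
class RdcRecord:
    residue: tuple[str, int]
    coupling_hz: float
    error_hz: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.coupling_hz):
            raise ValueError("coupling must be finite")
        if self.error_hz is not None and self.error_hz <= 0:
            raise ValueError("coupling error must be positive")


@dataclasses.dataclass(frozen=True)
class AlignmentTensor:
    """Symmetric traceless alignment tensor in Hz (Saupe-style order matrix)."""

    saupe: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.saupe, dtype=float)
        if s.shape != (3, 3):
            raise ValueError("tensor must be 3x3")
        if not np.allclose(s, s.T, atol=1e-9):
            raise ValueError("tensor must be symmetric")
        if abs(np.trace(s)) > 1e-10 * max(1.0, np.abs(s).max()):
            raise ValueError("tensor must be traceless")
        object.__setattr__(self, "saupe", s)

    @classmethod
    def from_parameters(
        cls, da_hz: float, rhombicity: float, rotation: np.ndarray | None = None
    ) -> "AlignmentTensor":
        """Build from axial magnitude, rhombicity and a principal-frame rotation.

        ``rotation`` maps principal-axis-system coordinates to the molecular
        frame (columns are the principal axes).
        """
        if not 0.0 <= rhombicity <= 2.0 / 3.0 + 1e-12:
            raise ValueError("rhombicity must lie in [0, 2/3]")
        azz = 2.0 * da_hz
        axx = -da_hz * (1.0 - 1.5 * rhombicity)
        ayy = -da_hz * (1.0 + 1.5 * rhombicity)
        pas = np.diag([axx, ayy, azz])
        if rotation is None:
            rotation = np.eye(3)
        rotation = np.asarray(rotation, dtype=float)
        return cls(rotation @ pas @ rotation.T)

    @property
    def da_hz(self) -> float:
        return tensor_parameters(self)[0]

    @property
    def rhombicity(self) -> float:
        return tensor_parameters(self)[1]


@dataclasses.dataclass(frozen=True)
class RdcFitResult:
    tensor: AlignmentTensor
    residues: tuple[tuple[str, int], ...]
    observed_hz: np.ndarray
    predicted_hz: np.ndarray
    r: float
    q_factor: float
    rmsd_hz: float
    condition_number: float


def _check_unit(vectors: np.ndarray) -> np.ndarray:
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("bond vectors must be unit length to 1e-6")
    return v


def back_calculate(vectors: Sequence[np.ndarray] | np.ndarray, tensor: AlignmentTensor) -> np.ndarray:
    """Couplings (Hz) for unit bond vectors: ``D_i = v_iᵀ A v_i``."""
    v = _check_unit(vectors)
    return np.einsum("ni,ij,nj->n", v, tensor.saupe, v)


def _design_matrix(v: np.ndarray) -> np.ndarray:
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    return np.column_stack([x * x - z * z, y * y - z * z, 2 * x * y, 2 * x * z, 2 * y * z])


def _tensor_from_elements(p: np.ndarray) -> AlignmentTensor:
    axx, ayy, axy, axz, ayz = p
    azz = -axx - ayy
    return AlignmentTensor(np.array([[axx, axy, axz], [axy, ayy, ayz], [axz, ayz, azz]]))


def fit_tensor_svd(
    vectors: Sequence[np.ndarray] | np.ndarray,
    observed: Sequence[RdcRecord],
    condition_limit: float = CONDITION_NUMBER_LIMIT,
) -> RdcFitResult:
    """Least-squares (SVD) fit of the five tensor elements to observed RDCs.

    ``vectors`` must be ordered like ``observed``.  When per-record errors
    are present on every record the fit is error-weighted.
    """
    records = list(observed)
    if len(records) < 5:
        raise ValueError(f"need at least 5 RDC records, got {len(records)}")
    v = _check_unit(vectors)
    if len(v) != len(records):
        raise ValueError("vectors and records must align")
    d_obs = np.array([r.coupling_hz for r in records])
    m = _design_matrix(v)
    cond = float(np.linalg.cond(m))
    if cond > condition_limit:
        raise DegenerateGeometryError(
            f"design-matrix condition number {cond:.3g} exceeds {condition_limit:.3g}; "
            "bond vectors are too close to coplanar/parallel"
        )
    errors = [r.error_hz for r in records]
    if all(e is not None for e in errors):
        w = 1.0 / np.asarray(errors, dtype=float)
        params, *_ = np.linalg.lstsq(m * w[:, None], d_obs * w, rcond=None)
    else:
        params, *_ = np.linalg.lstsq(m, d_obs, rcond=None)
    tensor = _tensor_from_elements(params)
    d_calc = back_calculate(v, tensor)
    resid = d_obs - d_calc
    rmsd = float(np.sqrt(np.mean(resid**2)))
    q = rmsd / float(np.sqrt(np.mean(d_obs**2)))
    r = float(pearsonr(d_obs, d_calc)[0]) if np.std(d_calc) > 0 and np.std(d_obs) > 0 else 0.0
    return RdcFitResult(
        tensor=tensor,
        residues=tuple(rec.residue for rec in records),
        observed_hz=d_obs,
        predicted_hz=d_calc,
        r=r,
        q_factor=q,
        rmsd_hz=rmsd,
        condition_number=cond,
    )


def tensor_parameters(tensor: AlignmentTensor) -> tuple[float, float, tuple[float, float, float]]:
    """Decompose into (Da [Hz], rhombicity, ZYZ Euler angles [rad]).

    Eigenvalues are ordered ``|Azz| ≥ |Ayy| ≥ |Axx|``; ``Da = Azz / 2``;
    ``R = (2/3)(Axx − Ayy)/Azz`` which lands in [0, 2/3] under this
    ordering.  The Euler angles rotate the molecular frame onto the
    principal axis system.
    """
    eigval, eigvec = np.linalg.eigh(tensor.saupe)
    order = np.argsort(np.abs(eigval))  # |Axx| <= |Ayy| <= |Azz|
    axx, ayy, azz = eigval[order]
    frame = eigvec[:, order]
    if np.linalg.det(frame) < 0:
        frame[:, 0] *= -1
    da = azz / 2.0
    rhomb = (2.0 / 3.0) * (axx - ayy) / azz if azz != 0 else 0.0
    rhomb = float(np.clip(rhomb, 0.0, 2.0 / 3.0))
    euler = tuple(Rotation.from_matrix(frame).as_euler("ZYZ"))
    return float(da), rhomb, euler


def compare_tensor_models(
    structure: StructureModel,
    domains: tuple[DomainDefinition, DomainDefinition],
    rdcs: Sequence[RdcRecord],
    add_ideal_h: bool = True,
) -> dict:
    """One- vs two-tensor fit of observed RDCs to a structure.

    The single-tensor model assumes both domains tumble as one rigid body;
    the two-tensor model fits an independent tensor per domain.  The
    two-tensor correlation ``r_multi`` is computed on the pooled
    per-domain predictions, mirroring how a concatenated two-domain fit is
    reported.  Returns a dict with keys ``single``, ``multi``, ``r_single``,
    ``r_multi``, ``q_single`` and ``q_multi``.
    """
    vecs, _ = nh_bond_vectors(structure, add_ideal_h=add_ideal_h)
    vec_by_res: Mapping[tuple[str, int], np.ndarray] = dict(vecs)
    usable = [r for r in rdcs if r.residue in vec_by_res]
    per_domain: list[list[RdcRecord]] = [[], []]
    for rec in usable:
        for k, dom in enumerate(domains):
            if dom.contains(*rec.residue):
                per_domain[k].append(rec)
                break
    for dom, recs in zip(domains, per_domain):
        if len(recs) < 5:
            raise ValueError(
                f"domain {dom.name!r} contributes only {len(recs)} usable RDCs (need >= 5)"
            )

    pooled = per_domain[0] + per_domain[1]
    v_pooled = np.array([vec_by_res[r.residue] for r in pooled])
    single = fit_tensor_svd(v_pooled, pooled)

    multi: list[RdcFitResult] = []
    for recs in per_domain:
        v_dom = np.array([vec_by_res[r.residue] for r in recs])
        multi.append(fit_tensor_svd(v_dom, recs))

    obs = np.concatenate([f.observed_hz for f in multi])
    calc = np.concatenate([f.predicted_hz for f in multi])
    r_multi = float(pearsonr(obs, calc)[0])
    q_multi = float(np.sqrt(np.mean((obs - calc) ** 2)) / np.sqrt(np.mean(obs**2)))
    return {
        "single": single,
        "multi": multi,
        "r_single": single.r,
        "r_multi": r_multi,
        "q_single": single.q_factor,
        "q_multi": q_multi,
    }
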