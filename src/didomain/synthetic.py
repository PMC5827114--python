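"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the statistical structure of a two-domain RNA-binding
protein study in which the raw measurements are not deposited: two compact
helical pseudo-domains joined by a flexible linker, with

* per-domain alignment tensors and rotational correlation times (shared in
  the ``rigid`` scenario, distinct in ``dynamic``/``detached``),
* fast-exchange CSP titrations localised to the inter-domain interface
  (absent in ``detached``),
* 1:1 Langmuir binding isotherms with additive noise, and
* four-pools-per-position SIA data generated from a known base-preference
  matrix.

Default parameters are the study conditions: domain τc 10.0 and 11.8 ns at
600 MHz, tensors (Da −17.7 Hz, R 0.22) and (−18.0 Hz, 0.31) with principal
frames 90° apart, titration Kd 29 µM at 50 µM protein over ratios 0–6,
isotherm Kd values 2.0 nM (50–0.78 nM series) and 29 µM (400–6.25 µM
series), a ~6-fold affinity loss for the mutant RNA, and a G-preferring
specificity at positions 1–2 with discrimination against U at position 3.

The toy structure itself is deterministic (no randomness); the seed drives
only the measurement noise, so every generator is reproducible per seed.
"""

from __future__ import annotations

import dataclasses
import math
from functools import lru_cache

import numpy as np

from . import relaxation as rx
from .binding import BindingSeries
from .rdc import AlignmentTensor, RdcRecord
from .relaxation import RelaxationRecord
from .sia import BASES, SiaPoolMeasurement
from .structures import Atom, DomainDefinition, StructureModel, contact_residues, nh_bond_vectors
from .titration import ShiftRecord, TitrationSeries, bound_fraction

__all__ = [
    "ScenarioSpec",
    "make_toy_didomain",
    "toy_domain_definitions",
    "interface_residues",
    "synth_rdc",
    "synth_relaxation",
    "synth_titration",
    "synth_isotherm",
    "synth_sia_pools",
]

SCENARIOS = ("rigid", "dynamic", "detached")

#: default per-position base-preference matrix (rows: positions 1..3,
#: columns A, C, G, U): G preferred at positions 1 and 2, U discriminated
#: against at position 3.
DEFAULT_SPECIFICITY = np.array(
    [
        [0.20, 0.15, 0.50, 0.15],
        [0.20, 0.15, 0.50, 0.15],
        [0.30, 0.33, 0.32, 0.05],
    ]
)


@dataclasses.dataclass(frozen=True)
class ScenarioSpec:
    """Fully determines one synthetic dataset (scenario + seed + noise levels)."""

    seed: int
    scenario: str = "dynamic"
    tauc_ns: tuple[float, float] = (10.0, 11.8)
    tensor_a: tuple[float, float] = (-17.7, 0.22)  # (Da [Hz], R)
    tensor_b: tuple[float, float] = (-18.0, 0.31)
    tensor_b_rotation_deg: float = 90.0  # principal-frame offset about y
    field_mhz: float = 600.0
    protein_conc_um: float = 50.0
    titration_kd_um: float = 29.0
    titration_ratios: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0)
    kd_high_nm: float = 2.0
    kd_moderate_um: float = 29.0
    mutant_fold_change: float = 6.0
    specificity: tuple[tuple[float, ...], ...] = tuple(map(tuple, DEFAULT_SPECIFICITY))
    rdc_noise_hz: float = 1.0
    relax_noise_frac: float = 0.03
    noe_sigma: float = 0.05
    csp_active_mean_ppm: float = 0.08
    csp_active_sd_ppm: float = 0.02
    csp_background_sd_ppm: float = 0.005
    csp_noise_frac: float = 0.02
    bli_noise_frac: float = 0.03
    sia_noise_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")

    @classmethod
    def preset(cls, scenario: str, seed: int) -> "ScenarioSpec":
        if scenario == "rigid":
            # one rigid unit: shared tensor and shared (larger-particle) tauc
            return cls(
                seed=seed,
                scenario="rigid",
                tauc_ns=(11.8, 11.8),
                tensor_b=(-17.7, 0.22),
                tensor_b_rotation_deg=0.0,
            )
        return cls(seed=seed, scenario=scenario)

    def rng(self, channel: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, channel])

    def tensors(self) -> tuple[AlignmentTensor, AlignmentTensor]:
        ta = AlignmentTensor.from_parameters(*self.tensor_a)
        theta = math.radians(self.tensor_b_rotation_deg)
        rot = np.array(
            [
                [math.cos(theta), 0.0, math.sin(theta)],
                [0.0, 1.0, 0.0],
                [-math.sin(theta), 0.0, math.cos(theta)],
            ]
        )
        tb = AlignmentTensor.from_parameters(*self.tensor_b, rotation=rot)
        return ta, tb


# ---------------------------------------------------------------------------
# toy structure


_BOND = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C-O": 1.231, "N-H": 1.02}
_ANGLE = {"N-CA-C": 111.2, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C-O": 120.8}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom d after a-b-c."""
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-math.cos(ang), math.sin(ang) * math.cos(tor), math.sin(ang) * math.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_segment(n_res: int, phi: float, psi: float) -> list[dict[str, np.ndarray]]:
    """Backbone (N, H, CA, C, O) for an ideal-torsion segment; GLY geometry."""
    res: list[dict[str, np.ndarray]] = []
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BOND["N-CA"], 0.0, 0.0])
    c0 = _place(np.array([0.0, 1.0, 0.0]), n0, ca0, _BOND["CA-C"], _ANGLE["N-CA-C"], 60.0)
    res.append({"N": n0, "CA": ca0, "C": c0})
    for i in range(1, n_res):
        prev = res[-1]
        n = _place(prev["N"], prev["CA"], prev["C"], _BOND["C-N"], _ANGLE["CA-C-N"], psi)
        ca = _place(prev["CA"], prev["C"], n, _BOND["N-CA"], _ANGLE["C-N-CA"], 180.0)
        c = _place(prev["C"], n, ca, _BOND["CA-C"], _ANGLE["N-CA-C"], phi)
        # carbonyl O of the previous residue, anti to the new amide N
        prev["O"] = _place(n, prev["CA"], prev["C"], _BOND["C-O"], _ANGLE["CA-C-O"], 180.0)
        # amide H: bisector of the CA and preceding-carbonyl directions
        u1 = (n - ca) / np.linalg.norm(n - ca)
        u2 = (n - prev["C"]) / np.linalg.norm(n - prev["C"])
        h_dir = u1 + u2
        h_dir /= np.linalg.norm(h_dir)
        res.append({"N": n, "CA": ca, "C": c, "H": n + _BOND["N-H"] * h_dir})
    # terminal carbonyl O (torsion relative to own N)
    last = res[-1]
    last["O"] = _place(last["N"], last["CA"], last["C"], _BOND["C-O"], _ANGLE["CA-C-O"], psi + 180.0)
    return res


def _helix(n_res: int) -> list[dict[str, np.ndarray]]:
    return _build_segment(n_res, phi=-57.0, psi=-47.0)


def _principal_axis(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords - center)
    axis = vt[0]
    if axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return center, axis


def _orient_segment(
    residues: list[dict[str, np.ndarray]], axis: np.ndarray, center: np.ndarray
) -> list[dict[str, np.ndarray]]:
    """Rigidly move a built segment so its CA principal axis matches ``axis``."""
    ca = np.array([r["CA"] for r in residues])
    c0, a0 = _principal_axis(ca)
    target = np.asarray(axis, float)
    target = target / np.linalg.norm(target)
    v = np.cross(a0, target)
    s, c = np.linalg.norm(v), float(a0 @ target)
    if s < 1e-12:
        rot = np.eye(3) if c > 0 else -np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        rot = np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)
    out = []
    for r in residues:
        out.append({k: rot @ (p - c0) + np.asarray(center, float) for k, p in r.items()})
    return out


_HELIX_LEN = 12
_SEG_LAYOUT = [
    # (first resnum, axis, center, kind)
    (1, (0, 0, 1), (-12.0, 0.0, 0.0), "helix"),  # domain A bundle
    (13, (1, 0, 0), (-12.0, 11.0, 0.0), "helix"),
    (25, (0, 1, 0), (0.0, 0.0, 0.0), "helix"),  # interface helix of A
    (37, (1, 0, 0), (0.0, -16.0, 0.0), "linker"),
    (45, (0, 1, 0), (7.2, 0.0, 0.0), "helix"),  # interface helix of B
    (57, (0, 0, 1), (19.2, 0.0, 0.0), "helix"),
    (69, (1, 0, 0), (19.2, 11.0, 0.0), "helix"),
]
_LINKER_LEN = 8
_LINKER_PRO = 40  # one proline in the linker exercises amide-skipping
_DETACH_SHIFT = 40.0


def toy_domain_definitions() -> tuple[DomainDefinition, DomainDefinition]:
    dom_a = DomainDefinition("N", "A", ((1, 36),))
    dom_b = DomainDefinition("eR1", "A", ((45, 80),))
    return dom_a, dom_b


def linker_residue_ids() -> list[tuple[str, int]]:
    return [("A", n) for n in range(37, 37 + _LINKER_LEN)]


@lru_cache(maxsize=4)
def make_toy_didomain(
    detached: bool = False,
) -> tuple[StructureModel, DomainDefinition, DomainDefinition]:
    """Deterministic two-domain toy structure (three-helix bundles + linker).

    Domains A (residues 1–36) and B (45–80) each comprise three ideal
    12-residue helices with mutually orthogonal axes (good orientational
    sampling for tensor fitting); the facing helices 25–36 and 45–56 form
    the inter-domain interface.  With ``detached`` the B domain is shifted
    40 Å away, leaving no contacts and ≈ 0 buried surface.
    """
    atoms: list[Atom] = []
    for first, axis, center, kind in _SEG_LAYOUT:
        if kind == "helix":
            built = _orient_segment(_helix(_HELIX_LEN), np.array(axis, float), center)
            n_res = _HELIX_LEN
        else:
            built = _orient_segment(
                _build_segment(_LINKER_LEN, phi=-120.0, psi=120.0), np.array(axis, float), center
            )
            n_res = _LINKER_LEN
        for i in range(n_res):
            resnum = first + i
            resname = "PRO" if resnum == _LINKER_PRO else "GLY"
            shift = np.array([_DETACH_SHIFT, 0.0, 0.0]) if (detached and resnum >= 45) else 0.0
            for name in ("N", "H", "CA", "C", "O"):
                pos = built[i].get(name)
                if pos is None or (name == "H" and resname == "PRO"):
                    continue
                pos = pos + shift
                atoms.append(
                    Atom(
                        chain="A",
                        resnum=resnum,
                        resname=resname,
                        name=name,
                        element="H" if name == "H" else name[0],
                        xyz=(round(float(pos[0]), 3), round(float(pos[1]), 3), round(float(pos[2]), 3)),
                    )
                )
    dom_a, dom_b = toy_domain_definitions()
    return StructureModel(atoms), dom_a, dom_b


def interface_residues(
    model: StructureModel,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
    cutoff: float = 5.0,
) -> set[tuple[str, int]]:
    """Ground-truth interface: residues appearing in any inter-domain contact."""
    pairs = contact_residues(model, dom_a, dom_b, cutoff=cutoff)
    out: set[tuple[str, int]] = set()
    for ra, rb in pairs:
        out.add(ra)
        out.add(rb)
    return out


# ---------------------------------------------------------------------------
# measurement generators


def synth_rdc(
    model: StructureModel,
    spec: ScenarioSpec,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
) -> list[RdcRecord]:
    """RDCs from per-domain tensors (shared in the rigid scenario) + noise."""
    rng = spec.rng(1)
    tensor_a, tensor_b = spec.tensors()
    vectors, _ = nh_bond_vectors(model)
    records: list[RdcRecord] = []
    from .rdc import back_calculate

    for rid, vec in vectors:
        if dom_a.contains(*rid):
            tensor = tensor_a
        elif dom_b.contains(*rid):
            tensor = tensor_b
        else:
            continue  # linker residues carry no rigid-body RDC information
        d = float(back_calculate(vec[None, :], tensor)[0])
        noise = rng.normal(0.0, spec.rdc_noise_hz) if spec.rdc_noise_hz > 0 else 0.0
        err = spec.rdc_noise_hz if spec.rdc_noise_hz > 0 else None
        records.append(RdcRecord(residue=rid, coupling_hz=d + noise, error_hz=err))
    return records


def synth_relaxation(
    spec: ScenarioSpec,
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
) -> list[RelaxationRecord]:
    """Per-residue T1/T2/hetNOE from the forward model at each domain's τc.

    Domain residues get relaxation simulated at the domain τc with
    fractional Gaussian noise on T1 and T2 and additive noise on the NOE;
    linker residues emulate fast internal motion (low hetNOE around 0.3,
    short effective τc).
    """
    rng = spec.rng(2)
    records: list[RelaxationRecord] = []

    def emit(rid: tuple[str, int], tauc: float, noe_center: float | None) -> None:
        t1, t2, noe = rx.simulate_relaxation(tauc, spec.field_mhz)
        t1 *= 1.0 + rng.normal(0.0, spec.relax_noise_frac)
        t2 *= 1.0 + rng.normal(0.0, spec.relax_noise_frac)
        base_noe = noe if noe_center is None else noe_center
        noe_obs = min(base_noe + rng.normal(0.0, spec.noe_sigma), 1.0)
        records.append(
            RelaxationRecord(
                residue=rid,
                t1_s=t1,
                t2_s=t2,
                hetnoe=noe_obs,
                field_mhz=spec.field_mhz,
                t1_err=spec.relax_noise_frac * t1,
                t2_err=spec.relax_noise_frac * t2,
                noe_err=spec.noe_sigma,
            )
        )

    for rid in dom_a.residue_ids():
        emit(rid, spec.tauc_ns[0], noe_center=0.8)
    for rid in dom_b.residue_ids():
        emit(rid, spec.tauc_ns[1], noe_center=0.8)
    for rid in linker_residue_ids():
        emit(rid, 4.0, noe_center=0.3)
    return records


def synth_titration(
    spec: ScenarioSpec,
    actives: set[tuple[str, int]],
    dom_a: DomainDefinition,
    dom_b: DomainDefinition,
) -> TitrationSeries:
    """Fast-exchange titration with CSPs concentrated on ``actives``.

    In the detached scenario the active set is forced empty: the domains do
    not report each other's interface.  Endpoint magnitudes: actives
    ~ N(0.08, 0.02) ppm (clipped positive), background ~ |N(0, 0.005)| ppm.
    """
    rng = spec.rng(3)
    if spec.scenario == "detached":
        actives = set()
    residues = dom_a.residue_ids() + dom_b.residue_ids()
    dmax: dict[tuple[str, int], tuple[float, float]] = {}
    free: dict[tuple[str, int], ShiftRecord] = {}
    for rid in residues:
        if rid in actives:
            mag = max(rng.normal(spec.csp_active_mean_ppm, spec.csp_active_sd_ppm), 0.01)
        else:
            mag = abs(rng.normal(0.0, spec.csp_background_sd_ppm))
        theta = rng.uniform(0.0, 2.0 * math.pi)
        # split the combined CSP into 1H and (scaled) 15N components
        dh = mag * math.cos(theta)
        dn = mag * math.sin(theta) / 0.154
        dmax[rid] = (dh, dn)
        free[rid] = ShiftRecord(rid, rng.uniform(7.0, 9.5), rng.uniform(105.0, 130.0))

    ratios = spec.titration_ratios
    fb = bound_fraction(np.asarray(ratios), spec.titration_kd_um, spec.protein_conc_um)
    tables = []
    for k, f in enumerate(fb):
        table: dict[tuple[str, int], ShiftRecord] = {}
        for rid in residues:
            dh, dn = dmax[rid]
            mag = math.hypot(dh, 0.154 * dn)
            noise_h = rng.normal(0.0, spec.csp_noise_frac * mag) if k > 0 else 0.0
            noise_n = rng.normal(0.0, spec.csp_noise_frac * mag / 0.154) if k > 0 else 0.0
            table[rid] = ShiftRecord(
                rid,
                free[rid].dh_ppm + f * dh + noise_h,
                free[rid].dn_ppm + f * dn + noise_n,
            )
        tables.append(table)
    return TitrationSeries(
        ratios=ratios, shifts=tuple(tables), protein_conc_um=spec.protein_conc_um
    )


def _dilution_series(top: float, n: int = 7) -> np.ndarray:
    return top / (2.0 ** np.arange(n))[::-1]


def synth_isotherm(spec: ScenarioSpec) -> dict[str, BindingSeries]:
    """BLI plateau series: high-affinity, moderate-affinity and a WT/mutant pair.

    * ``high``: Kd 2.0 nM over a 2× dilution series 50 → 0.78 nM,
    * ``moderate``: Kd 29 µM over 400 → 6.25 µM,
    * ``wt``/``mutant``: the high-affinity design with a true 6-fold Kd ratio.

    Rmax is 1 instrument unit; noise is additive Gaussian at 3 % of Rmax.
    """
    rng = spec.rng(4)
    out: dict[str, BindingSeries] = {}

    def series(kd_m: float, conc_m: np.ndarray, label: str) -> BindingSeries:
        resp = conc_m / (kd_m + conc_m)
        resp = resp + rng.normal(0.0, spec.bli_noise_frac, size=len(conc_m))
        return BindingSeries(conc_m=conc_m, response=resp, label=label)

    nm = _dilution_series(50e-9)
    um = _dilution_series(400e-6)
    out["high"] = series(spec.kd_high_nm * 1e-9, nm, "high-affinity")
    out["moderate"] = series(spec.kd_moderate_um * 1e-6, um, "moderate-affinity")
    out["wt"] = series(spec.kd_high_nm * 1e-9, nm, "wild-type RNA")
    out["mutant"] = series(spec.kd_high_nm * 1e-9 * spec.mutant_fold_change, nm, "mutant RNA")
    return out


def synth_sia_pools(
    spec: ScenarioSpec, n_reporters: int = 8, csp_scale_ppm: float = 0.32
) -> list[SiaPoolMeasurement]:
    """Four pools per position from the spec's true specificity matrix.

    Each reporter residue has a fixed sensitivity factor (constant across
    the four pools of a position, so it cancels in the share normalisation);
    multiplicative Gaussian noise at ``sia_noise_frac`` is applied per pool.
    """
    rng = spec.rng(5)
    truth = np.asarray(spec.specificity, dtype=float)
    reporters = [("A", 100 + i) for i in range(n_reporters)]
    sensitivity = rng.uniform(0.5, 1.5, size=n_reporters)
    pools: list[SiaPoolMeasurement] = []
    for p in range(truth.shape[0]):
        for b, base in enumerate(BASES):
            csps = {}
            for r, rid in enumerate(reporters):
                value = csp_scale_ppm * truth[p, b] * sensitivity[r]
                value *= 1.0 + rng.normal(0.0, spec.sia_noise_frac)
                csps[rid] = max(value, 0.0)
            pools.append(SiaPoolMeasurement(position=p + 1, base=base, reporter_csp_ppm=csps))
    return pools
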