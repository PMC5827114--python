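"""Integration of the three coupling-evidence channels into one verdict.

Three independent NMR observables report on whether two tethered domains
tumble as one rigid unit:

1. CSP/crystal-contact overlap — do solution perturbations map onto the
   crystallographic interface (is the crystal conformer populated)?
2. Δτc — do the domains share a rotational correlation time?
3. RDC one- vs two-tensor fit — does a single alignment tensor explain the
   couplings of both domains?

The decision rule (explicit, presentation-layer thresholds):

* ``rigidly-coupled``  iff r_single ≥ 0.9 and Δτc not significant (α 0.05),
* ``detached``         iff the CSP/contact Jaccard < 0.2,
* ``dynamically-coupled`` otherwise (an interface is populated but the
  domains do not share a tensor / correlation time).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

from .relaxation import DomainTaucEstimate, compare_domain_tauc

__all__ = ["CouplingVerdict", "THRESHOLDS", "assess_coupling", "render_report", "read_report"]

THRESHOLDS = {"r_single_rigid": 0.9, "jaccard_detached": 0.2, "tauc_alpha": 0.05}


@dataclasses.dataclass(frozen=True)
class CouplingVerdict:
    verdict: str  # rigidly-coupled | dynamically-coupled | detached
    csp_contact_jaccard: float | None
    delta_tauc_ns: float | None
    delta_tauc_p: float | None
    r_single: float | None
    r_multi: float | None
    partial: bool
    missing_channels: tuple[str, ...]
    notes: tuple[str, ...]
    thresholds: dict = dataclasses.field(default_factory=lambda: dict(THRESHOLDS))


def assess_coupling(
    csp_overlap: dict | None,
    tauc_estimates: tuple[DomainTaucEstimate, DomainTaucEstimate] | None,
    rdc_comparison: dict | None,
    thresholds: dict | None = None,
) -> CouplingVerdict:
    """Combine the evidence channels into a :class:`CouplingVerdict`.

    Any missing channel yields a partial verdict computed from the evidence
    that is present.
    """
    thr = dict(THRESHOLDS if thresholds is None else thresholds)
    missing = []
    notes = []

    jaccard = None
    if csp_overlap is not None:
        jaccard = float(csp_overlap["jaccard"])
        notes.append(
            f"CSP-active vs crystal-contact Jaccard {jaccard:.2f} "
            f"({csp_overlap['n_overlap']}/{csp_overlap['n_active']} active residues on the interface)"
        )
    else:
        missing.append("csp")

    delta = p_val = None
    if tauc_estimates is not None:
        cmp = compare_domain_tauc(*tauc_estimates)
        delta, p_val = cmp["delta_tauc_ns"], cmp["p_value"]
        a, b = tauc_estimates
        notes.append(
            f"tauc {a.domain} {a.tauc_ns:.1f} ± {a.sd_ns:.1f} ns vs "
            f"{b.domain} {b.tauc_ns:.1f} ± {b.sd_ns:.1f} ns (p = {p_val:.2g})"
        )
    else:
        missing.append("tauc")

    r_single = r_multi = None
    if rdc_comparison is not None:
        r_single = float(rdc_comparison["r_single"])
        r_multi = float(rdc_comparison["r_multi"])
        notes.append(f"RDC correlation: one tensor r = {r_single:.3f}, two tensors r = {r_multi:.3f}")
    else:
        missing.append("rdc")

    tauc_not_significant = p_val is not None and p_val >= thr["tauc_alpha"]
    rigid = r_single is not None and r_single >= thr["r_single_rigid"] and (
        tauc_not_significant or p_val is None
    )
    if rigid:
        verdict = "rigidly-coupled"
    elif jaccard is not None and jaccard < thr["jaccard_detached"]:
        verdict = "detached"
    else:
        verdict = "dynamically-coupled"

    return CouplingVerdict(
        verdict=verdict,
        csp_contact_jaccard=jaccard,
        delta_tauc_ns=delta,
        delta_tauc_p=p_val,
        r_single=r_single,
        r_multi=r_multi,
        partial=bool(missing),
        missing_channels=tuple(missing),
        notes=tuple(notes),
        thresholds=thr,
    )


def render_report(verdict: CouplingVerdict, stages: dict | None = None) -> tuple[dict, str]:
    """Machine-readable dict plus a human-readable text summary."""
    payload = {
        "verdict": verdict.verdict,
        "partial": verdict.partial,
        "missing_channels": list(verdict.missing_channels),
        "thresholds": verdict.thresholds,
        "channels": {
            "csp_contact_jaccard": verdict.csp_contact_jaccard,
            "delta_tauc_ns": verdict.delta_tauc_ns,
            "delta_tauc_p": verdict.delta_tauc_p,
            "r_single": verdict.r_single,
            "r_multi": verdict.r_multi,
        },
        "notes": list(verdict.notes),
    }
    if stages:
        payload["stages"] = stages
    lines = [
        "Inter-domain coupling report",
        "===========================",
        f"Verdict: {verdict.verdict}" + (" (partial evidence)" if verdict.partial else ""),
        "",
    ]
    for ch, value in payload["channels"].items():
        shown = "absent" if value is None else f"{value:.4g}"
        lines.append(f"  {ch:22s} {shown}")
    lines.append("")
    lines.extend(f"  - {n}" for n in verdict.notes)
    if verdict.missing_channels:
        lines.append(f"  ! missing channels: {', '.join(verdict.missing_channels)}")
    lines.append("")
    lines.append(
        "Thresholds: "
        + ", ".join(f"{k} = {v}" for k, v in verdict.thresholds.items())
    )
    return payload, "\n".join(lines)


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
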