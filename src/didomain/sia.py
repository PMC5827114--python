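"""Scaffold-independent analysis (SIA): per-position nucleobase preferences.

SIA probes the sequence specificity of an RNA-binding domain by comparing
its NMR response to quasi-degenerate RNA pools.  For each position of the
bound sequence, four pools fix that position to A, C, G or U while the
remaining positions are randomised; the size of the chemical shift
perturbations of a set of reporter residues measures how well each base is
accommodated.  Here the per-position score of base *b* is the mean reporter
CSP for the pool fixing *b*, normalised so the four scores sum to one —
the relative column heights of a specificity logo.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BASES",
    "SiaPoolMeasurement",
    "sia_scores",
    "consensus",
]

BASES = ("A", "C", "G", "U")


@dataclasses.dataclass(frozen=True)
class SiaPoolMeasurement:
    """CSPs of reporter residues for one pool (one position, one fixed base)."""

    position: int
    base: str
    reporter_csp_ppm: Mapping[tuple[str, int], float]

    def __post_init__(self) -> None:
        if self.base not in BASES:
            raise ValueError(f"base must be one of {BASES}, got {self.base!r}")
        if self.position < 1:
            raise ValueError("positions are 1-based")
        if any(v < 0 for v in self.reporter_csp_ppm.values()):
            raise ValueError("CSPs must be non-negative")


def sia_scores(
    measurements: Sequence[SiaPoolMeasurement],
    reporters: Sequence[tuple[str, int]] | None = None,
    aggregate: str = "mean",
) -> pd.DataFrame:
    """Specificity matrix (positions × A,C,G,U), each row summing to 1.

    ``reporters`` restricts the reporter-residue set (default: the residues
    shared by all pools of each position).  ``aggregate`` is ``"mean"`` or
    ``"median"`` over reporters.  A position where all four pools show zero
    CSP carries no preference information and is set to the uniform 0.25
    with a warning.
    """
    if aggregate not in {"mean", "median"}:
        raise ValueError("aggregate must be 'mean' or 'median'")
    agg = np.mean if aggregate == "mean" else np.median
    by_pos: dict[int, dict[str, SiaPoolMeasurement]] = {}
    for m in measurements:
        slot = by_pos.setdefault(m.position, {})
        if m.base in slot:
            raise ValueError(f"duplicate pool for position {m.position} base {m.base}")
        slot[m.base] = m

    rows = {}
    for pos in sorted(by_pos):
        pools = by_pos[pos]
        missing = [b for b in BASES if b not in pools]
        if missing:
            raise ValueError(f"position {pos}: missing pool(s) for base(s) {missing}")
        shared = set.intersection(*(set(pools[b].reporter_csp_ppm) for b in BASES))
        use = list(shared if reporters is None else (shared & set(reporters)))
        if not use:
            raise ValueError(f"position {pos}: no common reporter residues")
        raw = np.array([agg([pools[b].reporter_csp_ppm[r] for r in use]) for b in BASES])
        total = raw.sum()
        if total == 0:
            warnings.warn(
                f"position {pos}: all-zero CSPs, assigning uniform scores", stacklevel=2
            )
            rows[pos] = np.full(4, 0.25)
        else:
            rows[pos] = raw / total
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(BASES)).sort_index()


def consensus(
    matrix: pd.DataFrame, strong: float = 0.4, weak: float = 0.15
) -> dict[int, str]:
    """Human-readable per-position preference labels.

    Presentation-layer thresholds: the top base is called strongly preferred
    when its score is at least ``strong``; bases scoring below ``weak`` are
    annotated as discriminated against ("not-X"); a position with neither is
    "N".  Ties are broken alphabetically and flagged.
    """
    out: dict[int, str] = {}
    for pos, row in matrix.iterrows():
        scores = row[list(BASES)]
        top_score = scores.max()
        top_bases = sorted(scores[scores == top_score].index)
        parts: list[str] = []
        if top_score >= strong:
            tie = " [tie]" if len(top_bases) > 1 else ""
            parts.append(f"{top_bases[0]} (strong){tie}")
        anti = sorted(scores[scores < weak].index)
        parts.extend(f"not-{b}" for b in anti)
        out[int(pos)] = ", ".join(parts) if parts else "N"
    return out
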