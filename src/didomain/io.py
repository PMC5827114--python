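"""Tabular I/O for the pipeline's measurement types (TSV in, TSV/JSON out).

Residue identifiers are serialised as ``chain:resnum`` strings.  All tables
are plain tab-separated files with a header row so they can be produced and
inspected with ordinary spreadsheet / command-line tools.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import BindingSeries
from .rdc import RdcRecord
from .relaxation import RelaxationRecord
from .sia import SiaPoolMeasurement
from .titration import ShiftRecord, TitrationSeries

__all__ = [
    "write_rdc_tsv",
    "read_rdc_tsv",
    "write_relaxation_tsv",
    "read_relaxation_tsv",
    "write_titration_tsv",
    "read_titration_tsv",
    "write_sia_tsv",
    "read_sia_tsv",
    "write_binding_tsv",
    "read_binding_tsv",
    "write_json",
]


def _rid(chain: str, resnum) -> tuple[str, int]:
    return (str(chain), int(resnum))


def write_rdc_tsv(records: Sequence[RdcRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.residue[1] for r in records],
            "chain": [r.residue[0] for r in records],
            "D_obs_Hz": [r.coupling_hz for r in records],
            "err_Hz": [r.error_hz if r.error_hz is not None else np.nan for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_rdc_tsv(path: str | Path) -> list[RdcRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        err = None if pd.isna(row.err_Hz) else float(row.err_Hz)
        out.append(RdcRecord(_rid(row.chain, row.residue), float(row.D_obs_Hz), err))
    return out


def write_relaxation_tsv(records: Sequence[RelaxationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "residue": [r.residue[1] for r in records],
            "chain": [r.residue[0] for r in records],
            "T1_s": [r.t1_s for r in records],
            "T1_err": [r.t1_err for r in records],
            "T2_s": [r.t2_s for r in records],
            "T2_err": [r.t2_err for r in records],
            "NOE": [r.hetnoe for r in records],
            "NOE_err": [r.noe_err for r in records],
            "field_MHz": [r.field_mhz for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_relaxation_tsv(path: str | Path) -> list[RelaxationRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        out.append(
            RelaxationRecord(
                residue=_rid(row.chain, row.residue),
                t1_s=float(row.T1_s),
                t2_s=float(row.T2_s),
                hetnoe=float(row.NOE),
                field_mhz=float(row.field_MHz),
                t1_err=None if pd.isna(row.T1_err) else float(row.T1_err),
                t2_err=None if pd.isna(row.T2_err) else float(row.T2_err),
                noe_err=None if pd.isna(row.NOE_err) else float(row.NOE_err),
            )
        )
    return out


def write_titration_tsv(series: TitrationSeries, path: str | Path) -> None:
    rows = []
    for ratio, table in zip(series.ratios, series.shifts):
        for (chain, resnum), rec in sorted(table.items()):
            rows.append(
                {
                    "residue": resnum,
                    "chain": chain,
                    "ratio": ratio,
                    "dH_ppm": rec.dh_ppm,
                    "dN_ppm": rec.dn_ppm,
                    "protein_conc_uM": series.protein_conc_um,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_titration_tsv(path: str | Path) -> TitrationSeries:
    df = pd.read_csv(path, sep="\t")
    conc = float(df["protein_conc_uM"].iloc[0])
    ratios = sorted(df["ratio"].unique())
    tables = []
    for ratio in ratios:
        sub = df[df["ratio"] == ratio]
        table = {}
        for row in sub.itertuples():
            rid = _rid(row.chain, row.residue)
            table[rid] = ShiftRecord(rid, float(row.dH_ppm), float(row.dN_ppm))
        tables.append(table)
    return TitrationSeries(ratios=tuple(ratios), shifts=tuple(tables), protein_conc_um=conc)


def write_sia_tsv(pools: Sequence[SiaPoolMeasurement], path: str | Path) -> None:
    rows = []
    for pool in pools:
        for (chain, resnum), csp in sorted(pool.reporter_csp_ppm.items()):
            rows.append(
                {
                    "position": pool.position,
                    "base": pool.base,
                    "residue": f"{chain}:{resnum}",
                    "csp_ppm": csp,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.5f")


def read_sia_tsv(path: str | Path) -> list[SiaPoolMeasurement]:
    df = pd.read_csv(path, sep="\t")
    pools = []
    for (position, base), sub in df.groupby(["position", "base"], sort=True):
        csps = {}
        for row in sub.itertuples():
            chain, _, resnum = str(row.residue).partition(":")
            csps[(chain, int(resnum))] = float(row.csp_ppm)
        pools.append(SiaPoolMeasurement(position=int(position), base=str(base), reporter_csp_ppm=csps))
    return pools


_UNIT_TO_M = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9, "pM": 1e-12}


def write_binding_tsv(series_map: dict[str, BindingSeries], path: str | Path) -> None:
    rows = []
    for label, series in series_map.items():
        for c, r in zip(series.conc_m, series.response):
            rows.append({"conc": c * 1e6, "conc_unit": "uM", "response": r, "label": label})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.8g")


def read_binding_tsv(path: str | Path) -> dict[str, BindingSeries]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for label, sub in df.groupby("label", sort=True):
        factors = sub["conc_unit"].map(_UNIT_TO_M)
        if factors.isna().any():
            bad = sorted(set(sub["conc_unit"][factors.isna()]))
            raise ValueError(f"unknown concentration unit(s): {bad}")
        out[str(label)] = BindingSeries(
            conc_m=(sub["conc"] * factors).to_numpy(float),
            response=sub["response"].to_numpy(float),
            label=str(label),
        )
    return out


def write_json(payload: dict, path: str | Path) -> None:
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, set):
            return sorted(obj)
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
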