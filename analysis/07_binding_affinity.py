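#!/usr/bin/env python
"""Fit equilibrium Kd values to BLI plateau responses and compare constructs.

Fits the 1:1 Langmuir isotherm to every labelled series in the input table,
reports Kd with bootstrap CIs, the wild-type/mutant fold change, and the
affinity span between the moderate- and high-affinity interactions.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from didomain import io
from didomain.binding import fit_isotherm, fold_change, normalize_series


def fmt_kd(fit) -> str:
    if fit.kd_m < 1e-6:
        return f"{fit.kd_nm:.2f} nM"
    return f"{fit.kd_um:.1f} uM"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--input", type=Path, default=Path("results/simulated/dynamic/bli.tsv"))
    parser.add_argument("--n-boot", type=int, default=1000)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    parser.add_argument("--plot", action="store_true", help="write normalised isotherm overlay (PNG)")
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    series_map = io.read_binding_tsv(args.input)
    fits, rows = {}, []
    for label, series in series_map.items():
        fit = fit_isotherm(series, n_boot=args.n_boot, rng=np.random.default_rng([args.seed, hash(label) % 2**16]))
        fits[label] = fit
        lo, hi = fit.kd_ci95_m
        rows.append(
            {
                "label": label,
                "Kd_M": fit.kd_m,
                "Kd_ci_lo_M": lo,
                "Kd_ci_hi_M": hi,
                "Rmax": fit.rmax,
                "residual_rms": fit.residual_rms,
                "poorly_determined": fit.poorly_determined,
            }
        )
        print(f"{label:>18s}: Kd = {fmt_kd(fit)}  (95% CI {lo*1e9:.3g}-{hi*1e9:.3g} nM, Rmax {fit.rmax:.2f})")
    pd.DataFrame(rows).to_csv(args.outdir / "binding_fits.tsv", sep="\t", index=False, float_format="%.6g")

    payload = {r["label"]: r for r in rows}
    if "wt" in fits and "mutant" in fits:
        fc = fold_change(fits["wt"], fits["mutant"])
        print(f"hEXO mutation fold change: {fc['ratio']:.1f}x "
              f"(95% CI {fc['ci95'][0]:.1f}-{fc['ci95'][1]:.1f})")
        payload["wt_vs_mutant_fold_change"] = fc
    if "high" in fits and "moderate" in fits:
        span = fits["moderate"].kd_m / fits["high"].kd_m
        print(f"moderate/high affinity span: {span:,.0f}x (~{np.log10(span):.1f} orders of magnitude)")
        payload["moderate_vs_high_span"] = span
    io.write_json(payload, args.outdir / "binding_fits.json")

    if args.plot:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for label, series in series_map.items():
            norm = normalize_series(series, fits[label])
            ax.semilogx(norm.conc_m * 1e9, norm.response, "o", ms=4, label=f"{label} ({fmt_kd(fits[label])})")
            grid = np.geomspace(norm.conc_m.min(), norm.conc_m.max(), 100)
            ax.semilogx(grid * 1e9, grid / (fits[label].kd_m + grid), "-", lw=0.8, color=ax.lines[-1].get_color())
        ax.set_xlabel("protein concentration (nM)")
        ax.set_ylabel("normalised response")
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(args.outdir / "binding_isotherms.png", dpi=150)
        print(f"wrote {args.outdir}/binding_isotherms.png")
    print(f"wrote {args.outdir}/binding_fits.json and binding_fits.tsv")


if __name__ == "__main__":
    main()
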