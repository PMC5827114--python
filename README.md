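# didomain

Quantitative NMR/BLI analysis of inter-domain coupling and RNA-binding
specificity in tandem RNA-binding domains, built around the case of
Syncrip/hnRNP-Q: its N-terminal unit for RNA recognition (NURR) and the
extended RRM1 (eRRM1, the canonical RRM plus an αββ N-terminal extension)
form a two-domain unit whose coupling is *specific but dynamic*, and whose
cooperation produces selective, high-affinity miRNA recognition.

The package implements the full inference chain a structural biologist runs
to establish that conclusion, as reusable, tested library code:

1. **Interface burial** — Shrake–Rupley SASA and difference-method buried
   surface area (`didomain.structures`, `didomain.syncrip`): the αββ
   extension packs tightly against the core RRM1 (≈ 1640 Å² buried on the
   deposited structure, PDB 6ES4), while the N-domain/eRRM1 interface
   buries only ≈ 699 Å².
2. **CSP mapping** (`didomain.titration`) — combined amide perturbations
   `CSP = sqrt(ΔδH² + (0.154·ΔδN)²)`, a strict > 0.02 ppm activity
   threshold, overlap with crystallographic contacts, and a global
   fast-exchange Kd fit.
3. **Rotational correlation times** (`didomain.relaxation`) —
   `τc = sqrt(6·T1/T2 − 7)/(4π·νN)` per residue, hetNOE flexibility
   masking, trimmed per-domain aggregation and a Δτc significance test
   (two domains tumbling together must share a τc).
4. **RDC tensor analysis** (`didomain.rdc`) — back-calculation
   `D = vᵀ A v`, SVD fitting of the five Saupe elements, and the one- vs
   two-tensor comparison: a rigid di-domain is fit by a single alignment
   tensor; independently tumbling domains are not.
5. **Binding isotherms** (`didomain.binding`) — Langmuir fits
   `R = Rmax·[P]/(Kd + [P])` to BLI plateau responses with bootstrap CIs
   and fold-change comparisons.
6. **SIA specificity** (`didomain.sia`) — per-position nucleobase
   preference scores from quasi-degenerate RNA-pool CSPs.
7. **Coupling verdict** (`didomain.report`) — the three evidence channels
   combined into rigidly-coupled / dynamically-coupled / detached under
   explicit thresholds.

Because the study's raw NMR/BLI measurements are not publicly deposited,
`didomain.synthetic` generates every input with known ground truth under
the published study conditions (τc 10.0/11.8 ns at 600 MHz; tensors
Da −17.7 Hz/R 0.22 and −18.0 Hz/0.31; Kd 2.0 nM and 29 µM; a ~6-fold
mutant effect; G-preferring specificity), so every stage is validated by
parameter recovery.

## Worked example

Generate a synthetic "dynamic" dataset and run the chain:

```bash
python analysis/01_simulate.py --scenario dynamic --seed 1
python analysis/03_relaxation_tauc.py
python analysis/04_rdc_tensors.py
python analysis/05_csp_mapping.py --fit-kd
python analysis/08_coupling_report.py --scenario dynamic --seed 1
```

which prints (seed 1):

```
domain N:  tauc = 9.9 +/- 0.2 ns (36 residues)
domain eR1: tauc = 11.7 +/- 0.2 ns (36 residues)
delta tauc = 1.77 ns, p = 4.2e-35 -> domains do NOT tumble together

one tensor : r = 0.683, Q = 0.731
two tensors: r = 0.999, Q = 0.036
-> correlation gain +0.316: the domains do NOT share an alignment tensor

13 residues perturbed > 0.02 ppm (of 72 observed)
crystal-contact overlap: Jaccard 1.00 (13/13 active residues on the interface)
shared fast-exchange Kd = 29.3 uM (95% CI 27.7-31.2)

Verdict: dynamically-coupled
```

Read: the perturbed amides sit exactly on the crystal interface (the
crystal conformer dominates in solution), yet the two domains have
significantly different correlation times and cannot be fit with a single
alignment tensor — a specific but dynamic interaction. The binding stage
(`analysis/07_binding_affinity.py`) likewise recovers Kd ≈ 2.4 nM vs
≈ 25 µM (four orders of magnitude) and a 6.2× wild-type/mutant fold change.

`analysis/02_interface_surface.py` reports the buried-surface values; to
include the deposited crystal structure place its coordinates at
`data/6ES4.pdb` (not redistributed here — see `data/README.md`).

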