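# shiftalign

Assigning relative configurations to groups of stereoisomers by
comparing quantum-chemically calculated and experimental ¹³C NMR
chemical shifts is a standard tool in natural-product and synthetic
chemistry. The usual workflow scores each experimental shift set
against each calculated set in isolation (per-set Δδ, MAE, DP4-style
probabilities) — and on closely related diastereomers, whose spectra
differ by only a few ppm, this can be ambiguous: the same calculated
isomer can come out as the best fit for two different experimental
data sets.

`shiftalign` implements a whole-group alternative. With *n* calculated
sets (stereochemistry known a priori, fixed order) and *n* experimental
sets, every one of the *n*! candidate correspondences is scored as a
unit:

- for each unordered pair of calculated sets, the per-atom shift
  difference Δδ_calc = δ_calcA − δ_calcB; likewise Δδ_exp for the
  experimental pair that the alignment puts in correspondence;
- the per-atom discrepancy ΔΔδ = |Δδ_calc − Δδ_exp| — comparing
  *differences* rather than raw shifts cancels constant calibration
  errors shared by a group of sets;
- the alignment score MAE_ΔΔδ = Σ ΔΔδ / n_ΔΔδ, the mean over all
  n(n−1)/2 pairs and all shared atoms.

The lowest MAE_ΔΔδ across the n! alignments proposes the assignment.
For n = 2, 3, 4 sets there are 2, 6, 24 alignments, each accumulating
1, 3, 6 difference-set pairs — exhaustive enumeration is trivial at
realistic n (a configurable ceiling of 8 sets is enforced).

The package also ships the upstream steps that turn DFT shielding
outputs into shift sets (energy-window conformer filtering, Boltzmann
averaging with w_i ∝ exp(−ΔE_i/RT), multistandard calibration with TMS
for sp³ and benzene for sp² carbons), the classic per-set statistics
(Δδ, MAE, RMSD set-similarity summaries, a DP4-style t-density
probability backend with user-supplied parameters), and a seeded
synthetic-data generator with known ground truth.

## Worked example

Generate a synthetic tetrad (four isomers, 18 carbons, 2 ppm
inter-isomer contrast, 0.3 ppm experimental noise, experimental sets
scrambled by a hidden permutation), then rank all 24 alignments:

```bash
shiftalign simulate --seed 3 --out-dir demo/
shiftalign rank --calc demo/calc.csv --exp demo/exp.csv --out demo/report.json
```

```
Stereoisomer assignment by exhaustive alignment ranking
========================================================
sets per group:    4
alignments scored: 24
atoms compared:    18
difference pairs:  6 per alignment

Proposed correspondence (best alignment):
  calc_a  <->  exp_d
  calc_b  <->  exp_b
  calc_c  <->  exp_c
  calc_d  <->  exp_a

best MAE_dd (ppm):     0.3225
gap to 2nd (ppm):      1.8373

Top 10 alignments:
 rank               exp_order  mae_dddelta  avg_mae
    1 exp_d exp_b exp_c exp_a     0.322482 0.233003
    2 exp_a exp_b exp_c exp_d     2.159802 1.187422
    ...
```

The best alignment matches the hidden permutation written to
`demo/truth.txt`: experimental set `exp_d` belongs to the first
calculated isomer, and so on. Its MAE_ΔΔδ of 0.32 ppm reflects only
the 0.3 ppm measurement noise, while the 1.84 ppm gap to the runner-up
shows how decisively the whole-group comparison separates the correct
correspondence from the next best. The same objects are available as a
library:

```python
from shiftalign import StereoAssignment

res = StereoAssignment.from_files("demo/calc.csv", "demo/exp.csv").fit()
print(res.assignment)      # {'calc_a': 'exp_d', 'calc_b': 'exp_b', ...}
print(res.summary())
```

`shiftalign classic` prints the per-set MAE/RMSD matrix of the
traditional approach, and `shiftalign shifts` runs the
Boltzmann-averaging/calibration pipeline on per-conformer shielding
tables (see `docs/methods.md` for file formats and configuration keys).

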