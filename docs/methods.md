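# Methods

## The assignment problem

A group of n stereoisomers of one scaffold has been synthesized or
isolated, and n experimental ¹³C shift sets are on hand, but which
spectrum belongs to which configuration is uncertain. DFT/GIAO
calculations provide one calculated shift set per candidate
configuration. The task is to find the correspondence between the two
groups of sets.

The calculated sets form a fixed reference sequence (their
stereochemistry is known by construction); a candidate assignment is a
permutation placing one experimental set against each calculated set.
All n! permutations are scored and ranked.

## The MAE_ΔΔδ score

For an alignment that puts experimental set e(k) against calculated set
k, and for every unordered pair i < j of positions:

- Δδ_calc(i,j,a) = δ_calc,i(a) − δ_calc,j(a) per atom a,
- Δδ_exp(i,j,a) = δ_exp,e(i)(a) − δ_exp,e(j)(a),
- ΔΔδ(i,j,a) = |Δδ_calc(i,j,a) − Δδ_exp(i,j,a)|,
- MAE_ΔΔδ = mean of all ΔΔδ over the n(n−1)/2 pairs and all shared
  atoms (n_ΔΔδ = n(n−1)/2 × n_atoms terms).

Working with differences of shifts rather than shifts themselves means
any constant offset common to a whole group — the typical signature of
a calibration or referencing error — cancels exactly. The test suite
asserts this as a literal invariant: adding any constant to every
calculated (or every experimental) set changes no alignment's score,
and comparing a bundle with itself under the identity scores exactly 0.

Orientation within a pair is irrelevant: flipping (i,j) to (j,i) flips
the sign of both Δδ terms and the absolute value is unchanged, so
unordered pairs are accumulated once each. A secondary per-alignment
metric is also available: the mean of the n classic calc-vs-exp MAEs
under the alignment (`avg_mae`). It ranks alignments too but does not
cancel systematic offsets; the primary sort key is always MAE_ΔΔδ.

Scores are accumulated in double precision with plain summation; at
these magnitudes (tens of ppm, hundreds of terms) the rounding error is
orders of magnitude below the 1e-9 ppm tie tolerance.

## Classic per-set statistics

For completeness and for diagnosing ambiguity the package computes the
traditional quantities: signed Δδ = δ_calc − δ_exp per atom, MAE =
mean |Δδ|, the RMSD between two shift sets, and min/mean/max pairwise
RMSD summaries within a group (low values flag a hard problem — the
isomers' spectra barely differ). `classic_ranking` builds the full
n×n score matrix and flags, per experimental set, every calculated set
within tolerance of its optimum; ties and repeated best-fits are
reported, never silently broken, because that ambiguity is precisely
the failure mode the alignment ranking addresses.

A DP4-style probability backend is provided as a location-scale
Student-t density over the errors, normalized across candidates. The
degrees of freedom, location and scale must be supplied by the user
from a published parametrization; the backend deliberately does not
reproduce any specific published constant set, nor the scaled/unscaled
and sp²/sp³ partitioning of refined variants.

## Shielding-to-shift pipeline

Upstream of the comparison, per-conformer isotropic shieldings are
turned into one shift set per isomer:

1. **Energy window** — conformers more than `energy_window` above the
   minimum are discarded (default 3.0 kcal/mol ≙ 12.5 kJ/mol, a common
   redundant-conformer cutoff). The minimum-energy conformer always
   survives.
2. **Boltzmann averaging** — w_i = exp(−ΔE_i/RT) / Σ exp(−ΔE_j/RT),
   with T defaulting to 298.15 K and R expressed in the configured
   energy unit (`kcal_mol` default; `kj_mol` and `hartree` supported).
   Weights depend only on energy differences.
3. **Multistandard calibration** — δ = σ_ref − σ + δ_ref,exp with TMS
   as reference for sp³ carbons (δ_ref,exp = 0 by definition) and
   benzene for non-carbonyl sp² carbons (δ_ref,exp = 128.5 ppm
   default). Reference shieldings must come from the same level of
   theory as the compound. Carbonyl carbons are excluded from the
   benzene rule; which standard they should use is genuinely open, so
   `carbonyl_policy` exposes the choice and defaults to `tms` (the
   universal single-standard fallback).

Calibration is affine, so averaging shieldings and then calibrating is
identical to calibrating each conformer and averaging; the pipeline
averages first and the equivalence is tested.

Temperature, energy unit, window, standards and carbonyl policy are
read from a YAML config (`temperature_K`, `energy_unit`,
`energy_window`, `standards.{tms_sigma,benzene_sigma,benzene_delta_exp}`,
`carbonyl_policy`).

## File formats

Shift tables are CSV/TSV (dialect by extension, decimal points only)
with header `label, hybridization, <set_id>...` and one carbon per row;
empty cells are missing values, never zeros. Conformer tables have
header `conformer_id, rel_energy, <label>...`. Writers emit full
`repr` precision, so write→read round trips are bit-identical. An atom
label absent from any set of a bundle is dropped from all comparisons
(with a warning): every formula assumes matched carbons, and all pairs
must contribute the same atom count for n_ΔΔδ to be the product
n(n−1)/2 × n_atoms. The report writer produces JSON (ranking plus
metadata: set/atom counts, best order, gap to second, ties) with a TSV
mirror.

Peak-to-atom assignment of the experimental data is assumed resolved by
the user; the format offers no mechanism for exchangeable or
overlapping peaks.

## Synthetic data generator

`generate_bundle` emulates the structure of a stereoisomer study
without any shift-prediction physics. Defaults describe a
four-isomer tetrad of an 18-carbon natural-product-like scaffold:

| parameter | default | meaning |
|---|---|---|
| `n_isomers` | 4 | sets per group |
| `n_atoms` | 18 | carbons |
| `sp2_fraction` | 0.3 | fraction of sp² carbons (bases 100–170 ppm; sp³ 10–80 ppm) |
| `contrast_sd` | 2.0 ppm | per-atom, per-isomer configuration contrast |
| `noise_sd` | 0.3 ppm | experimental measurement noise |
| `systematic_offset` | 0 ppm | constant calibration error on the calculated group |
| `true_permutation` | random | hidden ground-truth correspondence |

The 2 ppm contrast yields pairwise set RMSDs of a few ppm, matching the
similarity scale of real closely-related diastereomer tetrads; 0.3 ppm
is a typical scale for combined measurement/assignment noise. All
randomness flows through NumPy's seeded PCG64 generator, so bundles are
bit-reproducible across platforms.

Perturbations are independent across atoms and isomers. Real
diastereomer shift differences are spatially correlated (largest near
the inverted stereocenters) and systematically structured; passing the
recovery tests therefore demonstrates that the machinery separates the
true correspondence from a realistic noise/contrast ratio, not that any
particular real compound would be assigned correctly.

`generate_ambiguous_bundle` constructs the diagnostic failure case of
the per-set approach: one experimental set is displaced 70% of the way
toward a *different* isomer's calculated set, so two experimental sets
share the same per-set best fit while the whole-group alignment still
recovers the truth.

## Numerical and design choices

- Tie tolerance 1e-9 ppm for declaring tied alignments; ties are
  reported (CLI exit code 3), and the stable lexicographic enumeration
  order (identity first) fixes only the display order.
- The ranking reports the score gap to the second-best alignment as a
  confidence diagnostic, but no probability or significance threshold
  is attached to it.
- Enumeration is exhaustive; n ≤ 8 (40320 alignments) is enforced by a
  configurable ceiling rather than a heuristic search.
- The model facade (`StereoAssignment` / `StereoAssignmentResults`)
  wraps the functional layer in a constructed-from-data → `fit()` →
  results-with-`summary()` shape; both surfaces are public.

## Problem sizes used in the checks

The verification suite runs brute-force cross-checks on 100 random
bundles (n ≤ 4, ≤ 10 atoms), 50 random permutation-composition draws,
and a 200-replicate recovery experiment at the generator defaults —
sizes at which the exhaustive reference implementations are exact and
the whole suite completes in seconds.

## Limitations

- Everything upstream of shieldings/energies (conformational search,
  geometry optimization, GIAO computation, geometry-level conformer
  deduplication) is out of scope; users export those to CSV.
- The DP4-style backend is a generic t-density, not a faithful
  reimplementation of any published DP4/DP4+ parametrization, and no
  probability over *alignments* is defined — MAE_ΔΔδ is a ranking
  statistic, not a calibrated posterior.
- Pair-only methods (CP3-style) are not implemented.
- MAE_ΔΔδ cancels offsets that are constant within a group; it does
  not correct atom-dependent systematic errors (e.g. heavy-atom
  neighbors), which calibration and error-distribution methods handle
  upstream.
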