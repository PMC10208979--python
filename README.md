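# resikit

A Python toolkit for **RESI** (Resolution Enhancement by Sequential Imaging)
analysis of DNA-PAINT / Exchange-PAINT single-molecule localization data.

## The problem

Widefield SMLM precision is limited by the photon budget per blinking event:
σ_SMLM ≈ σ_DIFF/√N. When one target species is split stochastically over *n*
orthogonal DNA sequences and imaged in *n* sequential Exchange-PAINT rounds,
each target's localization cloud becomes isolated, so its *K* localizations
can be grouped and averaged. Precision then improves from the standard
deviation to the standard error of the cloud,

    σ_RESI = σ_SMLM / √K,

independently of σ_SMLM itself — with hundreds of localizations per target
and σ_SMLM ≈ 3 nm, sub-nanometre (Ångström-scale) precision is reachable.
This package implements the full analysis chain for that idea plus the
supporting design math and statistics, for microscopists and analysts
working with localization tables (Picasso-style HDF5 or CSV):

- **io** — localization data model; Picasso-compatible HDF5 + YAML sidecar
  and CSV I/O, nm units internally, pixel conversion at the boundary.
- **synth** — synthetic ground-truth layouts (grids, sub-nm site pairs,
  nuclear-pore-like ring complexes, CSR patterns), DNA-PAINT localization
  clouds with blinking and sticking-artifact models, and CSR monomer/dimer
  membrane-receptor mixtures.
- **kinetics** — acquisition-time calculators (τ_dark = 1/(k_on·c), required
  localizations, measurement time) and stochastic-labelling design:
  P(diff. seq.) = 1 − 1/n, P(m, n) = n!/((n−m)!·nᵐ), and the unresolved
  fraction F = 1 − exp(−ρπd²) at effective density ρ = density/n.
- **align** — round-to-round registration: histogram cross-correlation for
  coarse translation, orthogonal Procrustes (rotation + translation) from
  fiducial correspondences.
- **cluster** — neighbour-count local-maxima clustering with radius *r* and
  minimum size *n*_min, plus the two temporal artifact filters (mean-frame
  band, 20-window / 80% sticking filter).
- **resi** — inverse-variance weighted cluster collapse (weights 1/lp²),
  weighted s.e.m. precision, merging of rounds, Gaussian rendering.
- **precision** — σ_RESI(K) by in-silico simulation and by resampling of
  measured clusters, using the scalar spread √(½·tr cov).
- **nnd** — k-th nearest-neighbour distance analysis, CSR references, and
  the iterative nonlinear least-squares monomer/dimer mixture fit with
  refit-based uncertainties.

## Worked example

```python
import numpy as np
import resikit as rk

# design: how many localizations and how long?
n_loc = rk.required_localizations(sigma_smlm=4.0, sigma_resi=1.0)
k = rk.KineticsParams(k_on=1e8, c=2e-10, tau_bright=0.5, t_exposure=0.1)
print(f"n_loc = {n_loc}, acquisition time = {rk.measurement_time(k, n_loc):.0f} s")
print(f"P(diff. seq.) at n=4 rounds: {rk.p_pair_distinct(4):.2f}")

# simulate a two-round acquisition of six 0.85-nm site pairs
base = rk.make_layout("pair_grid", n_pairs=6, pitch=20.0, pair_offset=0.85)
layout = rk.GroundTruthLayout(base.sites, np.tile([0, 1], 6), n_rounds=2)
tables = rk.sample_localizations(layout, sigma_smlm=2.0, locs_per_site=254, seed=0)

params = rk.ClusterParams(r=4.0, n_min=10)
per_round = [rk.collapse(t, rk.cluster(t, params)) for t in tables]
resi = rk.merge_rounds(per_round)
print(f"RESI localizations: {len(resi)}  "
      f"mean precision: {resi.records['precision_xy'].mean():.3f} nm")
```

prints

```
n_loc = 16, acquisition time = 160 s
P(diff. seq.) at n=4 rounds: 0.75
RESI localizations: 12  mean precision: 0.113 nm
```

Sixteen localizations suffice for 1 nm precision at σ_SMLM = 4 nm; four
labelling rounds give a 75% chance that a protein pair carries different
sequences; and averaging K = 254 localizations at σ_SMLM = 2 nm yields
~0.11 nm (≈ 2/√254) precision per target — enough that the 0.85 nm intra-pair
offset is measured as two clearly distinct RESI localizations per pair.

A command-line interface mirrors the library
(`resikit simulate|design|align|cluster|resi|precision|nnd-fit|run`); see
`resikit --help`. `resikit run config.yaml` executes a full configured
pipeline and writes a manifest with hashes for reproducibility.

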