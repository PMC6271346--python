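# plfatax

Chemotaxonomy of aquatic microbial communities from phospholipid fatty
acids (PLFA), with a focus on temporary-pond food webs.

Membrane phospholipids degrade quickly after cell death, so the fatty
acids derived from them (PLFA) proxy *living* biomass. Because taxa carry
characteristic FA ratios — branched iso/anteiso FAs in Gram-positive
bacteria, cyclopropyl and hydroxy FAs in Gram-negatives, 18:1ω9c in
fungi, C16/C18 PUFAs in algae and cyanobacteria, 20:5ω3 (EPA) and
22:6ω3 (DHA) in diatoms — the PLFA composition of pond seston can be
unmixed into the biomass fractions of the taxa that produced it. The
same markers, traced into zooplankton lipid fractions, show whether
energy of heterotrophic (bacterial/fungal) origin reaches the consumers.

`plfatax` is aimed at microbial ecologists working with FAME/PLFA tables
from gas chromatography. It provides:

* **FA nomenclature** (`plfatax.nomenclature`) — a parser for the many
  dialects of FA shorthand (`18:1ω9c` = `18:1w9c`, `i-15:0` = `15:0 iso`,
  `16:00` = `16:0`, `3-OH 10:0`, `10-Me 16:0`, `cy19:0`), with canonical
  spellings and structural classification (SAFA/MUFA/PUFA, branched,
  hydroxy, cyclopropyl).
* **Profiles and ratio matrices** (`plfatax.profiles`) — CSV/TSV readers
  and writers for FA composition tables; construction of taxa × FA
  *ratio matrices* (signatures referenced to 16:0 = 1) from isolate
  libraries, with the conventional filters (mean weight % < 1% in every
  taxon, single-taxon FAs); generic isolate identification by profile
  similarity. A nine-taxon pond ratio matrix (three fungal phyla, three
  bacterial phyla, green algae, cyanobacteria, diatoms) ships as a
  packaged fixture.
* **Unmixing engine** (`plfatax.unmixing`) — CHEMTAX-style estimation of
  taxon abundances: per-sample nonnegative least squares on the simplex
  against row-normalized signatures, alternated with projected
  steepest-descent adjustment of the ratio matrix within a multiplicative
  bound (default ±50%). Successive-runs and randomized-starts protocols,
  and per-location fits restricted to the taxa present.
* **Trophic markers** (`plfatax.trophic`) — marker-sum quantification of
  fungi / bacteria / autotroph contributions (fungi: 16:1ω5; bacteria:
  15:0, iso/anteiso, hydroxy, cyclopropyl FAs and 18:1ω8; autotrophs:
  C16+C18 PUFA), lipid-fraction pooling, and EPA/DHA retention ratios of
  consumers relative to seston.
* **Ordination statistics** (`plfatax.stats`) — Spearman rank correlation
  and PCA with the standard FA variable screening (< 14 carbons removed;
  Kaiser–Meyer–Olkin sampling adequacy > 0.50; communality > 0.50 on the
  eigenvalue-greater-than-1 component solution).
* **Synthetic data** (`plfatax.synthetic`) — generators for seston
  samples (known abundances + compositional noise), isolate libraries
  (within-taxon variability) and consumer profiles (selective retention),
  so every stage is testable against ground truth.
* A `plfatax` **command line** with subcommands `simulate`,
  `build-matrix`, `identify`, `unmix`, `markers`, `trophic`,
  `ordination` and `run` (config-driven pipeline with a run manifest).

## The model

A sample's PLFA composition **s** (proportions of total FA) is modelled
as a mixture of taxon signatures: **s** ≈ **a**ᵀ·F, where F is the
row-normalized ratio matrix R (each taxon's FA amounts relative to
16:0 = 1, renormalized to proportions) and **a** are nonnegative biomass
fractions summing to 1. For fixed R, **a** is the simplex-constrained
least-squares fit. Because published or cultured signatures never match
field conditions exactly, R itself is then adjusted — each nonzero
element confined to [r₀/1.5, 1.5·r₀], structural zeros and the 16:0
reference frozen — by projected gradient descent on the root-mean-square
residual, alternating with the abundance solve until the residual stops
improving.

## Worked example

```python
import plfatax as px

matrix = px.load_ratio_matrix_input()          # packaged 9-taxon signatures
scenario = px.make_scenario(matrix, n_samples=20, seed=1, cv=0.10,
                            preset="heterotroph_dominated")
samples, truth = px.gen_pond_samples(scenario)  # synthetic seston, known truth
result = px.fit(samples, matrix, px.UnmixingConfig(bound_factor=1.5, seed=1))

print(result.abundances.mean(axis=0).round(3))  # estimated biomass fractions
```

Output (estimated vs generating mean fractions over the 20 samples):

```
taxon            true    est
Ascomycetes      0.072   0.081
Zygomycetes      0.057   0.101
Basidiomycetes   0.115   0.078
Actinobacteria   0.096   0.112
Firmicutes       0.164   0.149
Proteobacteria   0.402   0.365
Green algae      0.052   0.050
Cyanobacteria    0.018   0.033
Diatoms          0.024   0.031
```

The mean absolute abundance error is 0.032 at 10% compositional noise;
the residual RMSE is 0.0011. The marker sums on the mean seston give
`{bacteria: 0.661, autotrophs: 0.339, fungi: 0.0}` — a heterotroph-
dominated pond, as constructed. A synthetic grazer generated with an EPA
retention factor of 3 measures a retention ratio of 2.85 relative to
that seston (3/(1 + 2·EPA share) ≈ 2.96 expected after compositional
renormalization, plus 10% noise).

The same run from the shell:

```
plfatax run --config src/plfatax/data/example_config.yaml --out out/
```

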