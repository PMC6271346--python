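"""Synthetic pond data with the statistical structure the pipeline assumes.

Generates the three kinds of input the analysis consumes, from known
ground truth, so every stage can be exercised and validated without field
samples:

* **seston PLFA samples** — mixtures of taxon signatures (a ratio matrix)
  with compositional noise, from known per-sample taxon abundances;
* **isolate libraries** — per-taxon FA profiles with multiplicative
  within-taxon variability around the taxon mean;
* **consumer (zooplankton) profiles** — seston compositions reshaped by
  class-specific selective retention plus a de-novo saturated-FA
  contribution, per lipid fraction.

Default noise is multiplicative lognormal with cv = 0.10 on each FA
quantity followed by renormalization (a compositional perturbation);
Dirichlet resampling is offered as an alternative.  Presets encode the
qualitative pond regimes discussed in the literature: heterotroph
dominated, green-algae dominated, and mixed with ~50% cyanobacteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nomenclature import classify, parse_fa_name
from .profiles import REFERENCE_FA, FAProfile, TaxonRatioMatrix
from .trophic import MarkerScheme, default_scheme
from .unmixing import SampleMatrix

__all__ = [
    "PRESETS",
    "SyntheticScenario",
    "ConsumerSpec",
    "make_scenario",
    "gen_pond_samples",
    "gen_isolate_library",
    "gen_consumer_profiles",
]

#: Mean taxon biomass fractions of the named pond regimes (nine packaged
#: taxa).  "heterotroph_dominated" puts 90% of the mass in bacteria+fungi;
#: "green_algae_dominated" gives green algae 80%; "cyanobacteria_mixed"
#: gives cyanobacteria half the mass.
PRESETS: dict[str, dict[str, float]] = {
    "heterotroph_dominated": {
        "Ascomycetes": 0.08,
        "Zygomycetes": 0.05,
        "Basidiomycetes": 0.12,
        "Actinobacteria": 0.10,
        "Firmicutes": 0.15,
        "Proteobacteria": 0.40,
        "Green algae": 0.05,
        "Cyanobacteria": 0.02,
        "Diatoms": 0.03,
    },
    "green_algae_dominated": {
        "Ascomycetes": 0.02,
        "Zygomycetes": 0.02,
        "Basidiomycetes": 0.03,
        "Actinobacteria": 0.02,
        "Firmicutes": 0.03,
        "Proteobacteria": 0.05,
        "Green algae": 0.80,
        "Cyanobacteria": 0.02,
        "Diatoms": 0.01,
    },
    "cyanobacteria_mixed": {
        "Ascomycetes": 0.05,
        "Zygomycetes": 0.03,
        "Basidiomycetes": 0.05,
        "Actinobacteria": 0.05,
        "Firmicutes": 0.07,
        "Proteobacteria": 0.15,
        "Green algae": 0.05,
        "Cyanobacteria": 0.50,
        "Diatoms": 0.05,
    },
}


@dataclass
class ConsumerSpec:
    """Selective-retention specification for synthetic consumers.

    ``retention`` maps an FA name, a structural tag (e.g. ``PUFA``) or a
    marker-group name (``bacteria``/``fungi``/``autotrophs``) to a
    multiplicative retention factor; unlisted FAs retain at 1.  Name keys
    take precedence over group keys, which take precedence over tag keys.
    ``de_novo_safa`` is the fraction of consumer FA mass synthesised
    de novo and distributed over dietary saturated FAs.
    ``fraction_pufa_boost`` applies an extra PUFA retention multiplier per
    lipid fraction; membranes (phospholipids) retain PUFA at least as
    strongly as reserve (neutral) lipids.
    """

    retention: dict[str, float] = field(default_factory=dict)
    de_novo_safa: float = 0.0
    cv: float = 0.0
    fraction_pufa_boost: dict[str, float] = field(
        default_factory=lambda: {
            "neutral": 1.0,
            "acetone_mobile": 1.0,
            "free_fa": 1.0,
            "phospholipid": 1.3,
        }
    )

    def __post_init__(self) -> None:
        for k, v in self.retention.items():
            if v < 0:
                raise ValueError(f"retention factor for {k!r} must be >= 0, got {v}")
        if not (0 <= self.de_novo_safa < 1):
            raise ValueError("de_novo_safa must lie in [0, 1)")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")


@dataclass
class SyntheticScenario:
    """Ground truth for one synthetic pond data set."""

    ratio_matrix: TaxonRatioMatrix
    true_abundances: pd.DataFrame  # samples × taxa, rows sum to 1
    noise_model: str = "lognormal"  # or "dirichlet"
    cv: float = 0.10
    dirichlet_concentration: float = 100.0
    seed: int = 0
    consumer_spec: ConsumerSpec | None = None

    def __post_init__(self) -> None:
        if self.noise_model not in ("lognormal", "dirichlet"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        A = self.true_abundances.to_numpy(dtype=float)
        if (A < 0).any() or not np.allclose(A.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("true_abundances rows must be nonnegative and sum to 1")
        if list(self.true_abundances.columns) != self.ratio_matrix.taxa:
            raise ValueError("true_abundances columns must match ratio-matrix taxa order")


def make_scenario(
    ratio_matrix: TaxonRatioMatrix,
    n_samples: int = 20,
    seed: int = 0,
    preset: str | Mapping[str, float] | None = None,
    dirichlet_alpha: float = 1.0,
    cv: float = 0.10,
    noise_model: str = "lognormal",
) -> SyntheticScenario:
    """Draw a scenario with Dirichlet-distributed true abundances.

    Without a preset the truth is symmetric Dirichlet(``dirichlet_alpha``)
    over the taxa; with a preset (name or mean fractions) the Dirichlet is
    centred on the preset means with an effective sample size of 50 so
    individual ponds scatter realistically around the regime.
    """
    rng = np.random.default_rng(seed)
    taxa = ratio_matrix.taxa
    if preset is None:
        alpha = np.full(len(taxa), float(dirichlet_alpha))
    else:
        mean = PRESETS[preset] if isinstance(preset, str) else dict(preset)
        missing = [t for t in taxa if t not in mean]
        if missing:
            raise KeyError(f"preset lacks taxa {missing}")
        m = np.array([mean[t] for t in taxa], dtype=float)
        alpha = 50.0 * m / m.sum()
    A = rng.dirichlet(alpha, size=n_samples)
    truth = pd.DataFrame(A, index=[f"sample_{i + 1}" for i in range(n_samples)], columns=taxa)
    return SyntheticScenario(
        ratio_matrix=ratio_matrix,
        true_abundances=truth,
        noise_model=noise_model,
        cv=cv,
        seed=seed,
    )


def _lognormal_factors(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    if cv == 0:
        return np.ones(shape)
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=shape)


def gen_pond_samples(sc: SyntheticScenario) -> tuple[SampleMatrix, pd.DataFrame]:
    """Synthetic seston PLFA compositions plus the truth record.

    Each sample is the abundance-weighted mixture of the row-normalized
    taxon signatures, perturbed by the scenario noise model and
    renormalized to weight %.
    """
    R = sc.ratio_matrix.values
    if (R.sum(axis=1) <= 0).any():
        raise ValueError("ratio matrix has an all-zero taxon row")
    Fn = R / R.sum(axis=1, keepdims=True)
    A = sc.true_abundances.to_numpy(dtype=float)
    clean = A @ Fn
    rng = np.random.default_rng(sc.seed)
    if sc.noise_model == "lognormal":
        noisy = clean * _lognormal_factors(rng, sc.cv, clean.shape)
    else:
        noisy = np.vstack(
            [rng.dirichlet(np.maximum(row, 1e-12) * sc.dirichlet_concentration) for row in clean]
        )
    noisy = noisy / noisy.sum(axis=1, keepdims=True) * 100.0
    S = SampleMatrix(
        sample_ids=list(sc.true_abundances.index),
        fas=sc.ratio_matrix.fas,
        values=noisy,
    )
    return S, sc.true_abundances.copy()


def gen_isolate_library(
    means: TaxonRatioMatrix,
    cv: float = 0.2,
    n_per_taxon: int = 5,
    seed: int = 0,
) -> list[tuple[str, FAProfile]]:
    """Isolate profiles with lognormal within-taxon variation around means.

    Each isolate multiplies its taxon's mean *ratio* vector element-wise by
    lognormal factors (unit mean, coefficient of variation ``cv``), keeping
    the 16:0 reference entry at 1 so that ratio averaging is unbiased, and
    is expressed in weight %.  Structural zeros stay zero.  Averaging the
    library back into a ratio matrix recovers the means as ``n_per_taxon``
    grows.
    """
    if n_per_taxon < 1:
        raise ValueError("n_per_taxon must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[tuple[str, FAProfile]] = []
    fas = means.fas
    ref = np.array([fa == REFERENCE_FA for fa in fas])
    for taxon in means.taxa:
        base = means.data.loc[taxon].to_numpy()
        for i in range(n_per_taxon):
            factors = _lognormal_factors(rng, cv, base.shape)
            factors[ref] = 1.0
            vals = base * factors
            vals = vals / vals.sum() * 100.0
            out.append(
                (
                    taxon,
                    FAProfile(
                        entity_id=f"{taxon}_isolate_{i + 1}",
                        values={fa: v for fa, v in zip(fas, vals) if v > 0},
                        lipid_fraction="PLFA",
                        meta={"taxon": taxon},
                    ),
                )
            )
    return out


def _retention_factor(fa: str, spec: ConsumerSpec, scheme: MarkerScheme) -> float:
    d = parse_fa_name(fa)
    if fa in spec.retention:
        return spec.retention[fa]
    group = scheme.assign(d)
    if group in spec.retention:
        return spec.retention[group]  # type: ignore[index]
    for tag in classify(d):
        if tag in spec.retention:
            return spec.retention[tag]
    return 1.0


def gen_consumer_profiles(
    seston: FAProfile,
    spec: ConsumerSpec,
    seed: int = 0,
    fractions: Sequence[str] = ("neutral", "acetone_mobile", "free_fa", "phospholipid"),
    scheme: MarkerScheme | None = None,
) -> list[FAProfile]:
    """Synthetic consumer FA profiles, one per lipid fraction.

    Consumer FA shares are proportional to seston shares times the
    retention factor (with the per-fraction PUFA boost), mixed with a
    de-novo SAFA component distributed over dietary saturated FAs, then
    perturbed by lognormal noise of coefficient of variation ``spec.cv``
    and renormalized to weight %.
    """
    scheme = scheme or default_scheme()
    s = seston.as_weight_pct()
    rng = np.random.default_rng(seed)
    out: list[FAProfile] = []
    fa_names = list(s.values)
    shares = np.array([s.values[f] for f in fa_names]) / 100.0
    is_pufa = np.array(["PUFA" in classify(parse_fa_name(f)) for f in fa_names])
    is_safa = np.array(["SAFA" in classify(parse_fa_name(f)) for f in fa_names])
    base_factors = np.array([_retention_factor(f, spec, scheme) for f in fa_names])

    for frac in fractions:
        factors = base_factors.copy()
        boost = spec.fraction_pufa_boost.get(frac, 1.0)
        factors[is_pufa] = factors[is_pufa] * boost
        retained = shares * factors
        tot = retained.sum()
        if tot <= 0:
            raise ValueError("all FA retained at zero; consumer profile undefined")
        retained = retained / tot
        if spec.de_novo_safa > 0 and is_safa.any():
            safa_dist = np.where(is_safa, shares, 0.0)
            safa_dist = safa_dist / safa_dist.sum()
            retained = (1 - spec.de_novo_safa) * retained + spec.de_novo_safa * safa_dist
        noisy = retained * _lognormal_factors(rng, spec.cv, retained.shape)
        noisy = noisy / noisy.sum() * 100.0
        out.append(
            FAProfile(
                entity_id=seston.entity_id + "_consumer",
                values={f: v for f, v in zip(fa_names, noisy) if v > 0},
                lipid_fraction=frac,
                meta={"source_seston": seston.entity_id},
            )
        )
    return out
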