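"""Constrained ratio-matrix unmixing of biomarker compositions.

Given per-sample PLFA compositions ``S`` (samples × FA) and an initial
taxon × FA ratio matrix ``R0`` (signatures referenced to 16:0 = 1), the
engine estimates taxon biomass fractions ``A`` while adjusting ``R``
within multiplicative bounds, in the style of the CHEMTAX family of
chemotaxonomy programs:

1. for fixed ``R``, each sample's abundances are the nonnegative
   least-squares fit of its composition (as proportions of total FA) onto
   the row-normalized taxon signatures, renormalized to sum 1;
2. ``R`` is then moved one projected steepest-descent step (analytic
   gradient, multiplicative preconditioning, backtracking line search)
   within the element-wise box ``[R0 / bound_factor, R0 × bound_factor]``.

Structural zeros of ``R0`` are never adjusted, and the 16:0 reference
entries stay frozen at 1, preserving the "referred to 16:0" semantics.
The objective is the unweighted RMSE between observed and reconstructed
compositions (both as proportions); a per-FA weight hook is exposed on
the configuration for users who prefer abundance weighting.

Two multi-run protocols are provided on top of the single fit, mirroring
standard ratio-optimization practice: *successive runs* (each run's
optimized matrix seeds the next) and *randomized starts* (many perturbed
input matrices; the best fraction is averaged and refit once).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .profiles import REFERENCE_FA, FAProfile, TaxonRatioMatrix
from .nomenclature import canonicalize

__all__ = [
    "SampleMatrix",
    "UnmixingConfig",
    "UnmixingResult",
    "solve_abundances",
    "fit",
    "successive_runs",
    "randomized_starts",
    "run_by_location",
]


@dataclass
class SampleMatrix:
    """Per-sample biomarker compositions (samples × FA, nonnegative)."""

    sample_ids: list[str]
    fas: list[str]
    values: np.ndarray
    location: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fas = [canonicalize(f) for f in self.fas]
        if len(set(self.fas)) != len(self.fas):
            raise ValueError("duplicate FA columns in sample matrix")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.fas)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples × {len(self.fas)} FAs"
            )
        if (self.values < 0).any():
            raise ValueError("sample matrix contains negative entries")
        if (self.values.sum(axis=1) <= 0).any():
            zero = [s for s, tot in zip(self.sample_ids, self.values.sum(axis=1)) if tot <= 0]
            raise ValueError(f"all-zero sample rows: {zero}")

    @classmethod
    def from_profiles(
        cls, profiles: Sequence[FAProfile], location: Mapping[str, str] | None = None
    ) -> "SampleMatrix":
        fas: list[str] = []
        for p in profiles:
            for fa in p.values:
                if fa not in fas:
                    fas.append(fa)
        vals = np.array([[p.values.get(fa, 0.0) for fa in fas] for p in profiles])
        return cls(
            sample_ids=[p.entity_id for p in profiles],
            fas=fas,
            values=vals,
            location=dict(location or {}),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.fas)


@dataclass
class UnmixingConfig:
    """Tuning knobs for the unmixing engine.

    ``bound_factor`` is the multiplicative ratio-adjustment bound (1.5
    means each nonzero element may move within ±50% of its input value).
    ``step_init`` is the initial steepest-descent step as a fraction of
    element magnitude.  ``start_jitter`` scales the random perturbation of
    the randomized-starts protocol (1 = anywhere within the bound box,
    0 = no perturbation).  ``fa_weights`` optionally weights the residual
    per FA (default: unweighted).
    """

    bound_factor: float = 1.5
    step_init: float = 0.05
    tol: float = 1e-8
    max_iter: int = 500
    n_successive_runs: int = 8
    n_random_starts: int = 60
    best_fraction: float = 0.1
    start_jitter: float = 1.0
    seed: int = 0
    fa_weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.bound_factor < 1:
            raise ValueError("bound_factor must be >= 1")
        if not (0 < self.best_fraction <= 1):
            raise ValueError("best_fraction must lie in (0, 1]")


@dataclass
class UnmixingResult:
    """Fitted abundances, optimized ratio matrix and fit diagnostics."""

    abundances: pd.DataFrame  # samples × taxa, rows sum to 1
    ratio_out: TaxonRatioMatrix
    rmse: float
    n_iter: int
    converged: bool
    rmse_trajectory: list[float] = field(default_factory=list)


# --------------------------------------------------------------------------
# internal numerics (plain ndarrays, canonical FA order fixed by the caller)

def _row_normalize(R: np.ndarray) -> np.ndarray:
    s = R.sum(axis=1, keepdims=True)
    if (s <= 0).any():
        raise ValueError("ratio matrix has an all-zero taxon row on the shared FA set")
    return R / s


#: Weight of the sum-to-one augmentation row in the NNLS solve.  Abundances
#: are biomass *fractions*, so the nonnegative fit is constrained to the
#: simplex by appending a heavily weighted Σa = 1 equation; the tiny
#: residual slack is removed by an exact renormalization afterwards.
_SUM_WEIGHT = 1e4


def _solve_all(Fn: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Simplex-constrained NNLS abundances for every sample row of S."""
    k = Fn.shape[0]
    A = np.empty((S.shape[0], k))
    At = np.vstack([Fn.T, np.full((1, k), _SUM_WEIGHT)])
    rhs = np.empty(Fn.shape[1] + 1)
    rhs[-1] = _SUM_WEIGHT
    for i in range(S.shape[0]):
        rhs[:-1] = S[i]
        a, _ = nnls(At, rhs)
        tot = a.sum()
        A[i] = a / tot if tot > 0 else a
    return A


def _rmse(S: np.ndarray, A: np.ndarray, Fn: np.ndarray, w: np.ndarray | None) -> float:
    E = S - A @ Fn
    if w is not None:
        E = E * w
    return float(np.sqrt(np.mean(E * E)))


def _fit_core(
    S: np.ndarray,
    R_start: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    free: np.ndarray,
    cfg: UnmixingConfig,
    w: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, float, int, bool, list[float]]:
    """Alternating NNLS / projected descent.  S rows are proportions.

    ``free`` masks the adjustable elements (nonzero, non-reference);
    ``lo``/``hi`` is the element-wise box.  Returns (A, R, rmse, n_iter,
    converged, trajectory).
    """
    R = np.clip(R_start, lo, hi)
    R[~free & (R_start == 0)] = 0.0
    trajectory: list[float] = []
    converged = False
    prev = np.inf
    A = None
    it = 0
    for it in range(1, cfg.max_iter + 1):
        Fn = _row_normalize(R)
        A = _solve_all(Fn, S)
        cur = _rmse(S, A, Fn, w)
        trajectory.append(cur)
        if it > 1 and prev - cur <= cfg.tol * max(prev, 1e-300):
            converged = True
            break
        prev = cur
        base = cur

        # Gradient of the residual with respect to R at the current optimal
        # abundances.  Because A minimizes the inner problem, the partial
        # derivative at fixed A equals the total derivative (envelope
        # theorem); the chain rule through the row normalization gives
        #   d mse / dR_kj = (G_kj − ⟨G_k, Fn_k⟩) / s_k,  G = (2/N) Aᵀ E.
        s_row = R.sum(axis=1, keepdims=True)
        E = A @ Fn - S
        if w is not None:
            E = E * (w * w)
        G = (2.0 / E.size) * A.T @ E
        g = (G - (G * Fn).sum(axis=1, keepdims=True)) / s_row
        g[~free] = 0.0
        if not np.any(g):
            converged = True
            break

        # multiplicative preconditioning: descend in log-ratio space
        # (d ∝ −g·R², i.e. equal relative sensitivity), the natural metric
        # for elements constrained to a multiplicative band
        d = -g * R * R
        rel = np.abs(d[free]) / np.maximum(R[free], 1e-12)
        if rel.max() == 0.0:
            converged = True
            break
        t = cfg.step_init / rel.max()

        # line search on the joint objective: abundances are re-solved at
        # each trial matrix, so accepted steps reduce the true residual
        def trial(step: float) -> tuple[np.ndarray, float]:
            Rt = np.clip(R + step * d, lo, hi)
            Rt[~free] = R[~free]
            Fn_t = _row_normalize(Rt)
            return Rt, _rmse(S, _solve_all(Fn_t, S), Fn_t, w)

        accepted = False
        for _ in range(20):
            Rt, val = trial(t)
            if val < base:
                accepted = True
                break
            t *= 0.5
        if not accepted:
            converged = True
            break
        # greedy expansion: keep doubling while the objective improves
        for _ in range(10):
            Rt2, val2 = trial(2 * t)
            if val2 < val:
                t, Rt, val = 2 * t, Rt2, val2
            else:
                break
        R = Rt
    # final abundances at the final matrix
    Fn = _row_normalize(R)
    A = _solve_all(Fn, S)
    final = _rmse(S, A, Fn, w)
    if not trajectory or final < trajectory[-1]:
        trajectory.append(final)
    return A, R, trajectory[-1], it, converged, trajectory


def _align(S: SampleMatrix, R0: TaxonRatioMatrix) -> tuple[list[str], np.ndarray, np.ndarray]:
    common = [f for f in R0.fas if f in S.fas]
    extra = [f for f in S.fas if f not in R0.fas]
    if extra:
        warnings.warn(
            f"dropping sample FAs absent from the ratio matrix: {extra}",
            stacklevel=3,
        )
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} FAs shared between samples and ratio matrix; need >= 3"
        )
    cols = [S.fas.index(f) for f in common]
    Ssub = S.values[:, cols]
    tot = Ssub.sum(axis=1)
    if (tot <= 0).any():
        zero = [s for s, v in zip(S.sample_ids, tot) if v <= 0]
        raise ValueError(f"samples with zero mass on the shared FA set: {zero}")
    Sprop = Ssub / tot[:, None]
    Rsub = R0.data[common].to_numpy()
    return common, Sprop, Rsub


def _weights(cfg: UnmixingConfig, fas: Sequence[str]) -> np.ndarray | None:
    if cfg.fa_weights is None:
        return None
    w = np.array([float(cfg.fa_weights.get(f, 1.0)) for f in fas])
    return w


def _result(
    S: SampleMatrix,
    R0: TaxonRatioMatrix,
    common: list[str],
    A: np.ndarray,
    R: np.ndarray,
    rmse: float,
    n_iter: int,
    converged: bool,
    trajectory: list[float],
) -> UnmixingResult:
    abundances = pd.DataFrame(A, index=S.sample_ids, columns=R0.taxa)
    data = R0.data.copy()
    data[common] = R
    ratio_out = TaxonRatioMatrix(data, provenance=f"{R0.provenance} (optimized)")
    return UnmixingResult(
        abundances=abundances,
        ratio_out=ratio_out,
        rmse=rmse,
        n_iter=n_iter,
        converged=converged,
        rmse_trajectory=trajectory,
    )


# --------------------------------------------------------------------------
# public operations

def solve_abundances(
    R: TaxonRatioMatrix, sample: Mapping[str, float] | pd.Series
) -> tuple[pd.Series, float]:
    """Abundances of one sample for a fixed ratio matrix.

    The sample composition is expressed as proportions of its total FA and
    fit by nonnegative least squares onto the row-normalized taxon
    signatures; the abundance vector is renormalized to sum 1.  Returns
    ``(abundances, residual_rmse)``.
    """
    vals = {canonicalize(k): float(v) for k, v in dict(sample).items()}
    if any(v < 0 for v in vals.values()):
        raise ValueError("sample contains negative quantities")
    common = [f for f in R.fas if f in vals]
    if len(common) < 3:
        raise ValueError(f"only {len(common)} FAs shared with the ratio matrix; need >= 3")
    s = np.array([vals[f] for f in common])
    if s.sum() <= 0:
        raise ValueError("sample has zero mass on the shared FA set")
    s = s / s.sum()
    Fn = _row_normalize(R.data[common].to_numpy())
    a = _solve_all(Fn, s[None, :])[0]
    resid = _rmse(s[None, :], a[None, :], Fn, None)
    return pd.Series(a, index=R.taxa), resid


def fit(S: SampleMatrix, R0: TaxonRatioMatrix, cfg: UnmixingConfig | None = None) -> UnmixingResult:
    """Single bounded-optimization run (abundances + adjusted ratio matrix).

    Alternates NNLS abundance solves with projected steepest-descent steps
    on the nonzero ratio elements inside ``[R0/bound, R0×bound]``; the
    RMSE sequence is non-increasing.  Non-convergence within ``max_iter``
    is reported via ``converged=False``, never an exception.
    """
    cfg = cfg or UnmixingConfig()
    common, Sprop, Rsub = _align(S, R0)
    free = (Rsub > 0) & (np.array(common) != REFERENCE_FA)[None, :]
    lo = np.where(Rsub > 0, Rsub / cfg.bound_factor, 0.0)
    hi = np.where(Rsub > 0, Rsub * cfg.bound_factor, 0.0)
    w = _weights(cfg, common)
    A, R, rmse, n_iter, converged, traj = _fit_core(Sprop, Rsub, lo, hi, free, cfg, w)
    return _result(S, R0, common, A, R, rmse, n_iter, converged, traj)


def successive_runs(
    S: SampleMatrix, R0: TaxonRatioMatrix, cfg: UnmixingConfig | None = None
) -> UnmixingResult:
    """Successive-runs protocol: feed each run's optimized matrix forward.

    Performs ``n_successive_runs`` fits, seeding each with the previous
    run's ``ratio_out``, and returns the run with minimal RMSE.  Because
    each run starts at the previous optimum, the RMSE sequence is
    non-increasing (up to line-search tolerance).
    """
    cfg = cfg or UnmixingConfig()
    R_in = R0
    best: UnmixingResult | None = None
    for _ in range(max(1, cfg.n_successive_runs)):
        res = fit(S, R_in, cfg)
        if best is None or res.rmse <= best.rmse:
            best = res
        R_in = res.ratio_out
    return best  # type: ignore[return-value]


def randomized_starts(
    S: SampleMatrix, R0: TaxonRatioMatrix, cfg: UnmixingConfig | None = None
) -> UnmixingResult:
    """Randomized-starts protocol: many perturbed inputs, best fraction kept.

    Each start multiplies the nonzero elements of ``R0`` by seeded random
    factors inside the adjustment bound (scaled by ``start_jitter``), fits
    it within the box anchored at ``R0``, and the element-wise mean of the
    best ``best_fraction`` of optimized matrices is refit once.  Bounds are
    anchored at ``R0`` throughout, so the returned matrix respects the
    original adjustment bound.  Fully reproducible under a fixed seed.
    """
    cfg = cfg or UnmixingConfig()
    common, Sprop, Rsub = _align(S, R0)
    free = (Rsub > 0) & (np.array(common) != REFERENCE_FA)[None, :]
    lo = np.where(Rsub > 0, Rsub / cfg.bound_factor, 0.0)
    hi = np.where(Rsub > 0, Rsub * cfg.bound_factor, 0.0)
    w = _weights(cfg, common)
    rng = np.random.default_rng(cfg.seed)

    n = max(1, cfg.n_random_starts)
    fits: list[tuple[float, tuple]] = []
    for _ in range(n):
        u = rng.uniform(-1.0, 1.0, size=Rsub.shape)
        factors = np.exp(u * cfg.start_jitter * np.log(cfg.bound_factor))
        R_start = Rsub.copy()
        R_start[free] = np.clip(Rsub[free] * factors[free], lo[free], hi[free])
        out = _fit_core(Sprop, R_start, lo, hi, free, cfg, w)
        fits.append((out[2], out))
    fits.sort(key=lambda t: t[0])
    n_best = max(1, int(np.ceil(cfg.best_fraction * n)))
    if n_best == 1:
        # averaging a single optimized matrix and refitting from its own
        # optimum is a no-op; return that fit directly
        A, R, rmse, n_iter, converged, traj = fits[0][1]
        return _result(S, R0, common, A, R, rmse, n_iter, converged, traj)
    R_mean = np.mean([out[1] for _, out in fits[:n_best]], axis=0)
    R_mean[~free] = Rsub[~free]
    A, R, rmse, n_iter, converged, traj = _fit_core(Sprop, R_mean, lo, hi, free, cfg, w)
    return _result(S, R0, common, A, R, rmse, n_iter, converged, traj)


def run_by_location(
    S: SampleMatrix,
    R0: TaxonRatioMatrix,
    membership: Mapping[str, Sequence[str]],
    cfg: UnmixingConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, UnmixingResult]]:
    """Independent fits per location using only the taxa present there.

    ``membership`` maps each location to its taxon subset; every sample
    must carry a location in ``S.location``.  Returns the merged abundance
    table (absent taxa reported as exact 0) and the per-location results.
    """
    cfg = cfg or UnmixingConfig()
    unassigned = [s for s in S.sample_ids if s not in S.location]
    if unassigned:
        raise ValueError(f"samples without a location: {unassigned}")
    for loc, taxa in membership.items():
        if not list(taxa):
            raise ValueError(f"location {loc!r} has an empty taxon subset")
        missing = [t for t in taxa if t not in R0.taxa]
        if missing:
            raise KeyError(f"location {loc!r} references unknown taxa {missing}")

    results: dict[str, UnmixingResult] = {}
    merged = pd.DataFrame(0.0, index=S.sample_ids, columns=R0.taxa)
    for loc, taxa in membership.items():
        ids = [s for s in S.sample_ids if S.location[s] == loc]
        if not ids:
            raise ValueError(f"location {loc!r} has no samples")
        rows = [S.sample_ids.index(s) for s in ids]
        sub = SampleMatrix(
            sample_ids=ids,
            fas=list(S.fas),
            values=S.values[rows],
            location={s: loc for s in ids},
        )
        res = fit(sub, R0.restrict(list(taxa)), cfg)
        results[loc] = res
        merged.loc[ids, list(taxa)] = res.abundances[list(taxa)].to_numpy()
    return merged, results
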