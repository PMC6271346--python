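import numpy as np
import pandas as pd
import pytest

import plfatax as px


@pytest.fixture(scope="session")
def ratio_input() -> px.TaxonRatioMatrix:
    return px.load_ratio_matrix_input()


@pytest.fixture(scope="session")
def ratio_output() -> px.TaxonRatioMatrix:
    return px.load_ratio_matrix_output()


@pytest.fixture(scope="session")
def small_matrix() -> px.TaxonRatioMatrix:
    """Well-separated 3-taxon × 8-FA signature matrix for recovery tests."""
    fas = ["16:0", "16:1ω7c", "18:1ω9c", "18:2ω6c", "18:3ω3", "20:5ω3", "a-15:0", "cy17:0"]
    data = pd.DataFrame(
        [
            [1, 0.2, 0.1, 0.0, 0.0, 1.8, 0.0, 0.0],
            [1, 0.1, 1.9, 0.6, 2.3, 0.0, 0.0, 0.0],
            [1, 0.9, 0.05, 0.0, 0.0, 0.0, 1.2, 0.4],
        ],
        index=["diatom-like", "green-like", "bacteria-like"],
        columns=fas,
    )
    return px.TaxonRatioMatrix(data)


def simplex_grid_argmin(Fn: np.ndarray, s: np.ndarray, resolution: float = 1e-4) -> np.ndarray:
    """Exhaustive simplex grid search for min ||aᵀFn − s||², a on the simplex.

    Independent oracle for the NNLS route: evaluates the quadratic objective
    on a full coarse grid over the simplex, then on a full fine grid (step
    ``resolution``) inside a window around the coarse optimum.  The
    objective is convex, so the refinement window (±3 coarse cells) contains
    the optimum for any reasonably conditioned instance.
    """
    k = Fn.shape[0]
    Q = Fn @ Fn.T
    b = Fn @ s

    def value(A: np.ndarray) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", A, Q, A) - 2.0 * A @ b

    def grid(lo: np.ndarray, hi: np.ndarray, step: float) -> np.ndarray:
        axes = [np.arange(max(0.0, l), min(1.0, h) + step / 2, step) for l, h in zip(lo, hi)]
        if k == 2:
            a0 = axes[0]
            return np.column_stack([a0, 1.0 - a0])
        assert k == 3
        pts = []
        for a0 in axes[0]:
            a1 = axes[1]
            a1 = a1[a1 <= 1.0 - a0 + step / 2]
            if a1.size == 0:
                continue
            a2 = 1.0 - a0 - a1
            ok = a2 >= -step / 2
            pts.append(np.column_stack([np.full(ok.sum(), a0), a1[ok], np.clip(a2[ok], 0, 1)]))
        return np.concatenate(pts)

    coarse = 0.01
    A = grid(np.zeros(k), np.ones(k), coarse)
    best = A[np.argmin(value(A))]
    A = grid(best - 3 * coarse, best + 3 * coarse, resolution)
    A = A / A.sum(axis=1, keepdims=True)
    return A[np.argmin(value(A))]
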