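"""Sparse non-negative matrix factorization of optical density.

Factorizes the OD pixel matrix as ``V ~ W H`` with ``W >= 0`` the stain
vectors and ``H >= 0`` the concentrations, minimizing

    f(W, H) = 0.5 * ||V - W H||_F^2 + sparsity * sum(H)

by multiplicative updates, which keep the objective non-increasing.  The
L1 penalty on concentrations encourages pixels to be explained by few
stains, which stabilizes the vectors when stains co-localize weakly.
"""

from __future__ import annotations

import warnings

import numpy as np

from .deconvolution import StainMatrix
from .density import DEFAULT_BACKGROUND, rgb_to_od
from .macenko import estimate_stains_macenko, order_stain_columns

__all__ = ["estimate_stains_snmf", "snmf_objective"]

_EPS = 1e-12


def snmf_objective(v, w, h, sparsity):
    resid = v - w @ h
    return 0.5 * float(np.sum(resid * resid)) + sparsity * float(np.sum(h))


def estimate_stains_snmf(
    im_rgb,
    sparsity: float = 0.1,
    init=None,
    od_threshold: float = 0.15,
    max_iter: int = 200,
    tol: float = 1e-6,
    bg_intensity: float = DEFAULT_BACKGROUND,
    return_objective: bool = False,
):
    """Estimate stain vectors by sparse NMF of the OD pixel cloud.

    Parameters
    ----------
    im_rgb : (H, W, 3) array
        RGB field containing both stains.
    sparsity : float
        L1 weight on concentrations; 0 gives plain NMF.
    init : StainMatrix, array or None
        Initial stain vectors; estimated via Macenko when None.
    max_iter, tol : int, float
        Iteration budget and relative objective tolerance.
    return_objective : bool
        Also return the per-iteration objective values.

    Returns
    -------
    StainMatrix (and optionally the objective trace).  If the iteration
    budget is exhausted before the tolerance is met, the best iterate is
    returned with a warning.
    """
    od = rgb_to_od(im_rgb, bg_intensity).reshape(-1, 3)
    keep = np.linalg.norm(od, axis=1) >= od_threshold
    v = od[keep].T  # 3 x N
    if v.shape[1] < 50:
        raise ValueError("too few above-threshold pixels for factorization")

    if init is None:
        init = estimate_stains_macenko(
            im_rgb, od_threshold=od_threshold, bg_intensity=bg_intensity
        )
    w0 = init.matrix if isinstance(init, StainMatrix) else np.asarray(init, dtype=float)
    w = np.maximum(w0[:, :2], _EPS).astype(float).copy()

    # Nonnegative least-squares-ish warm start for H via projected solve.
    h = np.maximum(np.linalg.lstsq(w, v, rcond=None)[0], _EPS)

    trace = [snmf_objective(v, w, h, sparsity)]
    converged = False
    for _ in range(max_iter):
        h *= (w.T @ v) / (w.T @ w @ h + sparsity + _EPS)
        w *= (v @ h.T) / (w @ (h @ h.T) + _EPS)
        trace.append(snmf_objective(v, w, h, sparsity))
        if abs(trace[-2] - trace[-1]) <= tol * max(abs(trace[-2]), _EPS):
            converged = True
            break
    if not converged:
        warnings.warn(
            f"SNMF did not reach tolerance {tol} in {max_iter} iterations; "
            "returning best iterate",
            UserWarning,
        )

    result = order_stain_columns(w)
    if return_objective:
        return result, np.array(trace)
    return result
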