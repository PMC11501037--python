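"""Archetypal analysis of the behavioral descriptor matrix.

Archetypal analysis (AA) approximates each observation as a convex
combination of k *archetypes* — extreme, idealised behavioral profiles that
themselves lie in the convex hull of the data.  Given the n x m matrix X it
minimises ``|| X - A Z ||_F^2`` over

* ``A`` (n x k): per-animal simplex weights (rows >= 0, summing to 1) — the
  *archetypal composition*; and
* ``Z`` (k x m): archetype coordinates, constrained to ``Z = D X`` with
  convex rows ``D`` (k x n), which pins every archetype inside the data hull.

The fit alternates two convexly-constrained least-squares steps
(Cutler-Breiman scheme): simplex-constrained weights for each animal given
Z, then a hull-constrained update of Z given the weights.  Each
simplex-constrained subproblem is solved by non-negative least squares on a
system augmented with a large penalty row enforcing the sum-to-one
constraint.

With k = 3 on the five choice descriptors the archetypes are labelled
Tracker (highest preference for the high-value side), Non-Switcher (highest
side bias among the rest) and Explorer (the remainder).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .descriptors import DESCRIPTOR_COLUMNS, DescriptorMatrix

#: Penalty constant of the sum-to-one row in the augmented NNLS systems.
SUM_PENALTY = 200.0

ARCHETYPE_NAMES = ("Tracker", "Explorer", "NonSwitcher")

__all__ = [
    "ArchetypeModel",
    "fit_archetypes",
    "project_alphas",
    "label_archetypes",
    "ternary_coordinates",
    "barycentric_coordinates",
    "composition_table",
]


@dataclass
class ArchetypeModel:
    """A fitted archetypal decomposition.

    Attributes
    ----------
    Z : (k, m) array
        Archetype coordinates in the space the model was fitted in.
    alphas : (n, k) array
        Simplex weights per observation (archetypal composition).
    delta_weights : (k, n) array
        Convex data weights defining each archetype, ``Z = delta_weights @ X``.
    rss : float
        Residual sum of squares of the best restart.
    rss_history : list of float
        Accepted RSS values of the best restart, non-increasing.
    """

    Z: np.ndarray
    alphas: np.ndarray
    delta_weights: np.ndarray
    rss: float
    n_iter: int
    converged: bool
    restart_index: int
    seed: int | None = None
    rss_history: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.Z.shape[0]


def _simplex_lsq(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """min ||A w - b|| subject to w >= 0, sum(w) = 1 (penalty-row NNLS)."""
    k = A.shape[1]
    A_aug = np.vstack([A, np.full((1, k), SUM_PENALTY)])
    b_aug = np.append(b, SUM_PENALTY)
    w, _ = nnls(A_aug, b_aug)
    s = w.sum()
    if s > 0:  # exact renormalisation removes the O(1/M^2) penalty slack
        w = w / s
    return w


def _alphas_for(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    At = Z.T  # m x k
    return np.vstack([_simplex_lsq(At, x) for x in X])


def _rss(X: np.ndarray, alphas: np.ndarray, Z: np.ndarray) -> float:
    r = X - alphas @ Z
    return float(np.sum(r * r))


def fit_archetypes(
    X: np.ndarray,
    k: int = 3,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int | None = None,
) -> ArchetypeModel:
    """Fit k archetypes to the rows of X by alternating convex least squares.

    Each restart initialises the archetypes at k distinct random data rows;
    the restart with the lowest residual sum of squares wins.  Within a
    restart the RSS of the accepted iterates is non-increasing: an iterate
    that would raise it (possible only through the hull-projection step)
    terminates the restart at the previous best.

    Deterministic given ``(X, k, n_restarts, max_iter, tol, seed)``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-dimensional")
    n, m = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n <= k:
        raise ValueError(f"need more observations than archetypes: n={n}, k={k}")

    rng = np.random.default_rng(seed)
    best: ArchetypeModel | None = None
    for restart in range(n_restarts):
        rows = rng.choice(n, size=k, replace=False)
        Z = X[rows].copy()
        alphas = _alphas_for(Z, X)
        rss = _rss(X, alphas, Z)
        history = [rss]
        best_state = (Z, alphas, rss)
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            # hull-constrained Z update: unconstrained LS target, then each
            # archetype re-expressed as a convex combination of data rows
            Zt, *_ = np.linalg.lstsq(alphas, X, rcond=None)
            delta = np.vstack([_simplex_lsq(X.T, z) for z in Zt])
            Z_new = delta @ X
            alphas_new = _alphas_for(Z_new, X)
            rss_new = _rss(X, alphas_new, Z_new)
            if rss_new > best_state[2] * (1 + 1e-12) + 1e-15:
                converged = True  # hull projection can no longer improve; keep best
                break
            rel = (best_state[2] - rss_new) / max(best_state[2], 1e-300)
            Z, alphas, rss = Z_new, alphas_new, rss_new
            best_state = (Z, alphas, rss)
            history.append(rss)
            if rel < tol:
                converged = True
                break
        Z, alphas, rss = best_state
        delta = np.vstack([_simplex_lsq(X.T, z) for z in Z])
        model = ArchetypeModel(
            Z=Z, alphas=alphas, delta_weights=delta, rss=rss,
            n_iter=it, converged=converged, restart_index=restart,
            seed=seed, rss_history=history,
        )
        if best is None or model.rss < best.rss:
            best = model
    assert best is not None
    if not best.converged:
        warnings.warn("no restart reached the convergence tolerance; best iterate returned")
    return best


def project_alphas(model: ArchetypeModel, x: np.ndarray) -> np.ndarray:
    """Simplex weights of a new observation on the fitted archetypes."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.Z.shape[1],):
        raise ValueError(
            f"x must have dimension {model.Z.shape[1]}, got shape {x.shape}"
        )
    return _simplex_lsq(model.Z.T, x)


def label_archetypes(
    model: ArchetypeModel, dmatrix: DescriptorMatrix
) -> dict[int, str]:
    """Name the three archetypes from their raw-unit descriptor coordinates.

    Tracker is the archetype with the highest ``pref`` coordinate (it goes
    most often to the high-value side); among the remaining two the
    Non-Switcher has the higher ``side_bias``; the Explorer is the last.
    """
    if model.k != 3:
        raise ValueError(f"semantic labels are defined for k = 3, got k = {model.k}")
    Zraw = dmatrix.unscale(model.Z)
    pref_col = DESCRIPTOR_COLUMNS.index("pref")
    bias_col = DESCRIPTOR_COLUMNS.index("side_bias")
    switch_col = DESCRIPTOR_COLUMNS.index("switch")

    pref = Zraw[:, pref_col]
    order = np.argsort(-pref, kind="stable")
    if pref[order[0]] == pref[order[1]]:
        warnings.warn("tie on pref; breaking by side_bias then index")
        tied = np.flatnonzero(pref == pref[order[0]])
        # the tied archetype with the LOWER side bias is the better Tracker
        tracker = int(tied[np.argsort(Zraw[tied, bias_col], kind="stable")[0]])
    else:
        tracker = int(order[0])
    rest = [i for i in range(3) if i != tracker]
    bias = Zraw[rest, bias_col]
    if bias[0] == bias[1]:
        warnings.warn("tie on side_bias; breaking by switch")
        ns = rest[int(np.argsort(-Zraw[rest, switch_col], kind="stable")[1])]
    else:
        ns = rest[int(np.argmax(bias))]
    explorer = next(i for i in rest if i != ns)
    return {tracker: "Tracker", explorer: "Explorer", ns: "NonSwitcher"}


_SQRT3 = np.sqrt(3.0)
#: Cartesian vertices of the reference ternary triangle, archetype order.
TERNARY_VERTICES = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, _SQRT3 / 2.0]])


def ternary_coordinates(alphas: np.ndarray) -> np.ndarray:
    """Barycentric (k = 3) simplex weights -> Cartesian plane coordinates."""
    a = np.atleast_2d(np.asarray(alphas, dtype=float))
    if a.shape[1] != 3:
        raise ValueError("ternary coordinates require k = 3 weights")
    if np.any(a < -1e-6) or np.any(np.abs(a.sum(axis=1) - 1) > 1e-6):
        raise ValueError("weights are off the simplex beyond 1e-6")
    xy = a @ TERNARY_VERTICES
    return xy[0] if np.asarray(alphas).ndim == 1 else xy


def barycentric_coordinates(xy: np.ndarray) -> np.ndarray:
    """Inverse of :func:`ternary_coordinates` on the simplex."""
    p = np.atleast_2d(np.asarray(xy, dtype=float))
    a3 = p[:, 1] / TERNARY_VERTICES[2, 1]
    a2 = p[:, 0] - 0.5 * a3
    a1 = 1.0 - a2 - a3
    out = np.column_stack([a1, a2, a3])
    return out[0] if np.asarray(xy).ndim == 1 else out


def composition_table(
    model: ArchetypeModel,
    mouse_ids: list[str],
    labels: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Per-animal composition: alpha per archetype, nearest label, ternary x/y."""
    if len(mouse_ids) != model.alphas.shape[0]:
        raise ValueError("mouse_ids length must match the number of fitted rows")
    names = (
        [labels[i] for i in range(model.k)]
        if labels is not None
        else [f"archetype_{i + 1}" for i in range(model.k)]
    )
    df = pd.DataFrame(
        model.alphas, columns=[f"alpha_{n}" for n in names],
        index=pd.Index(mouse_ids, name="mouse_id"),
    )
    nearest = np.argmax(model.alphas, axis=1)
    df["nearest"] = [names[i] for i in nearest]
    if model.k == 3:
        xy = ternary_coordinates(model.alphas)
        df["ternary_x"] = xy[:, 0]
        df["ternary_y"] = xy[:, 1]
    return df
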