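"""Delta-rule reinforcement learning with softmax choice and perseveration.

The model tracks one expected value per T-maze side.  After each trial the
chosen side's value is updated by the delta rule

    V <- V + alpha * (R - V)

with learning rate ``alpha`` and reward R equal to the value of the solution
delivered on the chosen side (1 for water or saccharin, 3 for sucrose, 0.3
for nicotine+saccharin).  The probability of choosing the right side is a
softmax over the value difference plus a perseveration term,

    P_R(t) = 1 / (1 + exp(-[beta (V_R - V_L) + chi (C_R(t-1) - C_L(t-1))]))

where ``beta`` is the inverse temperature (sensitivity to the value
difference), ``chi`` the perseveration weight (tendency to repeat, chi > 0,
or alternate, chi < 0, the previous side regardless of reward), and the
choice indicators C are 1 for the side taken on the previous trial and 0
otherwise; before the first trial the perseveration term is zero.

Fitting maximises the sequence likelihood under box constraints
alpha in (0, 1], beta in (0, 20], chi in [-2, 2], with expected values
started at zero.  The three-parameter model is compared against the nested
two-parameter (chi = 0) variant by BIC and a likelihood-ratio test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .trial_data import MouseRecord

#: Numerical floor standing in for the open end of ]0, ...] bounds.
EPS_BOUND = 1e-6
ALPHA_BOUNDS = (EPS_BOUND, 1.0)
BETA_BOUNDS = (EPS_BOUND, 20.0)
CHI_BOUNDS = (-2.0, 2.0)
#: Per-trial probability floor applied before the log during likelihood search.
PROB_FLOOR = 1e-12

__all__ = [
    "LatentTriplet",
    "ValueState",
    "FitConfig",
    "FitResult",
    "update_value",
    "choice_probability",
    "sequence_nll",
    "fit_mouse",
    "fit_reduced",
    "compare_models",
]


@dataclass(frozen=True)
class LatentTriplet:
    """The three latent decision parameters of one animal."""

    alpha: float
    beta: float
    chi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= ALPHA_BOUNDS[1]):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not (0.0 < self.beta <= BETA_BOUNDS[1]):
            raise ValueError(f"beta must be in (0, 20], got {self.beta}")
        if not (CHI_BOUNDS[0] <= self.chi <= CHI_BOUNDS[1]):
            raise ValueError(f"chi must be in [-2, 2], got {self.chi}")

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.chi], dtype=float)


@dataclass
class ValueState:
    """Expected value per side plus the previous choice."""

    v_left: float = 0.0
    v_right: float = 0.0
    prev_choice: str = "none"

    def __post_init__(self) -> None:
        if self.prev_choice not in ("L", "R", "none"):
            raise ValueError(f"prev_choice must be L, R or none, got {self.prev_choice!r}")


def update_value(v: float, reward: float, alpha: float) -> float:
    """Delta-rule update of the chosen option's expected value."""
    if not (0.0 <= alpha <= 1.0):
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return v + alpha * (reward - v)


def choice_probability(state: ValueState, beta: float, chi: float) -> float:
    """P(choose right) under the softmax-with-perseveration rule."""
    c_term = 0.0
    if state.prev_choice == "R":
        c_term = 1.0
    elif state.prev_choice == "L":
        c_term = -1.0
    z = beta * (state.v_right - state.v_left) + chi * c_term
    # numerically stable logistic
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    e = math.exp(z)
    return e / (1.0 + e)


def _nll_core_py(chosen, reward, alpha, beta, chi, v0):
    """Sequential negative log-likelihood; ``chosen`` coded L=0, R=1."""
    v_l = v0
    v_r = v0
    prev = 0.0  # C_R - C_L of the previous trial; 0 before the first
    nll = 0.0
    for t in range(chosen.shape[0]):
        z = beta * (v_r - v_l) + chi * prev
        if z >= 0:
            p_r = 1.0 / (1.0 + math.exp(-z))
        else:
            e = math.exp(z)
            p_r = e / (1.0 + e)
        p = p_r if chosen[t] == 1 else 1.0 - p_r
        if p < PROB_FLOOR:
            p = PROB_FLOOR
        nll -= math.log(p)
        if chosen[t] == 1:
            v_r = v_r + alpha * (reward[t] - v_r)
            prev = 1.0
        else:
            v_l = v_l + alpha * (reward[t] - v_l)
            prev = -1.0
    return nll


try:  # jit-compile the inner loop when numba is available
    from numba import njit

    _nll_core = njit(cache=False)(_nll_core_py)
    _nll_core(np.zeros(1, dtype=np.int8), np.ones(1), 0.5, 1.0, 0.0, 0.0)
except Exception:  # pragma: no cover - exercised only without numba
    _nll_core = _nll_core_py


def sequence_nll(
    record: MouseRecord,
    triplet: LatentTriplet | tuple[float, float, float],
    v0: float = 0.0,
) -> float:
    """Negative log-likelihood (nats) of a choice sequence.

    Rewards are deterministic: each trial delivers the value of the solution
    on the chosen side, read from the record's sessions.  Learned values
    carry across session boundaries — a bottle swap changes which side pays
    which value, not the animal's estimates.  ``v0`` initialises both values
    (0 for fitting).
    """
    if record.n_trials == 0:
        raise ValueError(f"mouse {record.mouse_id}: empty record")
    if isinstance(triplet, LatentTriplet):
        a, b, c = triplet.alpha, triplet.beta, triplet.chi
    else:
        a, b, c = triplet
    chosen, reward, _ = record.reward_arrays()
    return float(_nll_core(chosen, reward, float(a), float(b), float(c), float(v0)))


@dataclass
class FitConfig:
    """Settings for maximum-likelihood fitting."""

    n_starts: int = 20
    tol: float = 1e-8
    seed: int | None = None
    v0: float = 0.0
    min_trials: int = 10
    alpha_bounds: tuple[float, float] = ALPHA_BOUNDS
    beta_bounds: tuple[float, float] = BETA_BOUNDS
    chi_bounds: tuple[float, float] = CHI_BOUNDS


@dataclass
class FitResult:
    """A fitted model for one animal."""

    triplet: LatentTriplet
    nll: float
    n_trials: int
    bic: float
    n_params: int
    converged: bool
    n_starts_used: int
    best_start: int


# fixed starts spanning the box, used before the random ones
_FIXED_STARTS = (
    (0.5, 1.0, 0.0),
    (0.9, 5.0, 0.0),
    (0.05, 5.0, 0.0),
    (0.3, 0.5, 0.0),
)


def _fit(record: MouseRecord, config: FitConfig, fix_chi: bool) -> FitResult:
    if record.n_trials < config.min_trials:
        raise ValueError(
            f"mouse {record.mouse_id}: {record.n_trials} trials "
            f"(< {config.min_trials}) — too few to fit"
        )
    chosen, reward, _ = record.reward_arrays()
    v0 = float(config.v0)
    lo = np.array([config.alpha_bounds[0], config.beta_bounds[0], config.chi_bounds[0]])
    hi = np.array([config.alpha_bounds[1], config.beta_bounds[1], config.chi_bounds[1]])

    if fix_chi:
        def objective(x):
            return _nll_core(chosen, reward, x[0], x[1], 0.0, v0)
        bounds = list(zip(lo[:2], hi[:2]))
        fixed = [s[:2] for s in _FIXED_STARTS]
        ndim, n_params = 2, 2
    else:
        def objective(x):
            return _nll_core(chosen, reward, x[0], x[1], x[2], v0)
        bounds = list(zip(lo, hi))
        fixed = list(_FIXED_STARTS)
        ndim, n_params = 3, 3

    rng = np.random.default_rng(config.seed)
    starts = [np.asarray(s, dtype=float) for s in fixed[: config.n_starts]]
    while len(starts) < config.n_starts:
        starts.append(rng.uniform(lo[:ndim], hi[:ndim]))

    best = None
    failures = []
    for i, x0 in enumerate(starts):
        res = minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": config.tol, "gtol": 1e-8, "maxiter": 500},
        )
        if not np.isfinite(res.fun):
            failures.append(res.message)
            continue
        # ties broken by the earlier start
        if best is None or res.fun < best[1].fun - 1e-9:
            best = (i, res)
    if best is None:
        raise RuntimeError(
            f"mouse {record.mouse_id}: optimizer failed on all starts: {failures}"
        )
    start_idx, res = best
    x = res.x
    triplet = LatentTriplet(
        alpha=float(np.clip(x[0], EPS_BOUND, 1.0)),
        beta=float(np.clip(x[1], EPS_BOUND, 20.0)),
        chi=0.0 if fix_chi else float(np.clip(x[2], -2.0, 2.0)),
    )
    nll = float(res.fun)
    n = record.n_trials
    return FitResult(
        triplet=triplet,
        nll=nll,
        n_trials=n,
        bic=2.0 * nll + n_params * math.log(n),
        n_params=n_params,
        converged=bool(res.success),
        n_starts_used=len(starts),
        best_start=start_idx,
    )


def fit_mouse(record: MouseRecord, config: FitConfig | None = None) -> FitResult:
    """Maximum-likelihood fit of (alpha, beta, chi) for one animal.

    Multi-start bounded L-BFGS-B: a handful of fixed starts covering the
    parameter box followed by seeded uniform draws; the lowest negative
    log-likelihood wins, ties going to the earlier start.
    """
    return _fit(record, config or FitConfig(), fix_chi=False)


def fit_reduced(record: MouseRecord, config: FitConfig | None = None) -> FitResult:
    """Fit of the nested two-parameter model (chi pinned to 0)."""
    return _fit(record, config or FitConfig(), fix_chi=True)


def compare_models(fit_full: FitResult, fit_reduced: FitResult) -> dict[str, float]:
    """BIC difference and likelihood-ratio test of full vs chi = 0 model.

    ``lrt_statistic`` = 2 (nll_reduced - nll_full), chi-square with 1 df
    under the null; a (numerically) negative statistic is clipped to zero
    with a warning.  ``delta_bic`` > 0 favours the full model.
    """
    if fit_full.n_trials != fit_reduced.n_trials:
        raise ValueError("fits compare different numbers of trials")
    stat = 2.0 * (fit_reduced.nll - fit_full.nll)
    if stat < 0:
        warnings.warn(f"negative LRT statistic {stat:.3g} clipped to 0 (optimizer noise)")
        stat = 0.0
    return {
        "delta_bic": fit_reduced.bic - fit_full.bic,
        "lrt_statistic": stat,
        "lrt_p": float(chi2.sf(stat, df=1)),
    }
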