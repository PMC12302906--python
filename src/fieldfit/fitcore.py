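"""Per-gene expression model and its two-tier fitting procedure.

A gene's log2(rpm+1) expression is modeled as the sum of three sub-models and
their interactions with the environmental input::

    y = b0 + b_age * age + b_cos * cos(2*pi*clock/24) + b_sin * sin(...)
        + x * (b_e + b_e_age * age + b_e_cos * cos(...) + b_e_sin * sin(...))

where ``x`` is a gated, clipped look-back mean of one environmental variable
(temperature or irradiance).  The gate weights the variable by time of day —
a plant may respond to light or heat only during part of the diel cycle — and
is controlled by 7 nonlinear parameters (window length T, lag D, gate peak
phi, gate depth gamma, gate sharpness w, clipping bounds theta_lo/theta_hi)
that cannot be handled by the penalized linear solver.  They are optimized by
grid search followed by Nelder-Mead; the linear coefficients are fitted at
every candidate by an adaptive group LASSO and models are compared by BIC.

The clock phase enters through the cos/sin pair, so it is estimated by the
linear stage (phase = atan2(b_sin, b_cos)); whole sub-models can be zeroed as
coefficient groups: G1 = {b_age}, G2 = {b_cos, b_sin}, G3 = the four
environmental terms.  A gene whose winning model zeroes G3 responds to
neither variable.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import minimize

from ._agl import _agl_best, _agl_best_batch, _fista, _pilot_weights, _power_L
from .data import EnvSeries, EnvStack, SampleSet, LOOKBACK_H

VARIABLES = ("temperature", "radiation")

#: column ids of the 8-column design row
DESIGN_COLUMNS = ["b0", "b_age", "b_cos", "b_sin", "b_e", "b_e_age", "b_e_cos", "b_e_sin"]
#: penalized-group membership of the 7 non-intercept columns
GROUP_IDS = np.array([0, 1, 1, 2, 2, 2, 2], dtype=np.int64)
N_GROUPS = 3
_ENV_SLICE = slice(4, 8)  # G3 columns within the full 8-vector


@dataclass(frozen=True)
class NonlinearParams:
    """The 7 nonlinear parameters of the environmental-response sub-model.

    T : look-back window length (h), D : lag between window end and the
    sample (h), phi : clock time of peak responsiveness (h), gamma : gate
    depth in [0, 1] (0 = ungated), w : gate sharpness (> 0), theta_lo /
    theta_hi : clipping bounds on the environmental variable.
    """

    T: float
    D: float
    phi: float
    gamma: float
    w: float
    theta_lo: float
    theta_hi: float

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("window length T must be positive")
        if self.D < 0:
            raise ValueError("lag D must be non-negative")
        if self.T + self.D > LOOKBACK_H + 1e-9:
            raise ValueError(f"T + D must not exceed the {LOOKBACK_H:.0f}-h look-back")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gate depth gamma must lie in [0, 1]")
        if not self.w > 0:
            raise ValueError("gate sharpness w must be positive")
        if not self.theta_lo < self.theta_hi:
            raise ValueError("clipping bounds must satisfy theta_lo < theta_hi")
        object.__setattr__(self, "phi", float(self.phi) % 24.0)


@dataclass(frozen=True)
class LinearCoefs:
    """Linear coefficients of the summed sub-models (see module docstring)."""

    b0: float = 0.0
    b_age: float = 0.0
    b_cos: float = 0.0
    b_sin: float = 0.0
    b_e: float = 0.0
    b_e_age: float = 0.0
    b_e_cos: float = 0.0
    b_e_sin: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.b0, self.b_age, self.b_cos, self.b_sin,
             self.b_e, self.b_e_age, self.b_e_cos, self.b_e_sin]
        )

    @staticmethod
    def from_array(a) -> "LinearCoefs":
        a = np.asarray(a, dtype=float)
        return LinearCoefs(*a.tolist())

    @property
    def env_group(self) -> np.ndarray:
        return self.as_array()[_ENV_SLICE]

    @property
    def clock_phase_h(self) -> float:
        """Peak clock time implied by the cos/sin pair, in hours."""
        return (math.atan2(self.b_sin, self.b_cos) * 24.0 / (2 * math.pi)) % 24.0


@dataclass
class GeneModelFit:
    gene_id: str
    predictor: str  # temperature | radiation | neither
    nl: NonlinearParams
    coefs: LinearCoefs
    criterion: float
    n_train: int

    def __post_init__(self):
        if self.predictor not in ("temperature", "radiation", "neither"):
            raise ValueError(f"unknown predictor {self.predictor!r}")
        if self.predictor == "neither" and np.any(self.coefs.env_group != 0):
            raise ValueError("a neither-model must have all environmental coefficients zero")

    def to_dict(self) -> dict:
        return {
            "gene_id": self.gene_id,
            "predictor": self.predictor,
            "nl": asdict(self.nl),
            "coefs": asdict(self.coefs),
            "criterion": float(self.criterion),
            "n_train": int(self.n_train),
        }

    @staticmethod
    def from_dict(d: dict) -> "GeneModelFit":
        return GeneModelFit(
            d["gene_id"], d["predictor"], NonlinearParams(**d["nl"]),
            LinearCoefs(**d["coefs"]), d["criterion"], d["n_train"],
        )


# ---------------------------------------------------------------------------
# gate, environmental input, design
# ---------------------------------------------------------------------------

def gate(clock_time, nl: NonlinearParams):
    """Diel gate weight in [1 - gamma, 1], peaking at clock time ``phi``."""
    ct = np.asarray(clock_time, dtype=float)
    base = (1.0 + np.cos(2.0 * np.pi * (ct - nl.phi) / 24.0)) / 2.0
    return (1.0 - nl.gamma) + nl.gamma * base ** nl.w


def _window_bounds(nl: NonlinearParams, dt: float) -> tuple[int, int]:
    """Grid steps back from the sample for the window [t-D-T, t-D)."""
    h1 = int(math.floor((nl.D + nl.T) / dt + 1e-9))
    h0 = int(math.floor(nl.D / dt + 1e-9))
    if h1 - h0 < 1:
        raise ValueError(
            f"window length T={nl.T} h resolves to zero grid points at dt={dt} h"
        )
    return h1, h0


def _env_inputs(stack: EnvStack, pos: np.ndarray, min_pos: np.ndarray,
                nl: NonlinearParams, variable: str) -> np.ndarray:
    """Gated, clipped look-back means for samples at grid positions ``pos``."""
    series = gate(stack.clock, nl) * np.clip(
        stack.variable(variable), nl.theta_lo, nl.theta_hi
    )
    cs = np.empty(len(series) + 1)
    cs[0] = 0.0
    np.cumsum(series, out=cs[1:])
    h1, h0 = _window_bounds(nl, stack.dt)
    i_lo = pos - h1
    if np.any(i_lo < min_pos):
        raise ValueError(
            f"insufficient environmental history for window T={nl.T}, D={nl.D}"
        )
    i_hi = pos - h0
    return (cs[i_hi] - cs[i_lo]) / (h1 - h0)


def env_input(env: EnvSeries, t: float, nl: NonlinearParams, variable: str) -> float:
    """Environmental input for a single sample at time ``t`` (hours into ``env``)."""
    stack = EnvStack([env])
    k = t / stack.dt
    ki = int(round(k))
    if abs(k - ki) > 1e-6 or not 0 <= ki < stack.n_total:
        raise ValueError("sample time must sit on the environmental grid")
    x = _env_inputs(stack, np.array([ki]), np.array([0]), nl, variable)
    return float(x[0])


def sample_env_inputs(samples: SampleSet, nl: NonlinearParams, variable: str) -> np.ndarray:
    """Environmental inputs for every sample of a :class:`SampleSet`."""
    min_pos = samples.stack.offsets[samples.trace]
    return _env_inputs(samples.stack, samples.pos, min_pos, nl, variable)


def grid_env_inputs(samples: SampleSet, grid, variable: str) -> np.ndarray:
    """Stack of environmental inputs, one row per grid point (m, n_samples)."""
    return np.stack([sample_env_inputs(samples, nl, variable) for nl in grid])


def design_row(clock_time: float, age: float, x_env: float) -> np.ndarray:
    return design_matrix(np.array([clock_time]), np.array([age]), np.array([x_env]))[0]


def design_matrix(clock, age, x) -> np.ndarray:
    clock = np.asarray(clock, dtype=float)
    age = np.asarray(age, dtype=float)
    x = np.asarray(x, dtype=float)
    ang = 2.0 * np.pi * clock / 24.0
    c, s = np.cos(ang), np.sin(ang)
    return np.column_stack(
        [np.ones_like(clock), age, c, s, x, age * x, c * x, s * x]
    )


# ---------------------------------------------------------------------------
# linear stage: adaptive group LASSO with BIC selection
# ---------------------------------------------------------------------------

_REL_LAMBDAS = np.logspace(0, -4, 10)


def _standardize(X):
    """Center/scale the 7 non-intercept columns; zero-variance columns go to 0."""
    Z = X[:, 1:]
    mu = Z.mean(axis=0)
    sd = Z.std(axis=0)
    keep = sd > 1e-12
    sd_safe = np.where(keep, sd, 1.0)
    Xs = (Z - mu) / sd_safe
    Xs[:, ~keep] = 0.0
    return Xs, mu, sd_safe


def _unstandardize(beta_std, mu, sd, y_mean) -> np.ndarray:
    beta = beta_std / sd
    b0 = y_mean - float(beta @ mu)
    return np.concatenate([[b0], beta])


def _bic(n, rssn, beta_std) -> float:
    rssn = max(rssn, 1e-12)
    df = 1 + int(np.count_nonzero(beta_std))
    return n * math.log(rssn) + df * math.log(n)


def fit_linear_agl(X, y, lambda_grid=None, max_iter=400, tol=1e-7):
    """Fit the 8-column design by adaptive group LASSO, selecting lambda by BIC.

    Stage one is a lightly ridged pilot fit; stage two a group LASSO with
    group weights 1/||pilot_g|| solved by proximal gradient descent over a
    descending lambda path (``lambda_grid``; an automatic log-spaced path
    from the critical lambda when omitted).  Returns ``(LinearCoefs, BIC)``;
    BIC = n log(RSS/n) + df log n with df = number of nonzero coefficients.

    A lambda of exactly 0 is solved as ordinary least squares.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if p != len(DESIGN_COLUMNS):
        raise ValueError(f"design must have {len(DESIGN_COLUMNS)} columns")
    if n != len(y):
        raise ValueError("X and y must have matching length")
    if n < 16:
        raise ValueError("at least 16 training rows are required")
    y_mean = float(y.mean())
    yc = y - y_mean
    if yc.std() < 1e-12:
        warnings.warn("response has zero variance; returning intercept-only fit")
        return LinearCoefs(b0=y_mean), _bic(n, 1e-12, np.zeros(7))

    Xs, mu, sd = _standardize(X)
    G = (Xs.T @ Xs) / n
    c = (Xs.T @ yc) / n
    yty = float(yc @ yc) / n

    if lambda_grid is None:
        beta_std, bic, _ = _agl_best(
            G, c, yty, n, GROUP_IDS, N_GROUPS, _REL_LAMBDAS, max_iter, tol
        )
    else:
        lams = sorted((float(l) for l in lambda_grid), reverse=True)
        if not lams:
            raise ValueError("lambda_grid must be nonempty")
        gw = _pilot_weights(G, c, GROUP_IDS, N_GROUPS)
        L = _power_L(G)
        beta = np.zeros(7)
        best = None
        for lam in lams:
            if lam < 0:
                raise ValueError("lambda must be non-negative")
            if lam == 0.0:
                beta = np.linalg.lstsq(Xs, yc, rcond=None)[0]
            else:
                beta = _fista(G, c, lam, gw, GROUP_IDS, N_GROUPS, beta, L,
                              max_iter, tol)
            rssn = yty - 2.0 * float(c @ beta) + float(beta @ G @ beta)
            bic = _bic(n, rssn, beta)
            if best is None or bic < best[0]:
                best = (bic, beta.copy())
        bic, beta_std = best

    coef = _unstandardize(beta_std, mu, sd, y_mean)
    return LinearCoefs.from_array(coef), float(bic)


def _fit_from_x(yc, y_mean, yty, n, clock, age, x, max_iter=400, tol=1e-7):
    """AGL fit given precomputed environmental inputs; Gram-scale fast path."""
    X = design_matrix(clock, age, x)
    Xs, mu, sd = _standardize(X)
    G = (Xs.T @ Xs) / n
    c = (Xs.T @ yc) / n
    beta_std, bic, _ = _agl_best(
        G, c, yty, n, GROUP_IDS, N_GROUPS, _REL_LAMBDAS, max_iter, tol
    )
    coef = _unstandardize(beta_std, mu, sd, y_mean)
    return LinearCoefs.from_array(coef), float(bic)


# ---------------------------------------------------------------------------
# nonlinear stage: grid search + Nelder-Mead on transformed parameters
# ---------------------------------------------------------------------------

def default_nl_grid(theta_lo: float, theta_hi: float, *,
                    Ts=(3.0, 6.0, 12.0, 24.0), Ds=(0.0, 6.0),
                    phis=(0.0, 6.0, 12.0, 18.0), gammas=(0.0, 1.0),
                    ws=(2.0,)) -> list[NonlinearParams]:
    """Coarse initializer grid for the 7 nonlinear parameters.

    The grid seeds Nelder-Mead, which then refines all parameters
    continuously; clipping bounds start at the observed range of the
    variable (clipping inactive).
    """
    if not theta_lo < theta_hi:
        theta_lo, theta_hi = theta_lo - 0.5, theta_lo + 0.5
    grid = []
    for T, D, phi, g, w in itertools.product(Ts, Ds, phis, gammas, ws):
        if g == 0.0 and (phi != phis[0] or w != ws[0]):
            continue  # gate flat: phi and w are inert, keep one representative
        grid.append(NonlinearParams(T, D, phi, g, w, theta_lo, theta_hi))
    return grid


_GAMMA_EPS = 1e-4


def _nl_to_vector(nl: NonlinearParams) -> np.ndarray:
    g = min(max(nl.gamma, _GAMMA_EPS), 1.0 - _GAMMA_EPS)
    half = (nl.theta_hi - nl.theta_lo) / 2.0
    return np.array([
        math.log(nl.T),
        math.sqrt(nl.D),
        nl.phi,
        math.log(g / (1.0 - g)),
        math.log(nl.w),
        (nl.theta_lo + nl.theta_hi) / 2.0,
        math.log(half),
    ])


def _vector_to_nl(u, dt: float) -> NonlinearParams | None:
    T = math.exp(min(u[0], 6.0))
    D = u[1] * u[1]
    if T < dt or T + D > LOOKBACK_H:
        return None
    gamma = 1.0 / (1.0 + math.exp(-min(max(u[3], -30.0), 30.0)))
    w = math.exp(min(max(u[4], -4.0), 4.0))
    half = math.exp(min(max(u[6], -8.0), 12.0))
    return NonlinearParams(T, D, u[2] % 24.0, gamma, w, u[5] - half, u[5] + half)


def optimize_nonlinear(y, samples: SampleSet, variable: str = "temperature",
                       grid=None, grid_inputs=None, nm_maxiter: int = 80,
                       max_iter: int = 400, tol: float = 1e-7):
    """Optimize the 7 nonlinear parameters for one gene and one variable.

    Evaluates the BIC of the adaptive-group-LASSO fit at every grid point,
    then refines from the best point with Nelder-Mead on transformed
    parameters (log T, sqrt D, wrapped phi, logit gamma, log w, clipping
    midpoint and log half-width).  ``grid_inputs`` may carry precomputed
    environmental inputs, one row per grid point, to amortize repeated fits
    over subsamples of a fixed pool.

    Returns ``(NonlinearParams, LinearCoefs, criterion)``.
    """
    if variable not in VARIABLES:
        raise ValueError(f"variable must be one of {VARIABLES}")
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(samples):
        raise ValueError("y must align with samples")
    if n < 16:
        raise ValueError("at least 16 training samples are required")
    if grid is None:
        E = samples.stack.variable(variable)
        grid = default_nl_grid(float(E.min()), float(E.max()))
    grid = list(grid)
    if not grid:
        raise ValueError("empty nonlinear parameter grid")

    y_mean = float(y.mean())
    yc = y - y_mean
    if yc.std() < 1e-12:
        coefs, bic = fit_linear_agl(
            design_matrix(samples.clock, samples.age, np.zeros(n)), y
        )
        return grid[0], coefs, bic
    yty = float(yc @ yc) / n

    if grid_inputs is None:
        grid_inputs = grid_env_inputs(samples, grid, variable)
    grid_inputs = np.asarray(grid_inputs, dtype=float)
    if grid_inputs.shape != (len(grid), n):
        raise ValueError("grid_inputs must have shape (len(grid), n_samples)")

    # batched Gram construction over the grid
    ang = 2.0 * np.pi * samples.clock / 24.0
    ccol, scol = np.cos(ang), np.sin(ang)
    m = len(grid)
    D = np.empty((m, n, 8))
    D[:, :, 0] = 1.0
    D[:, :, 1] = samples.age
    D[:, :, 2] = ccol
    D[:, :, 3] = scol
    D[:, :, 4] = grid_inputs
    D[:, :, 5] = grid_inputs * samples.age
    D[:, :, 6] = grid_inputs * ccol
    D[:, :, 7] = grid_inputs * scol
    Z = D[:, :, 1:]
    mus = Z.mean(axis=1)
    sds = Z.std(axis=1)
    keep = sds > 1e-12
    sds_safe = np.where(keep, sds, 1.0)
    Xs = (Z - mus[:, None, :]) / sds_safe[:, None, :]
    Xs[~np.broadcast_to(keep[:, None, :], Xs.shape)] = 0.0
    Gs = np.einsum("mnp,mnq->mpq", Xs, Xs) / n
    cs = np.einsum("mnp,n->mp", Xs, yc) / n
    ytys = np.full(m, yty)
    betas, bics = _agl_best_batch(
        Gs, cs, ytys, n, GROUP_IDS, N_GROUPS, _REL_LAMBDAS, max_iter, tol
    )
    i0 = int(np.argmin(bics))

    state = {"bic": float(bics[i0]), "nl": grid[i0]}

    def objective(u):
        nl = _vector_to_nl(u, samples.stack.dt)
        if nl is None:
            return 1e12
        try:
            x = sample_env_inputs(samples, nl, variable)
        except ValueError:
            return 1e12
        # exploration can run the inner solver a little looser; the winning
        # point is refitted at full precision below
        _, bic = _fit_from_x(yc, y_mean, yty, n, samples.clock, samples.age, x,
                             min(max_iter, 150), max(tol, 1e-6))
        if bic < state["bic"]:
            state["bic"] = bic
            state["nl"] = nl
        return bic

    if nm_maxiter > 0:
        minimize(objective, _nl_to_vector(grid[i0]), method="Nelder-Mead",
                 options={"maxiter": nm_maxiter, "xatol": 1e-3, "fatol": 1e-4})

    nl_best = state["nl"]
    x = sample_env_inputs(samples, nl_best, variable)
    coefs, bic = _fit_from_x(yc, y_mean, yty, n, samples.clock, samples.age, x,
                             max_iter, tol)
    return nl_best, coefs, float(bic)


# ---------------------------------------------------------------------------
# prediction and per-gene predictor choice
# ---------------------------------------------------------------------------

def predict(fit: GeneModelFit, env, samples) -> np.ndarray:
    """Predicted expression for samples; ``env`` may be EnvSeries or EnvStack.

    ``samples`` is a :class:`SampleSet` (its stack must be the one the
    samples refer to, and ``env`` is then ignored in favour of it) or a list
    of ``(clock_time, age_days, time_h)`` triples resolved against ``env``.
    """
    if not isinstance(samples, SampleSet):
        stack = env if isinstance(env, EnvStack) else EnvStack([env])
        triples = np.asarray(samples, dtype=float).reshape(-1, 3)
        samples = SampleSet(
            stack,
            np.zeros(len(triples), dtype=np.int64),
            triples[:, 2], triples[:, 0], triples[:, 1],
        )
    if fit.predictor == "neither":
        x = np.zeros(len(samples))
    else:
        x = sample_env_inputs(samples, fit.nl, fit.predictor)
    X = design_matrix(samples.clock, samples.age, x)
    return X @ fit.coefs.as_array()


_TIE_TOL = 1e-8


def _zero_env_group(coefs: LinearCoefs) -> LinearCoefs:
    a = coefs.as_array()
    a[_ENV_SLICE] = 0.0
    return LinearCoefs.from_array(a)


def choose_predictor(fits: dict) -> str:
    """Deterministic per-gene choice between the two fitted variables.

    ``fits`` maps variable name to ``(nl, coefs, criterion)``.  The lower
    criterion wins; near-ties resolve to "neither" if both candidates zero
    the environmental group, else to the sparser model, else to temperature.
    A winner whose environmental group is zero is reported as "neither".
    """
    (nt, ct, bt) = fits["temperature"]
    (nr, cr, br) = fits["radiation"]
    zt = np.all(ct.env_group == 0)
    zr = np.all(cr.env_group == 0)
    if abs(bt - br) < _TIE_TOL:
        if zt and zr:
            return "neither"
        nnz_t = int(np.count_nonzero(ct.as_array()))
        nnz_r = int(np.count_nonzero(cr.as_array()))
        if nnz_t != nnz_r:
            winner = "temperature" if nnz_t < nnz_r else "radiation"
        else:
            winner = "temperature"
    else:
        winner = "temperature" if bt < br else "radiation"
    if winner == "temperature" and zt:
        return "neither"
    if winner == "radiation" and zr:
        return "neither"
    return winner


def fit_gene(gene_id: str, y, samples: SampleSet, grids=None, grid_inputs=None,
             nm_maxiter: int = 80) -> GeneModelFit:
    """Fit both candidate variables for one gene and keep the better model.

    ``grids`` / ``grid_inputs`` optionally map variable name to a parameter
    grid and its precomputed inputs (see :func:`optimize_nonlinear`).
    """
    fits = {}
    for var in VARIABLES:
        grid = None if grids is None else grids[var]
        gx = None if grid_inputs is None else grid_inputs[var]
        fits[var] = optimize_nonlinear(
            y, samples, var, grid=grid, grid_inputs=gx, nm_maxiter=nm_maxiter
        )
    predictor = choose_predictor(fits)
    if predictor == "neither":
        nl, coefs, bic = min(fits.values(), key=lambda f: f[2])
        coefs = _zero_env_group(coefs)
    else:
        nl, coefs, bic = fits[predictor]
    return GeneModelFit(gene_id, predictor, nl, coefs, float(bic), len(samples))
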