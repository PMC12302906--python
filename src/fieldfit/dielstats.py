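"""Diel summary statistics and expression screens for multi-condition studies.

Covers the descriptive layer of the analysis: which genes are expressed at
all, how large their day-night oscillation is (smoothing-spline amplitude),
which genes are private to one cultivar, which differ between cultivars
within a condition (paired t-test with Benjamini-Hochberg FDR control), and
which track air temperature (Pearson correlation screens).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import solve
from statsmodels.stats.multitest import multipletests

from .data import ExpressionStudy

EXPRESSED_MEAN_MIN = 1.0
AMPLITUDE_MIN = 2.0
CORR_THRESHOLD = 0.5
SPECIFIC_DIFF = 2.0
SPECIFIC_LOW = 0.5
DEFAULT_SPAR = 0.3
GRID_STEP_H = 1.5


def filter_expressed(study: ExpressionStudy,
                     min_mean: float = EXPRESSED_MEAN_MIN) -> list[str]:
    """Genes whose grand mean log2(rpm+1) strictly exceeds ``min_mean``."""
    means = study.matrix.mean(axis=1)
    return list(means.index[means > min_mean])


# ---------------------------------------------------------------------------
# smoothing-spline diel amplitude
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeResult:
    gene_id: str
    cultivar: str
    condition_id: str
    amplitude: float
    spline_grid: np.ndarray
    spline_values: np.ndarray
    penalty: float  # lambda actually used on the unit-scaled domain

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


def _bspline_design(u: np.ndarray):
    """Cubic B-spline design and curvature penalty over knots at unique u.

    The knot vector places boundary knots with full multiplicity and interior
    knots at every unique data point, giving n + 2 basis functions.  The
    penalty matrix integrates products of second derivatives exactly
    (two-point Gauss per knot interval; the integrand is quadratic).
    """
    uu = np.unique(u)
    t = np.concatenate([[uu[0]] * 3, uu, [uu[-1]] * 3])
    k = 3
    nb = len(t) - k - 1
    B = BSpline.design_matrix(u, t, k).toarray()
    # second-derivative basis values at Gauss points of each interval
    a, b = uu[:-1], uu[1:]
    g1 = (a + b) / 2 - (b - a) / (2 * np.sqrt(3))
    g2 = (a + b) / 2 + (b - a) / (2 * np.sqrt(3))
    wq = (b - a) / 2
    pts = np.concatenate([g1, g2])
    wts = np.concatenate([wq, wq])
    eye = np.eye(nb)
    D2 = np.empty((len(pts), nb))
    for j in range(nb):
        D2[:, j] = BSpline(t, eye[j], k).derivative(2)(pts)
    Omega = (D2 * wts[:, None]).T @ D2
    return t, k, B, Omega


def spar_to_lambda(spar: float, B: np.ndarray, Omega: np.ndarray) -> float:
    """Convert a normalized smoothing parameter to a curvature penalty.

    Uses the standard parameterization for cubic smoothing splines on the
    unit-scaled abscissa: lambda = r * 256**(3*spar - 1) with
    r = tr(B'B) / tr(Omega), so spar is comparable across data sets.
    """
    r = np.trace(B.T @ B) / np.trace(Omega)
    return float(r * 256.0 ** (3.0 * spar - 1.0))


def diel_amplitude(times, values, spar: float = DEFAULT_SPAR,
                   grid_step: float = GRID_STEP_H, gene_id: str = "",
                   cultivar: str = "", condition_id: str = "") -> AmplitudeResult:
    """Amplitude of the diel oscillation: spline max minus min on a fine grid.

    A cubic smoothing spline (penalty set by the ``spar`` parameterization)
    is fitted to expression against clock time and evaluated on a
    ``grid_step``-spaced grid over the observed span; the amplitude is the
    difference between the maximum and minimum of the fitted curve.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    order = np.argsort(times)
    times, values = times[order], values[order]
    if len(times) < 4:
        raise ValueError("need at least 4 time points for the spline fit")
    span = times[-1] - times[0]
    if span < 21.0:
        raise ValueError("time points must span at least 21 h")
    u = (times - times[0]) / span
    t, k, B, Omega = _bspline_design(u)
    lam = spar_to_lambda(spar, B, Omega)
    A = B.T @ B + lam * Omega
    A[np.diag_indices_from(A)] += 1e-10 * np.trace(A)
    beta = solve(A, B.T @ values, assume_a="pos")
    grid = np.arange(times[0], times[-1] + 1e-9, grid_step)
    ug = (grid - times[0]) / span
    fitted = BSpline(t, beta, k)(ug)
    amp = float(fitted.max() - fitted.min())
    return AmplitudeResult(gene_id, cultivar, condition_id, amp, grid, fitted, lam)


def amplitude_table(study: ExpressionStudy, genes=None, spar: float = DEFAULT_SPAR,
                    grid_step: float = GRID_STEP_H) -> pd.DataFrame:
    """Diel amplitude for every (gene, cultivar, condition) series."""
    genes = list(genes) if genes is not None else list(study.matrix.index)
    meta = study.meta
    rows = []
    for (cv, cond), grp in meta.groupby(["cultivar", "condition_id"], sort=False):
        cols = list(grp.index)
        times = grp["clock_time_h"].to_numpy()
        block = study.matrix.loc[genes, cols]
        for g in genes:
            res = diel_amplitude(times, block.loc[g].to_numpy(), spar=spar,
                                 grid_step=grid_step, gene_id=g, cultivar=cv,
                                 condition_id=cond)
            rows.append({"gene_id": g, "cultivar": cv, "condition_id": cond,
                         "amplitude": res.amplitude})
    return pd.DataFrame(rows)


def filter_oscillating(amplitudes: pd.DataFrame,
                       threshold: float = AMPLITUDE_MIN) -> list[str]:
    """Genes whose mean amplitude strictly exceeds the threshold in *both* cultivars.

    ``amplitudes`` is the long table from :func:`amplitude_table`; the
    per-cultivar mean is taken over conditions.
    """
    cultivars = sorted(amplitudes["cultivar"].unique())
    if len(cultivars) < 2:
        raise ValueError("amplitudes for both cultivars are required")
    means = amplitudes.groupby(["gene_id", "cultivar"])["amplitude"].mean().unstack()
    if means.isna().any().any():
        missing = means[means.isna().any(axis=1)].index[0]
        raise ValueError(f"gene {missing!r} lacks amplitudes for a cultivar")
    keep = (means > threshold).all(axis=1)
    return list(means.index[keep])


# ---------------------------------------------------------------------------
# cultivar-specific genes and DEGs
# ---------------------------------------------------------------------------

def cultivar_specific_genes(study: ExpressionStudy, diff: float = SPECIFIC_DIFF,
                            low: float = SPECIFIC_LOW) -> dict:
    """Genes private to one cultivar, keyed by cultivar.

    A gene is specific to cultivar X when mean(X) - mean(other) exceeds
    ``diff`` and the other cultivar's mean is below ``low`` (means over all
    samples of each cultivar).
    """
    cultivars = sorted(study.meta["cultivar"].unique())
    if len(cultivars) != 2:
        raise ValueError("exactly two cultivars are required")
    a, b = cultivars
    mean_a = study.matrix[study.meta.index[study.meta["cultivar"] == a]].mean(axis=1)
    mean_b = study.matrix[study.meta.index[study.meta["cultivar"] == b]].mean(axis=1)
    spec_a = (mean_a - mean_b > diff) & (mean_b < low)
    spec_b = (mean_b - mean_a > diff) & (mean_a < low)
    return {a: list(mean_a.index[spec_a]), b: list(mean_b.index[spec_b])}


@dataclass
class DEGResult:
    gene_id: str
    condition_id: str
    direction: str  # higher_<cultivar>
    p: float
    q: float

    def __post_init__(self):
        if not 0 <= self.p <= 1:
            raise ValueError("p-value out of range")


def deg_paired_t(study: ExpressionStudy, condition_id: str, alpha: float = 0.05,
                 exclude=None):
    """Cultivar DEGs within one condition by paired t-test + BH step-up.

    Samples of the two cultivars at the same sampling time are paired.
    Returns ``(degs, table)``: the significant results (q < alpha) and the
    full per-gene table.  Cultivar-specific genes should be passed via
    ``exclude`` so fixed subspecies differences don't swamp the comparison.
    """
    meta = study.meta[study.meta["condition_id"] == condition_id]
    cultivars = sorted(meta["cultivar"].unique())
    if len(cultivars) != 2:
        raise ValueError(f"condition {condition_id!r} must contain two cultivars")
    a, b = cultivars
    ma = meta[meta["cultivar"] == a].sort_values("sampling_time_index")
    mb = meta[meta["cultivar"] == b].sort_values("sampling_time_index")
    if len(ma) != len(mb) or len(ma) < 2:
        raise ValueError("cultivars must share >= 2 paired sampling times")
    if not np.array_equal(ma["sampling_time_index"].to_numpy(),
                          mb["sampling_time_index"].to_numpy()):
        raise ValueError("sampling times differ between cultivars; cannot pair")
    genes = [g for g in study.matrix.index if not (exclude and g in set(exclude))]
    Xa = study.matrix.loc[genes, list(ma.index)].to_numpy()
    Xb = study.matrix.loc[genes, list(mb.index)].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat, p = stats.ttest_rel(Xa, Xb, axis=1)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance differences: no evidence
    q = multipletests(p, method="fdr_bh")[1]
    mean_diff = (Xa - Xb).mean(axis=1)
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "condition_id": condition_id,
            "direction": np.where(mean_diff > 0, f"higher_{a}", f"higher_{b}"),
            "p": p,
            "q": q,
        }
    )
    degs = [
        DEGResult(r.gene_id, r.condition_id, r.direction, r.p, r.q)
        for r in table[table["q"] < alpha].itertuples()
    ]
    return degs, table


# ---------------------------------------------------------------------------
# temperature-correlation screen
# ---------------------------------------------------------------------------

def temp_correlation_screen(study: ExpressionStudy, temperatures=None,
                            threshold: float = CORR_THRESHOLD):
    """Per-gene Pearson correlation of expression with air temperature.

    Pools all samples (conditions and time points together).  Returns
    ``(positive, negative, r)``: genes with r strictly above ``threshold``,
    genes strictly below ``-threshold``, and the full r series.  Genes with
    zero expression variance have undefined r and are excluded with a warning.
    """
    if temperatures is None:
        if "nominal_temp_C" not in study.meta.columns:
            raise ValueError("no temperature annotation; pass `temperatures`")
        temps = study.meta["nominal_temp_C"].astype(float).to_numpy()
    else:
        temps = pd.Series(temperatures).loc[list(study.matrix.columns)].to_numpy()
    X = study.matrix.to_numpy()
    xc = X - X.mean(axis=1, keepdims=True)
    tc = temps - temps.mean()
    sx = np.sqrt((xc**2).sum(axis=1))
    st = np.sqrt((tc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ tc) / (sx * st)
    degenerate = sx < 1e-12
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero variance excluded from the screen"
        )
    r = pd.Series(np.where(degenerate, np.nan, r), index=study.matrix.index, name="r")
    positive = list(r.index[r > threshold])
    negative = list(r.index[r < -threshold])
    return positive, negative, r
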