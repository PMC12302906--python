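"""Training-set-composition experiment.

Per-gene models are trained on subsampled pools of growth-chamber (GC),
field, or mixed (50% GC / 50% field) data; for each subsample the better of
the temperature- and radiation-driven models is chosen by BIC, and held-out
prediction error (MAE on log2(rpm+1)) is measured on field data never seen
in training.  Tallying the choices over subsampling replicates shows whether
a pool lets the model identify a gene's true driver consistently; MAE
summaries show whether mixing GC data into field training improves field
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import SampleSet
from .fitcore import (VARIABLES, default_nl_grid, fit_gene, grid_env_inputs,
                      predict)

CHOICES = ("temperature", "radiation", "neither")
POOR_MAE_THRESHOLD = 5.0
CONSISTENCY_THRESHOLD = 0.8
DEFAULT_SIZES = (64, 128, 256, 512)


@dataclass
class TrainingPool:
    """A named pool of candidate training samples with aligned expression."""

    name: str
    samples: SampleSet
    expr: pd.DataFrame  # genes x samples, aligned to ``samples``
    source: np.ndarray  # per-sample origin label, e.g. "gc" / "field"

    def __post_init__(self):
        if self.expr.shape[1] != len(self.samples):
            raise ValueError("expression matrix must align with the sample set")
        self.source = np.asarray(self.source)

    def __len__(self) -> int:
        return len(self.samples)


def build_pool(name: str, bundles) -> TrainingPool:
    """Assemble a pool from one or more simulated study bundles."""
    samples = SampleSet.concat([b.samples for b in bundles])
    expr = pd.concat([b.expr for b in bundles], axis=1)
    source = np.concatenate(
        [np.full(len(b.samples), b.source) for b in bundles]
    )
    return TrainingPool(name, samples, expr, source)


def subsample(pool: TrainingPool, n: int, seed) -> np.ndarray:
    """Indices of a training subsample, without replacement.

    A pool with both "gc" and "field" samples is treated as mixed: ceil(n/2)
    samples come from the GC part and floor(n/2) from the field part.
    """
    rng = np.random.default_rng(seed)
    sources = np.unique(pool.source)
    if len(sources) == 1:
        if n > len(pool):
            raise ValueError(f"subsample size {n} exceeds pool size {len(pool)}")
        return np.sort(rng.choice(len(pool), size=n, replace=False))
    if set(sources) != {"gc", "field"}:
        raise ValueError("mixed pools must combine 'gc' and 'field' sources")
    n_gc = (n + 1) // 2
    n_fd = n // 2
    gc_idx = np.flatnonzero(pool.source == "gc")
    fd_idx = np.flatnonzero(pool.source == "field")
    if n_gc > len(gc_idx) or n_fd > len(fd_idx):
        raise ValueError("subsample size exceeds a source within the mixed pool")
    pick = np.concatenate(
        [rng.choice(gc_idx, size=n_gc, replace=False),
         rng.choice(fd_idx, size=n_fd, replace=False)]
    )
    return np.sort(pick)


def mae(pred, obs) -> float:
    """Mean absolute error on the log2(rpm+1) scale."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.size == 0:
        raise ValueError("pred and obs must be nonempty and equally long")
    return float(np.mean(np.abs(pred - obs)))


def classify_poor(mae_value: float, threshold: float = POOR_MAE_THRESHOLD) -> bool:
    """A prediction is poor when its MAE reaches the threshold (inclusive)."""
    if mae_value < 0:
        raise ValueError("MAE must be non-negative")
    return mae_value >= threshold


@dataclass
class SelectionSummary:
    """Per (gene, pool, size): predictor-choice tally and held-out MAEs."""

    gene_id: str
    pool: str
    n: int
    reps: int
    tally: dict
    mae: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self):
        self.tally = {c: int(self.tally.get(c, 0)) for c in CHOICES}
        if sum(self.tally.values()) != self.reps:
            raise ValueError("tally must sum to the number of replicates")
        self.mae = np.asarray(self.mae, dtype=float)
        if self.mae.size and np.any(self.mae < 0):
            raise ValueError("MAE values must be non-negative")


def consistency_class(summary: SelectionSummary,
                      threshold: float = CONSISTENCY_THRESHOLD) -> str:
    """The choice made in >= threshold of replicates, else "inconsistent"."""
    if summary.reps <= 0:
        raise ValueError("need at least one replicate")
    for choice in CHOICES:
        if summary.tally[choice] >= threshold * summary.reps:
            return choice
    return "inconsistent"


def genome_wide_impact(selected_exemplars, cluster_table: pd.DataFrame):
    """Convert an exemplar-level selection into genome-wide gene counts.

    Returns ``(count, percent)`` where count sums the cluster sizes of the
    selected exemplars and percent is 100 * count / total member genes,
    rounded to one decimal.
    """
    sizes = cluster_table.groupby("exemplar_gene_id").size()
    selected = list(selected_exemplars)
    unknown = [e for e in selected if e not in sizes.index]
    if unknown:
        raise ValueError(f"unknown exemplar(s): {unknown[:5]}")
    count = int(sizes.loc[selected].sum()) if selected else 0
    total = int(sizes.sum())
    percent = round(100.0 * count / total, 1)
    return count, percent


@dataclass
class ExperimentResult:
    summaries: list
    excluded: set
    records: pd.DataFrame  # long format: gene, pool, n, rep, choice, mae

    def summary(self, gene_id: str, pool: str, n: int) -> SelectionSummary:
        for s in self.summaries:
            if s.gene_id == gene_id and s.pool == pool and s.n == n:
                return s
        raise KeyError((gene_id, pool, n))


def run_selection_experiment(genes, pools, sizes=DEFAULT_SIZES, reps: int = 100,
                             test=None, seed: int = 0, grids=None,
                             nm_maxiter: int = 40,
                             paired: bool = False) -> ExperimentResult:
    """Run the subsampling experiment over genes x pools x sizes x replicates.

    ``test`` is ``(test_expr, test_samples)`` — held-out data disjoint from
    every pool.  Genes whose fitting fails in any replicate of any pool are
    flagged excluded (their summaries are dropped, the failures remain in
    ``records``).  With ``paired=True`` the same subsampling seed stream is
    reused across pools.
    """
    if test is None:
        raise ValueError("a held-out test set (expr, samples) is required")
    test_expr, test_samples = test
    genes = list(genes)
    rows = []
    for pi, pool in enumerate(pools):
        pool_grids, pool_grid_x = {}, {}
        for var in VARIABLES:
            E = pool.samples.stack.variable(var)
            g = grids[var] if grids is not None else default_nl_grid(
                float(E.min()), float(E.max())
            )
            pool_grids[var] = list(g)
            pool_grid_x[var] = grid_env_inputs(pool.samples, pool_grids[var], var)
        y_pool = {g: pool.expr.loc[g].to_numpy() for g in genes}
        y_test = {g: test_expr.loc[g].to_numpy() for g in genes}
        for si, n in enumerate(sizes):
            for rep in range(reps):
                key = (si, rep) if paired else (pi, si, rep)
                ss = np.random.SeedSequence(seed, spawn_key=key)
                idx = subsample(pool, n, ss)
                sub = pool.samples.subset(idx)
                gx = {var: pool_grid_x[var][:, idx] for var in VARIABLES}
                for gene in genes:
                    try:
                        fit = fit_gene(gene, y_pool[gene][idx], sub,
                                       grids=pool_grids, grid_inputs=gx,
                                       nm_maxiter=nm_maxiter)
                        pred = predict(fit, test_samples.stack, test_samples)
                        err = mae(pred, y_test[gene])
                        rows.append((gene, pool.name, n, rep, fit.predictor, err))
                    except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                        rows.append((gene, pool.name, n, rep, f"failed:{exc}", np.nan))
    records = pd.DataFrame(
        rows, columns=["gene_id", "pool", "n", "rep", "choice", "mae"]
    )
    failed = records["choice"].str.startswith("failed")
    excluded = set(records.loc[failed, "gene_id"])
    summaries = []
    ok = records[~records["gene_id"].isin(excluded)]
    for (gene, pool_name, n), grp in ok.groupby(["gene_id", "pool", "n"], sort=False):
        tally = grp["choice"].value_counts().to_dict()
        summaries.append(
            SelectionSummary(gene, pool_name, int(n), len(grp), tally,
                             grp.sort_values("rep")["mae"].to_numpy())
        )
    return ExperimentResult(summaries, excluded, records)


def selection_accuracy(result: ExperimentResult, truth_drivers: dict,
                       pool: str, n: int) -> float:
    """Fraction of (gene, replicate) choices matching the ground-truth driver."""
    hits = total = 0
    for s in result.summaries:
        if s.pool != pool or s.n != n:
            continue
        hits += s.tally[truth_drivers[s.gene_id]]
        total += s.reps
    if total == 0:
        raise ValueError(f"no summaries for pool={pool!r}, n={n}")
    return hits / total


def summarize_mae(summaries, axis: str = "per_gene_median",
                  threshold: float = POOR_MAE_THRESHOLD) -> pd.DataFrame:
    """Summary tables of held-out MAE across genes and replicates.

    * ``per_gene_median`` — median over replicates for each (gene, pool, n);
    * ``per_rep_median`` — median over genes for each (pool, n, replicate);
    * ``poor_counts`` — per replicate, the number of genes whose MAE in that
      replicate reaches the poor-prediction threshold.
    """
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries given")
    if axis == "per_gene_median":
        rows = [
            {"gene_id": s.gene_id, "pool": s.pool, "n": s.n,
             "median_mae": float(np.nanmedian(s.mae))}
            for s in summaries
        ]
        return pd.DataFrame(rows)
    long = []
    for s in summaries:
        for rep, m in enumerate(s.mae):
            long.append((s.pool, s.n, rep, s.gene_id, m))
    df = pd.DataFrame(long, columns=["pool", "n", "rep", "gene_id", "mae"])
    if axis == "per_rep_median":
        out = df.groupby(["pool", "n", "rep"])["mae"].median().reset_index()
        return out.rename(columns={"mae": "median_mae"})
    if axis == "poor_counts":
        df["poor"] = df["mae"] >= threshold
        out = df.groupby(["pool", "n", "rep"])["poor"].sum().reset_index()
        return out.rename(columns={"poor": "n_poor"})
    raise ValueError(f"unknown axis {axis!r}")
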