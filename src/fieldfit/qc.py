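"""Data-integrity procedures.

Two independent checks identify annotation errors introduced during library
processing:

* **Plate-swap detection.** Growth temperature leaves a strong signature in
  the transcriptome, so nominal temperature can be predicted from expression.
  A sparse (lasso) regression of temperature on the expression matrix is
  trained with one 96-well plate held out and used to predict that plate's
  temperatures; a plate whose nominal labels disagree with its predicted
  temperatures far more than typical flags an annotation swap.  Flagged
  plates are paired by exhaustively searching the pairing that minimizes the
  residual error once their annotations are exchanged, and a second
  prediction round verifies the correction.
* **Genotype concordance.** Cultivar-specific SNP calls from the reads are
  compared with the nominal cultivar; a sample matching neither cultivar
  (about half the called loci agreeing) is discarded, and a sample matching
  the *other* cultivar is a swap candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LassoCV

from .data import ExpressionStudy
from .synthdata import inject_plate_swap

FLAG_MEDIAN_FACTOR = 1.5
DISCARD_BAND = (0.3, 0.7)


@dataclass
class PlatePrediction:
    """Held-out temperature predictions for one plate."""

    plate_id: str
    sample_ids: list
    predicted: np.ndarray
    nominal: np.ndarray
    mae: float
    alpha: float

    def __post_init__(self):
        if self.mae < 0:
            raise ValueError("plate MAE must be non-negative")


def _temperatures(study: ExpressionStudy, temperatures) -> pd.Series:
    if temperatures is None:
        if "nominal_temp_C" not in study.meta.columns:
            raise ValueError("no temperature annotation; pass `temperatures`")
        return study.meta["nominal_temp_C"].astype(float)
    s = pd.Series(temperatures)
    missing = [c for c in study.matrix.columns if c not in s.index]
    if missing:
        raise ValueError(f"temperature missing for sample(s) {missing[:5]}")
    return s.loc[list(study.matrix.columns)].astype(float)


def loo_plate_temperature(study: ExpressionStudy, temperatures=None,
                          lambda_grid=None, cv: int = 5, n_alphas: int = 20,
                          seed: int = 0) -> list[PlatePrediction]:
    """Leave-one-plate-out lasso regression of temperature on expression.

    For each plate the model is trained on all other plates (regularization
    strength chosen by ``cv``-fold cross-validated MAE within the training
    portion) and used to predict the held-out plate's temperatures; the
    plate's MAE against its nominal labels is reported.
    """
    # canonical sample/gene order so results don't depend on column order
    order = sorted(study.matrix.columns)
    matrix = study.matrix.sort_index().loc[:, order]
    meta = study.meta.loc[order]
    temps = _temperatures(study, temperatures).loc[order].to_numpy()
    X = matrix.to_numpy().T  # samples x genes
    plates = meta["plate_id"].to_numpy()
    unique_plates = list(pd.unique(plates))
    if len(unique_plates) < 3:
        raise ValueError("need at least 3 plates for leave-one-plate-out QC")
    # scale features once; lasso convergence is much better on standardized
    # expression and the plate MAE is unaffected
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Xs = (X - mu) / sd
    out = []
    for plate in unique_plates:
        test_mask = plates == plate
        X_tr, y_tr = Xs[~test_mask], temps[~test_mask]
        if len(y_tr) == 0:
            raise ValueError(f"plate {plate!r} contains every sample")
        if np.std(y_tr) < 1e-12:
            pred = np.full(int(test_mask.sum()), y_tr[0])
            alpha = 0.0
        else:
            model = LassoCV(alphas=n_alphas if lambda_grid is None else lambda_grid,
                            cv=cv, random_state=seed, max_iter=3000, tol=1e-3,
                            eps=1e-2)
            model.fit(X_tr, y_tr)
            pred = model.predict(Xs[test_mask])
            alpha = float(model.alpha_)
        nominal = temps[test_mask]
        out.append(
            PlatePrediction(
                plate,
                list(np.asarray(order)[test_mask]),
                np.asarray(pred, dtype=float),
                np.asarray(nominal, dtype=float),
                float(np.mean(np.abs(pred - nominal))),
                alpha,
            )
        )
    return out


@dataclass
class SwapProposal:
    """Proposed plate re-annotation: pairs of plates to exchange."""

    pairs: list
    flagged: list
    unpaired: list
    threshold: float
    pre_mae: dict
    post_mae: dict = field(default_factory=dict)


def _pair_cost(pa: PlatePrediction, pb: PlatePrediction) -> float | None:
    """Total MAE if the two plates' nominal annotations are exchanged."""
    if len(pa.nominal) != len(pb.nominal):
        return None
    return float(np.mean(np.abs(pa.predicted - pb.nominal))
                 + np.mean(np.abs(pb.predicted - pa.nominal)))


def _partial_matchings(items):
    """All partial matchings of a small list: (pairs, unmatched) tuples."""
    if not items:
        yield [], []
        return
    first, rest = items[0], items[1:]
    for pairs, single in _partial_matchings(rest):
        yield pairs, [first] + single
    for i, other in enumerate(rest):
        for pairs, single in _partial_matchings(rest[:i] + rest[i + 1:]):
            yield [(first, other)] + pairs, single


def infer_swaps(predictions, flag_threshold: float | None = None) -> SwapProposal:
    """Flag outlier plates and propose the swap pairing that explains them.

    Plates with MAE >= ``flag_threshold`` (default: 1.5x the median plate
    MAE — deliberately liberal, since a swap also corrupts the training
    labels and lifts every plate's error) are flagged.  Among flagged plates
    an exhaustive search over *partial* pairings picks the assignment
    minimizing total MAE, where a pair contributes its post-exchange MAE and
    an unpaired plate its current MAE: a pair is therefore only ever
    proposed when exchanging the two plates' nominal annotations genuinely
    lowers the error, so liberally flagged innocent plates are left
    unpaired rather than spuriously swapped.
    """
    predictions = list(predictions)
    maes = {p.plate_id: p.mae for p in predictions}
    if flag_threshold is None:
        flag_threshold = FLAG_MEDIAN_FACTOR * float(np.median(list(maes.values())))
    flagged = [p for p in predictions if p.mae >= flag_threshold]
    flagged_ids = [p.plate_id for p in flagged]
    if len(flagged) < 2:
        return SwapProposal([], flagged_ids, flagged_ids, flag_threshold, maes)

    best = None
    for matching, single in _partial_matchings(flagged):
        total = sum(p.mae for p in single)
        ok = True
        for a, b in matching:
            c = _pair_cost(a, b)
            if c is None:
                ok = False
                break
            total += c
        if ok and (best is None or total < best[0]):
            best = (total, matching, single)
    _, matching, single = best
    pairs = [(a.plate_id, b.plate_id) for a, b in matching]
    post = {f"{a.plate_id}<->{b.plate_id}": _pair_cost(a, b) for a, b in matching}
    unpaired = [p.plate_id for p in single]
    return SwapProposal(pairs, flagged_ids, unpaired, flag_threshold, maes, post)


def apply_proposal(study: ExpressionStudy, proposal: SwapProposal) -> ExpressionStudy:
    """Re-annotate a copy of the study according to the proposed pairing."""
    out = study
    for a, b in proposal.pairs:
        out = inject_plate_swap(out, a, b)
    return out


def verify_correction(study: ExpressionStudy, proposal: SwapProposal,
                      temperatures=None, lambda_grid=None, cv: int = 5,
                      seed: int = 0):
    """Second-round check: re-annotate, re-run the plate predictions.

    Returns ``(predictions, accepted)``; the correction is accepted iff the
    second round no longer implies a systematic plate interchange, i.e.
    running swap inference on the re-annotated study proposes no pairs.
    """
    corrected = apply_proposal(study, proposal)
    preds = loo_plate_temperature(corrected, temperatures=temperatures,
                                  lambda_grid=lambda_grid, cv=cv, seed=seed)
    second = infer_swaps(preds)
    return preds, second.pairs == []


# ---------------------------------------------------------------------------
# genotype concordance
# ---------------------------------------------------------------------------

@dataclass
class GenotypeReport:
    sample_id: str
    n_called: int
    prop_match_nominal: float
    verdict: str  # pass | swap_candidate | discard
    reason: str = ""


def genotype_concordance(calls: pd.DataFrame, nominal_cultivars,
                         discard_band=DISCARD_BAND) -> list[GenotypeReport]:
    """Per-sample concordance of SNP calls with the nominal cultivar.

    ``calls`` is tidy (sample_id, locus_id, call) with calls in
    {"A", "B", "unknown", "none"}.  The match proportion is computed over
    loci with a called allele only.  Verdicts: pass when the proportion is at
    or above the band, swap_candidate at or below it (the labels likely
    exchanged between cultivars), discard inside the band (matching neither
    cultivar, e.g. a mixed/contaminated sample) or when no locus was called.
    """
    bad = set(calls["call"]) - {"A", "B", "unknown", "none"}
    if bad:
        raise ValueError(f"unknown call categories: {sorted(bad)}")
    lo, hi = discard_band
    nominal = pd.Series(nominal_cultivars)
    reports = []
    for sid, grp in calls.groupby("sample_id", sort=False):
        if sid not in nominal.index:
            raise ValueError(f"no nominal cultivar for sample {sid!r}")
        called = grp[grp["call"].isin(["A", "B"])]
        n_called = len(called)
        if n_called == 0:
            reports.append(GenotypeReport(sid, 0, float("nan"), "discard",
                                          "no called loci"))
            continue
        prop = float((called["call"] == nominal[sid]).mean())
        if prop >= hi:
            verdict, reason = "pass", ""
        elif prop <= lo:
            verdict, reason = "swap_candidate", "matches the other cultivar"
        else:
            verdict, reason = "discard", "matches neither cultivar"
        reports.append(GenotypeReport(sid, n_called, prop, verdict, reason))
    return reports
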