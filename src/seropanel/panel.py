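"""Consensus predictor-panel selection.

Samples are rotated through k folds (default 10). Within each fold the
training portion is re-screened for differential markers, a bidirectional
stepwise logistic regression (scored by AIC by default) picks the most
discriminative subset, and the consensus panel is the set of markers
selected in every fold. A consensus logistic model over that panel
provides the reported coefficients.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold, StratifiedKFold

from ._utils import Standardizer, spawn_seed
from .errors import ValidationError
from .screening import COMPARISONS, _group_matrix, _screen_stats, test_phase_filter, test_phase_hits
from .signals import SignalMatrix

logger = logging.getLogger(__name__)

#: Ridge strength used purely to bound coefficients under perfect
#: separation; lambda = RIDGE_SCALE * n.
RIDGE_SCALE = 1e-8


@dataclass
class FoldPlan:
    """Assignment of every sample to exactly one of ``n_folds`` folds."""

    n_folds: int
    assignments: pd.Series  # sample_id -> fold index
    stratified: bool
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return list(self.assignments.index[self.assignments == fold])

    def training_ids(self, fold: int) -> list[str]:
        return list(self.assignments.index[self.assignments != fold])

    def sizes(self) -> list[int]:
        return [int((self.assignments == k).sum()) for k in range(self.n_folds)]


@dataclass
class PanelSelection:
    """Per-fold marker sets and their consensus."""

    per_fold_sets: list[set]
    consensus_panel: list[str]
    fold_frequency: dict[str, int]
    coefficients: pd.Series | None = None
    standardizer: Standardizer | None = None
    candidate_sets: list[set] = field(default_factory=list)


def make_folds(
    metadata: pd.DataFrame,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
    by: str = "group",
) -> FoldPlan:
    """Random near-equal folds (sizes differ by <= 1), optionally stratified.

    Stratification keeps each fold's class proportions within one sample
    of the cohort proportions; deterministic under ``seed``.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    if len(metadata) < n_folds:
        raise ValidationError("need at least n_folds samples")
    ids = metadata["sample_id"].to_numpy()
    rs = spawn_seed(seed, 11)
    if stratified:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        splits = splitter.split(ids, metadata[by].to_numpy())
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=rs)
        splits = splitter.split(ids)
    assignments = pd.Series(
        np.full(len(ids), -1, dtype=int), index=pd.Index(ids, name="sample_id")
    )
    for fold, (_, test_idx) in enumerate(splits):
        assignments.iloc[test_idx] = fold
    return FoldPlan(n_folds=n_folds, assignments=assignments, stratified=stratified, seed=seed)


def fold_differential(
    matrix: SignalMatrix,
    metadata: pd.DataFrame,
    training_ids,
    mode: str = "pooled",
    alpha: float = 0.05,
    fc_min: float = 1.2,
    sens_min: float = 0.15,
    min_spec: float = 0.90,
) -> list[str]:
    """Differential markers on the training portion of one fold.

    ``pooled`` compares HCC against healthy + cirrhotic pooled controls
    with the test-phase criteria; ``two_way`` runs the full two-comparison
    test-phase filter and returns the union of hits (equal to
    :func:`test_phase_filter` output when the training set is the full
    data); ``ttest`` keeps only the p < alpha criterion on pooled controls.
    """
    training_ids = list(training_ids)
    sub_matrix = matrix.subset(training_ids)
    sub_meta = metadata[metadata["sample_id"].isin(training_ids)]
    if "HCC" not in set(sub_meta["group"]):
        raise ValidationError("training set lacks HCC samples")
    if mode == "two_way":
        table = test_phase_filter(
            sub_matrix, sub_meta, alpha=alpha, fc_min=fc_min, sens_min=sens_min, min_spec=min_spec
        )
        return test_phase_hits(table)
    case = _group_matrix(sub_matrix, sub_meta, "HCC")
    control = _group_matrix(sub_matrix, sub_meta, ("healthy", "cirrhotic"))
    stats_table = _screen_stats(case, control, sub_matrix.protein_ids, min_spec=min_spec)
    if mode == "pooled":
        passing = (
            (stats_table["p_value"] < alpha)
            & (stats_table["fold_change"] >= fc_min)
            & (stats_table["sens_at_spec"] > sens_min)
        )
    elif mode == "ttest":
        passing = stats_table["p_value"] < alpha
    else:
        raise ValidationError(f"unknown fold_differential mode {mode!r}")
    return sorted(stats_table.loc[passing, "protein_id"])


def _fit_logit(X: np.ndarray, y: np.ndarray):
    """Ridge-stabilized logistic fit; returns (log-likelihood, model|None)."""
    n = y.shape[0]
    if X.shape[1] == 0:
        p = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        ll = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return ll, None
    clf = LogisticRegression(
        C=1.0 / (RIDGE_SCALE * n), solver="lbfgs", max_iter=5000, tol=1e-10
    )
    clf.fit(X, y)
    prob = np.clip(clf.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
    ll = float(np.sum(y * np.log(prob) + (1 - y) * np.log(1 - prob)))
    return ll, clf


def _ic(ll: float, k_params: int, n: int, criterion: str) -> float:
    if criterion == "aic":
        return 2.0 * k_params - 2.0 * ll
    if criterion == "bic":
        return np.log(n) * k_params - 2.0 * ll
    raise ValidationError(f"unknown criterion {criterion!r}")


@dataclass
class StepwiseFit:
    """Result of a stepwise logistic search."""

    selected: list[str]
    coefficients: pd.Series  # on the standardized scale, incl. intercept
    score: float
    criterion: str
    standardizer: Standardizer


def stepwise_logistic(
    values: pd.DataFrame,
    labels,
    criterion: str = "aic",
    direction: str = "both",
    max_steps: int = 200,
) -> StepwiseFit:
    """Bidirectional stepwise variable selection on a logistic model.

    Starts from the intercept-only model; at each step the single
    addition or removal giving the best criterion improvement is taken
    (ties broken by ascending protein_id, additions before removals).
    Candidate columns are standardized with training-set mean/SD before
    fitting, and the search is deterministic given the input.
    """
    y = np.asarray(labels, dtype=float)
    if values.shape[0] != y.shape[0]:
        raise ValidationError("values and labels length mismatch")
    if len(np.unique(y)) < 2:
        raise ValidationError("both classes must be present")
    cols = sorted(values.columns)
    std = Standardizer.fit(values[cols])
    Z = std.transform(values[cols]).to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(cols)}
    n = y.shape[0]

    selected: list[str] = []
    ll0, _ = _fit_logit(Z[:, []], y)
    current = _ic(ll0, 1, n, criterion)
    for _ in range(max_steps):
        best_move = None
        best_score = current - 1e-9
        for col in cols:  # additions, ascending id
            if col in selected:
                continue
            trial = selected + [col]
            ll, _ = _fit_logit(Z[:, [col_idx[c] for c in trial]], y)
            score = _ic(ll, len(trial) + 1, n, criterion)
            if score < best_score:
                best_score, best_move = score, ("add", col)
        if direction == "both":
            for col in sorted(selected):  # removals, ascending id
                trial = [c for c in selected if c != col]
                ll, _ = _fit_logit(Z[:, [col_idx[c] for c in trial]], y)
                score = _ic(ll, len(trial) + 1, n, criterion)
                if score < best_score:
                    best_score, best_move = score, ("drop", col)
        elif direction != "forward":
            raise ValidationError(f"unknown direction {direction!r}")
        if best_move is None:
            break
        kind, col = best_move
        if kind == "add":
            selected.append(col)
        else:
            selected.remove(col)
        current = best_score

    sel_sorted = sorted(selected)
    ll, model = _fit_logit(Z[:, [col_idx[c] for c in sel_sorted]], y)
    if model is None:
        coefs = pd.Series({"intercept": float(np.log(y.mean() / (1 - y.mean())))})
    else:
        coefs = pd.Series(model.coef_[0], index=sel_sorted)
        coefs["intercept"] = float(model.intercept_[0])
    sub_std = Standardizer(mean=std.mean[sel_sorted], sd=std.sd[sel_sorted])
    return StepwiseFit(
        selected=sel_sorted,
        coefficients=coefs,
        score=_ic(ll, len(sel_sorted) + 1, n, criterion),
        criterion=criterion,
        standardizer=sub_std,
    )


def consensus_select(per_fold_sets: list, require_folds: int | None = None) -> PanelSelection:
    """Markers selected in at least ``require_folds`` folds (default: all).

    With the default, the consensus is the intersection of the per-fold
    selected sets; ``fold_frequency`` is reported for every marker seen in
    any fold.
    """
    if len(per_fold_sets) == 0:
        raise ValidationError("need at least one fold set")
    sets = [set(s) for s in per_fold_sets]
    if require_folds is None:
        require_folds = len(sets)
    if not 1 <= require_folds <= len(sets):
        raise ValidationError("require_folds must be in [1, n_folds]")
    freq = Counter()
    for s in sets:
        freq.update(s)
    consensus = sorted(m for m, c in freq.items() if c >= require_folds)
    return PanelSelection(
        per_fold_sets=sets, consensus_panel=consensus, fold_frequency=dict(freq)
    )


def select_panel(
    matrix: SignalMatrix,
    metadata: pd.DataFrame,
    n_folds: int = 10,
    stratified: bool = True,
    seed: int = 0,
    mode: str = "pooled",
    criterion: str = "aic",
    require_folds: int | None = None,
    **filter_kwargs,
) -> PanelSelection:
    """Full fold-rotation panel selection over a normalized signal matrix.

    Per fold: re-screen the training portion (``mode`` as in
    :func:`fold_differential`), run stepwise logistic regression
    (HCC vs pooled controls) on the candidates, and intersect the per-fold
    selections. The consensus coefficients come from a ridge-stabilized
    logistic fit of the consensus panel on the full cohort.
    """
    meta = metadata[metadata["sample_id"].isin(matrix.sample_ids)]
    plan = make_folds(meta, n_folds=n_folds, stratified=stratified, seed=seed)
    y_all = (meta.set_index("sample_id").loc[matrix.values.index, "group"] == "HCC").to_numpy(float)

    per_fold_sets, candidate_sets = [], []
    for fold in range(n_folds):
        train_ids = plan.training_ids(fold)
        candidates = fold_differential(matrix, meta, train_ids, mode=mode, **filter_kwargs)
        candidate_sets.append(set(candidates))
        if not candidates:
            per_fold_sets.append(set())
            logger.info("fold %d: no differential candidates", fold)
            continue
        train_values = matrix.values.loc[train_ids, candidates]
        labels = (
            meta.set_index("sample_id").loc[train_ids, "group"] == "HCC"
        ).to_numpy(float)
        fit = stepwise_logistic(train_values, labels, criterion=criterion)
        per_fold_sets.append(set(fit.selected))
        logger.info("fold %d: %d candidates -> %d selected", fold, len(candidates), len(fit.selected))

    selection = consensus_select(per_fold_sets, require_folds=require_folds)
    selection.candidate_sets = candidate_sets
    if selection.consensus_panel:
        std = Standardizer.fit(matrix.values[selection.consensus_panel])
        Z = std.transform(matrix.values[selection.consensus_panel]).to_numpy(float)
        _, model = _fit_logit(Z, y_all)
        coefs = pd.Series(model.coef_[0], index=selection.consensus_panel)
        coefs["intercept"] = float(model.intercept_[0])
        selection.coefficients = coefs
        selection.standardizer = std
    return selection


def panel_report(selection: PanelSelection, path) -> None:
    """TSV report: protein, fold frequency, consensus flag, coefficient."""
    rows = []
    for pid in sorted(selection.fold_frequency):
        coef = np.nan
        if selection.coefficients is not None and pid in selection.coefficients.index:
            coef = float(selection.coefficients[pid])
        rows.append(
            {
                "protein_id": pid,
                "fold_frequency": selection.fold_frequency[pid],
                "consensus": pid in selection.consensus_panel,
                "coefficient": coef,
            }
        )
    pd.DataFrame(rows, columns=["protein_id", "fold_frequency", "consensus", "coefficient"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )
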