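"""ROC/AUC machinery, AFP rules, AFP+ANN combination, stratified reports.

AUC follows the Mann-Whitney pair-counting definition (ties count 1/2);
the serum AFP detector calls positive strictly above the 400 ng/mL
diagnostic cutoff, and the AFP-negative subgroup is AFP < 20 ng/mL.
Performance tables report, per case stratum x detector x control
comparison, the AUC and the sensitivity/specificity at each detector's
operating point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from ._utils import Standardizer
from .errors import ValidationError

AFP_DIAGNOSTIC_CUTOFF = 400.0
AFP_NEGATIVE_CUTOFF = 20.0


@dataclass(frozen=True)
class RocResult:
    """AUC and an operating point for one comparison."""

    auc: float
    operating_threshold: float
    sensitivity: float
    specificity: float
    comparison: str
    n_case: int
    n_control: int


def roc_auc(scores_case, scores_control) -> float:
    """Mann-Whitney AUC: P(case > control) + 0.5 P(tie)."""
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    u = stats.mannwhitneyu(case, control, alternative="two-sided").statistic
    return float(u / (case.size * control.size))


def sens_spec_at(scores_case, scores_control, threshold: float) -> tuple[float, float]:
    """Sensitivity/specificity with positive = strictly above threshold."""
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    return float((case > threshold).mean()), float((control <= threshold).mean())


def afp_rule(afp_ng_ml, cutoff: float = AFP_DIAGNOSTIC_CUTOFF):
    """AFP call: positive iff strictly above the diagnostic cutoff."""
    afp = np.asarray(afp_ng_ml, dtype=float)
    if (afp < 0).any():
        raise ValidationError("AFP must be non-negative")
    calls = np.where(afp > cutoff, "positive", "negative")
    return calls if afp.ndim else str(calls)


def afp_negative_flag(afp_ng_ml, cutoff: float = AFP_NEGATIVE_CUTOFF):
    """AFP-negative subgroup flag: strictly below 20 ng/mL."""
    afp = np.asarray(afp_ng_ml, dtype=float)
    if (afp < 0).any():
        raise ValidationError("AFP must be non-negative")
    flags = afp < cutoff
    return flags if afp.ndim else bool(flags)


class AfpAnnCombiner:
    """Logistic combination of AFP and the committee vote.

    Fitted on training-phase data over (log1p(AFP), vote), both
    standardized; the combined score is the fitted HCC probability and the
    fitted parameters are applied frozen to any later phase. An OR-rule
    alternative (positive iff either detector is positive) is available
    via :meth:`or_rule`.
    """

    def __init__(self):
        self._clf: LogisticRegression | None = None
        self._std: Standardizer | None = None

    @staticmethod
    def _features(afp_values, votes) -> pd.DataFrame:
        afp = np.asarray(afp_values, dtype=float)
        if (afp < 0).any():
            raise ValidationError("AFP must be non-negative")
        return pd.DataFrame({"log1p_afp": np.log1p(afp), "vote": np.asarray(votes, dtype=float)})

    def fit(self, afp_values, votes, labels) -> "AfpAnnCombiner":
        y = np.asarray(labels, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValidationError("combiner needs both classes in the training labels")
        feats = self._features(afp_values, votes)
        self._std = Standardizer.fit(feats)
        self._clf = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
        self._clf.fit(self._std.transform(feats).to_numpy(), y)
        return self

    @property
    def coefficients(self) -> pd.Series:
        if self._clf is None:
            raise ValidationError("combiner is not fitted")
        out = pd.Series(self._clf.coef_[0], index=["log1p_afp", "vote"])
        out["intercept"] = float(self._clf.intercept_[0])
        return out

    def score(self, afp_values, votes) -> np.ndarray:
        if self._clf is None:
            raise ValidationError("combiner is not fitted")
        feats = self._features(afp_values, votes)
        return self._clf.predict_proba(self._std.transform(feats).to_numpy())[:, 1]

    @staticmethod
    def or_rule(afp_values, votes, afp_cutoff: float = AFP_DIAGNOSTIC_CUTOFF,
                vote_threshold: float = 0.5) -> np.ndarray:
        """Binary OR combination: positive iff either detector is positive."""
        afp_pos = np.asarray(afp_values, dtype=float) > afp_cutoff
        vote_pos = np.asarray(votes, dtype=float) > vote_threshold
        return (afp_pos | vote_pos).astype(float)


def combine_afp_ann(afp_values, votes, labels_train) -> tuple[np.ndarray, "AfpAnnCombiner"]:
    """Fit the logistic combiner and return (combined scores, combiner)."""
    combiner = AfpAnnCombiner().fit(afp_values, votes, labels_train)
    return combiner.score(afp_values, votes), combiner


#: Default case strata mirroring the headline performance tables.
DEFAULT_STRATA: tuple[str, ...] = (
    "all", "AFP-", "HBsAg+", "HBsAg-", "BCLC 0/A", "BCLC B", "BCLC C",
)

_COMPARISON_CONTROLS = {
    "HCC_vs_healthy+cirrhotic": ("healthy", "cirrhotic"),
    "HCC_vs_healthy": ("healthy",),
    "HCC_vs_cirrhotic": ("cirrhotic",),
}


def _stratum_mask(meta: pd.DataFrame, stratum: str) -> pd.Series:
    hcc = meta["group"] == "HCC"
    if stratum == "all":
        return hcc
    if stratum == "AFP-":
        return hcc & afp_negative_flag(meta["afp_ng_ml"].to_numpy())
    if stratum == "HBsAg+":
        return hcc & (meta["hbsag"] == "pos")
    if stratum == "HBsAg-":
        return hcc & (meta["hbsag"] == "neg")
    if stratum == "BCLC 0/A":
        return hcc & meta["bclc_stage"].isin(["0", "A"])
    if stratum == "BCLC B":
        return hcc & (meta["bclc_stage"] == "B")
    if stratum == "BCLC C":
        return hcc & (meta["bclc_stage"] == "C")
    raise ValidationError(f"unknown stratum {stratum!r}")


def stratified_report(
    metadata: pd.DataFrame,
    votes: pd.Series,
    combined_scores: pd.Series | None = None,
    strata=DEFAULT_STRATA,
    vote_threshold: float = 0.5,
    combined_threshold: float = 0.5,
    afp_cutoff: float = AFP_DIAGNOSTIC_CUTOFF,
) -> pd.DataFrame:
    """Performance table over case strata x detectors x control comparisons.

    Detectors: AFP (score = AFP ng/mL, operating point the diagnostic
    cutoff), ANN (committee vote at ``vote_threshold``), and, when
    ``combined_scores`` is given, AFP+ANN (combiner probability at
    ``combined_threshold``). Controls are never stratified; an empty case
    stratum yields a row with counts and NA metrics.
    """
    meta = metadata.set_index("sample_id")
    meta = meta.loc[votes.index]
    detectors = {"AFP": (meta["afp_ng_ml"].astype(float), afp_cutoff),
                 "ANN": (votes.astype(float), vote_threshold)}
    if combined_scores is not None:
        detectors["AFP+ANN"] = (combined_scores.reindex(votes.index).astype(float), combined_threshold)

    rows = []
    for stratum in strata:
        case_mask = _stratum_mask(meta, stratum)
        for comparison, control_groups in _COMPARISON_CONTROLS.items():
            control_mask = meta["group"].isin(control_groups)
            for name, (scores, threshold) in detectors.items():
                n_case = int(case_mask.sum())
                n_control = int(control_mask.sum())
                if n_case == 0 or n_control == 0:
                    auc = sens = spec = np.nan
                else:
                    s_case = scores[case_mask.to_numpy()]
                    s_ctrl = scores[control_mask.to_numpy()]
                    auc = roc_auc(s_case, s_ctrl)
                    sens, spec = sens_spec_at(s_case, s_ctrl, threshold)
                rows.append(
                    {
                        "stratum": stratum,
                        "comparison": comparison,
                        "detector": name,
                        "auc": auc,
                        "specificity": spec,
                        "sensitivity": sens,
                        "operating_threshold": threshold,
                        "n_case": n_case,
                        "n_control": n_control,
                    }
                )
    return pd.DataFrame(rows)


def roc_curve_points(scores_case, scores_control) -> pd.DataFrame:
    """Empirical ROC coordinates (threshold, sensitivity, specificity)."""
    case = np.asarray(scores_case, dtype=float)
    control = np.asarray(scores_control, dtype=float)
    thresholds = np.unique(np.concatenate([case, control]))
    rows = [
        {"threshold": float(t), "sensitivity": float((case > t).mean()),
         "specificity": float((control <= t).mean())}
        for t in thresholds
    ]
    return pd.DataFrame(rows)
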