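"""Marker screening filters for case-control seromics.

Two filters are implemented:

* the discovery filter (proteome-wide array, HCC vs healthy): a protein is
  a candidate iff Welch t-test p <= alpha, fold change >= fc_min, and
  positive ratio >= ratio_min, where the positive ratio is the fraction of
  cases exceeding the healthy mean + 2 SD seropositivity cutoff;
* the test-phase filter (focused array): p < alpha, fold change >= fc_min,
  and sensitivity > sens_min at >= 90% specificity, run separately for
  HCC vs healthy and HCC vs cirrhotic, with each hit labelled by the
  comparison(s) it passes.

Note the deliberate asymmetry in the p-value inequality (<= at discovery,
strict < at the test phase): both forms are kept exactly as stated. No
multiple-testing correction is applied by either filter; a
Benjamini-Hochberg q-value column is reported for information only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import LITERATURE_AUTOANTIGENS
from .errors import ValidationError
from .signals import SignalMatrix

COMPARISONS = ("HCC_vs_healthy", "HCC_vs_cirrhotic")


@dataclass(frozen=True)
class MarkerScreenResult:
    """Per-protein screening statistics for one case/control comparison."""

    protein_id: str
    comparison: str
    p_value: float
    fold_change: float
    positive_ratio: float
    sens_at_spec: float
    threshold_used: float
    passes_discovery: bool
    passes_test: bool


def positive_ratio(case_values, control_values, sd_multiplier: float = 2.0):
    """Fraction of cases strictly above control mean + ``sd_multiplier`` x SD.

    Returns ``(ratio, threshold)``. Requires >= 2 controls so the sample SD
    is defined; zero control variance is degenerate (threshold collapses to
    the control mean) and is still computed, with a warning.
    """
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if control.size < 2:
        raise ValidationError("positive_ratio needs >= 2 control values")
    if case.size < 1:
        raise ValidationError("positive_ratio needs >= 1 case value")
    sd = control.std(ddof=1)
    if sd == 0.0:
        warnings.warn("zero control variance: seropositivity threshold equals the control mean")
    threshold = control.mean() + sd_multiplier * sd
    ratio = float((case > threshold).mean())
    return ratio, float(threshold)


def sensitivity_at_specificity(case_values, control_values, min_spec: float = 0.90):
    """Sensitivity at the smallest threshold reaching ``min_spec`` specificity.

    Candidate thresholds are the observed values; a sample is called
    positive iff strictly above the threshold, so specificity is the
    fraction of controls <= threshold. Returns ``(sensitivity, threshold)``.
    """
    if not 0.0 < min_spec <= 1.0:
        raise ValidationError("min_spec must be in (0, 1]")
    case = np.asarray(case_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if case.size == 0 or control.size == 0:
        raise ValidationError("both groups must be non-empty")
    candidates = np.unique(np.concatenate([case, control]))
    # specificity is non-decreasing in the threshold: scan upward.
    for t in candidates:
        spec = (control <= t).mean()
        if spec >= min_spec:
            return float((case > t).mean()), float(t)
    # unreachable: the largest observed value always gives specificity 1
    raise AssertionError("no threshold reached the requested specificity")


def _group_matrix(matrix: SignalMatrix, metadata: pd.DataFrame, group) -> np.ndarray:
    groups = (group,) if isinstance(group, str) else tuple(group)
    ids = metadata.loc[metadata["group"].isin(groups), "sample_id"]
    ids = [s for s in ids if s in matrix.values.index]
    if len(ids) == 0:
        raise ValidationError(f"no samples for group(s) {groups} in the signal matrix")
    return matrix.values.loc[ids].to_numpy(dtype=float)


def _screen_stats(
    case: np.ndarray, control: np.ndarray, protein_ids, min_spec: float = 0.90
) -> pd.DataFrame:
    """Vectorized per-protein Welch p, FC, positive ratio, sens@spec."""
    with np.errstate(invalid="ignore"):
        p = stats.ttest_ind(case, control, axis=0, equal_var=False).pvalue
    p = np.nan_to_num(p, nan=1.0)  # zero-variance-both-groups proteins
    case_mean = case.mean(axis=0)
    ctrl_mean = control.mean(axis=0)
    fc = case_mean / ctrl_mean
    thr = ctrl_mean + 2.0 * control.std(axis=0, ddof=1)
    ratio = (case > thr).mean(axis=0)
    sens = np.empty(case.shape[1])
    sens_thr = np.empty(case.shape[1])
    for j in range(case.shape[1]):
        sens[j], sens_thr[j] = sensitivity_at_specificity(case[:, j], control[:, j], min_spec)
    q = stats.false_discovery_control(np.clip(p, 0.0, 1.0))
    return pd.DataFrame(
        {
            "protein_id": list(protein_ids),
            "p_value": p,
            "q_value": q,
            "fold_change": fc,
            "positive_ratio": ratio,
            "threshold_used": thr,
            "sens_at_spec": sens,
            "sens_threshold": sens_thr,
        }
    )


def discovery_filter(
    matrix: SignalMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    fc_min: float = 1.2,
    ratio_min: float = 0.10,
) -> pd.DataFrame:
    """Discovery-phase candidate filter (HCC vs healthy).

    A protein passes iff p <= alpha AND fold change >= fc_min AND positive
    ratio >= ratio_min. All statistics are reported for every protein
    regardless of pass status.
    """
    if not matrix.normalized:
        raise ValidationError("discovery_filter expects a normalized matrix")
    case = _group_matrix(matrix, metadata, "HCC")
    control = _group_matrix(matrix, metadata, "healthy")
    if case.shape[0] < 2 or control.shape[0] < 2:
        raise ValidationError("both groups need n >= 2")
    out = _screen_stats(case, control, matrix.protein_ids)
    out["comparison"] = "HCC_vs_healthy"
    out["passes_discovery"] = (
        (out["p_value"] <= alpha)
        & (out["fold_change"] >= fc_min)
        & (out["positive_ratio"] >= ratio_min)
    )
    return out


def test_phase_filter(
    matrix: SignalMatrix,
    metadata: pd.DataFrame,
    alpha: float = 0.05,
    fc_min: float = 1.2,
    sens_min: float = 0.15,
    min_spec: float = 0.90,
) -> pd.DataFrame:
    """Test-phase filter, run per comparison (vs healthy and vs cirrhotic).

    A protein passes a comparison iff p < alpha (strict) AND fold change
    >= fc_min AND sensitivity > sens_min (strict) at >= min_spec
    specificity. The returned long table carries a ``hit_class`` column
    labelling each protein as healthy-only / cirrhotic-only / both / none.
    """
    if not matrix.normalized:
        raise ValidationError("test_phase_filter expects a normalized matrix")
    case = _group_matrix(matrix, metadata, "HCC")
    frames = []
    for comparison, control_group in zip(COMPARISONS, ("healthy", "cirrhotic")):
        control = _group_matrix(matrix, metadata, control_group)
        if case.shape[0] < 2 or control.shape[0] < 2:
            raise ValidationError("both groups need n >= 2")
        out = _screen_stats(case, control, matrix.protein_ids, min_spec=min_spec)
        out["comparison"] = comparison
        out["passes_test"] = (
            (out["p_value"] < alpha)
            & (out["fold_change"] >= fc_min)
            & (out["sens_at_spec"] > sens_min)
        )
        frames.append(out)
    table = pd.concat(frames, ignore_index=True)
    passes = table.pivot(index="protein_id", columns="comparison", values="passes_test")
    label = pd.Series("none", index=passes.index, name="hit_class")
    label[passes["HCC_vs_healthy"] & ~passes["HCC_vs_cirrhotic"]] = "healthy-only"
    label[~passes["HCC_vs_healthy"] & passes["HCC_vs_cirrhotic"]] = "cirrhotic-only"
    label[passes["HCC_vs_healthy"] & passes["HCC_vs_cirrhotic"]] = "both"
    table = table.merge(label.reset_index(), on="protein_id", how="left")
    return table


def test_phase_hits(table: pd.DataFrame) -> list[str]:
    """Proteins passing the test-phase filter in at least one comparison."""
    hits = table.loc[table["hit_class"] != "none", "protein_id"].unique()
    return sorted(hits)


def assemble_focused_panel(screened_ids, literature=LITERATURE_AUTOANTIGENS) -> list[str]:
    """Content of a focused array: screened candidates plus literature markers.

    Preserves order (screened first) and de-duplicates.
    """
    seen: dict[str, None] = {}
    for pid in list(screened_ids) + list(literature):
        seen.setdefault(pid, None)
    return list(seen)


def screening_report(table: pd.DataFrame, path) -> None:
    """Write a screening table (one row per protein x comparison) as TSV."""
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")
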