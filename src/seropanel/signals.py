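"""Array signal quantification: per-protein SNR, normalization, reproducibility.

The quantitative readout of each spot is the signal-to-noise ratio (SNR),
the ratio of the median foreground to the median background intensity.
Duplicate spots of a protein are combined by the arithmetic mean of their
spot SNRs, one samples x proteins matrix per detection channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


@dataclass
class SignalMatrix:
    """Samples x proteins SNR matrix for one detection channel.

    ``values`` is a DataFrame indexed by sample_id with protein_id columns;
    ``normalized`` records whether cross-array normalization has been
    applied, and ``provenance`` carries the method and any upstream notes.
    """

    values: pd.DataFrame
    channel: str
    normalized: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate sample_id in SignalMatrix")
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate protein_id in SignalMatrix")
        if self.values.isna().any().any():
            raise ValidationError("SignalMatrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("SNR values must be non-negative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids) -> "SignalMatrix":
        return SignalMatrix(
            values=self.values.loc[list(sample_ids)],
            channel=self.channel,
            normalized=self.normalized,
            provenance=dict(self.provenance),
        )

    def to_tsv(self, path, sidecar_path=None) -> None:
        out = self.values.copy()
        out.insert(0, "sample_id", out.index)
        out.to_csv(path, sep="\t", index=False, float_format="%.10g")
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "channel": self.channel,
                        "normalized": self.normalized,
                        "provenance": self.provenance,
                    },
                    fh,
                    indent=2,
                    sort_keys=True,
                )
                fh.write("\n")

    @classmethod
    def from_tsv(cls, path, sidecar_path=None) -> "SignalMatrix":
        df = pd.read_csv(path, sep="\t").set_index("sample_id")
        meta = {"channel": "IgG", "normalized": False, "provenance": {}}
        if sidecar_path is not None:
            with open(sidecar_path) as fh:
                meta.update(json.load(fh))
        return cls(values=df, **meta)


def _validate_spots(spots: pd.DataFrame) -> None:
    required = {"sample_id", "protein_id", "spot_index", "channel", "fg_median", "bg_median"}
    missing = required - set(spots.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    bad = spots["bg_median"] <= 0
    if bad.any():
        row = spots.loc[bad.idxmax()]
        raise ValidationError(
            "non-positive background median at "
            f"(sample={row['sample_id']}, protein={row['protein_id']}, "
            f"spot={row['spot_index']}, channel={row['channel']})"
        )
    if (spots["fg_median"] < 0).any():
        raise ValidationError("negative foreground median")
    keys = ["sample_id", "protein_id", "spot_index", "channel"]
    dup = spots.duplicated(subset=keys)
    if dup.any():
        row = spots.loc[dup.idxmax()]
        raise ValidationError(
            "duplicate spot key "
            f"(sample={row['sample_id']}, protein={row['protein_id']}, "
            f"spot={row['spot_index']}, channel={row['channel']})"
        )


def compute_snr(spots: pd.DataFrame) -> dict[str, SignalMatrix]:
    """Per-protein SNR matrices, one per channel.

    Per-spot SNR = fg_median / bg_median; the per-protein value is the
    arithmetic mean over that protein's duplicate spots. Invariant to the
    row order of the spot table.
    """
    _validate_spots(spots)
    work = spots.assign(snr=spots["fg_median"] / spots["bg_median"])
    out: dict[str, SignalMatrix] = {}
    for channel, chunk in work.groupby("channel", sort=True):
        mat = chunk.pivot_table(
            index="sample_id", columns="protein_id", values="snr", aggfunc="mean"
        )
        if mat.isna().any().any():
            raise ValidationError(f"channel {channel}: missing spots for some sample/protein pairs")
        mat = mat.sort_index(axis=0).sort_index(axis=1)
        mat.index.name = None
        mat.columns.name = None
        out[str(channel)] = SignalMatrix(values=mat, channel=str(channel))
    return out


def snr_matrix(spots: pd.DataFrame, channel: str = "IgG") -> SignalMatrix:
    """Convenience: the SNR matrix of a single channel."""
    matrices = compute_snr(spots)
    if channel not in matrices:
        raise ValidationError(f"channel {channel!r} not present in spot table")
    return matrices[channel]


def _quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Mean-quantile-profile normalization with tie averaging.

    Every sample's sorted values are mapped onto the cross-sample mean of
    the order statistics; tied values receive the mean of the profile
    entries they span, so within-sample rank order (ties allowed) is
    preserved exactly.
    """
    arr = values.to_numpy(dtype=float)
    n, p = arr.shape
    profile = np.sort(arr, axis=1).mean(axis=0)
    ranks = pd.DataFrame(arr).rank(axis=1, method="average").to_numpy()
    out = np.interp(ranks, np.arange(1, p + 1), profile)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize_signals(matrix: SignalMatrix, method: str = "quantile") -> SignalMatrix:
    """Cross-array normalization of an unnormalized SNR matrix.

    ``quantile``: each sample's sorted values are set to the cross-sample
    mean quantile profile (requires >= 2 samples). ``median_scale``: each
    sample is divided by its own median and multiplied by the median of the
    per-sample medians. ``none`` passes values through but flags them as
    normalized.
    """
    if matrix.normalized:
        raise ValidationError("matrix is already normalized")
    if method == "quantile":
        if matrix.values.shape[0] < 2:
            raise ValidationError("quantile normalization requires >= 2 samples")
        values = _quantile_normalize(matrix.values)
    elif method == "median_scale":
        medians = matrix.values.median(axis=1)
        if (medians <= 0).any():
            raise ValidationError("median_scale requires positive sample medians")
        grand = float(np.median(medians))
        values = matrix.values.div(medians, axis=0) * grand
    elif method == "none":
        values = matrix.values.copy()
    else:
        raise ValidationError(f"unknown normalization method {method!r}")
    provenance = dict(matrix.provenance)
    provenance["normalization"] = method
    return SignalMatrix(values=values, channel=matrix.channel, normalized=True, provenance=provenance)


def replicate_correlation(scans: list[SignalMatrix]) -> tuple[pd.DataFrame, float]:
    """Pairwise Pearson correlations between replicate scans of one sample.

    Each scan must contain exactly one sample over an identical protein
    set. Returns the symmetric correlation matrix (diagonal 1) and the
    mean over its off-diagonal entries.
    """
    if len(scans) < 2:
        raise ValidationError("need >= 2 replicate scans")
    proteins = scans[0].protein_ids
    rows = []
    for scan in scans:
        if scan.values.shape[0] != 1:
            raise ValidationError("each replicate scan must contain exactly one sample")
        if scan.protein_ids != proteins:
            raise ValidationError("replicate scans have mismatched protein sets")
        rows.append(scan.values.to_numpy(dtype=float)[0])
    stacked = np.vstack(rows)
    corr = np.corrcoef(stacked)
    labels = [scan.sample_ids[0] for scan in scans]
    corr_df = pd.DataFrame(corr, index=labels, columns=labels)
    k = len(scans)
    mean_r = float((corr.sum() - k) / (k * (k - 1)))
    return corr_df, mean_r
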