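"""Synthetic seromics cohort generator.

Emulates a three-group serum-autoantibody study (HCC patients, cirrhotic
patients, healthy controls) profiled on protein arrays, starting at the
level of spot median intensities:

* each printed protein has a latent log signal-to-noise ratio (SNR) that is
  normal across samples, with a mean shift (``effect_size``) for a minority
  of truly discriminative proteins in HCC samples and a fractional leak of
  that shift (``cirrhosis_leak``) in cirrhotic samples;
* spot background medians are gamma-distributed (right-skewed, positive)
  and foreground = background x latent SNR, so the observed per-spot ratio
  recovers the latent SNR up to small spot-level noise;
* each protein is printed in duplicate and scanned in two channels (IgG,
  IgM); by default the planted group effect is expressed in IgG only;
* clinical covariates mimic an East-Asian HCC cohort: serum AFP drawn from
  a two-component log-normal mixture in HCC (an AFP-high and an AFP-low
  subpopulation) and a low log-normal in controls, HBsAg status, and BCLC
  stage.

Per-sample RNG streams are derived from the master seed and a fixed
(group, index) key, so enlarging one group never perturbs the draws of
existing samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import substream
from .errors import ValidationError

GROUPS = ("HCC", "cirrhotic", "healthy")
_GROUP_CODE = {"HCC": 1, "cirrhotic": 2, "healthy": 3}

#: Column order of the simplified tab-delimited spot-table dialect.
SPOT_COLUMNS = ("sample_id", "protein_id", "spot_index", "channel", "fg_median", "bg_median")

METADATA_COLUMNS = ("sample_id", "group", "afp_ng_ml", "hbsag", "bclc_stage", "phase")


@dataclass(frozen=True)
class AfpParams:
    """Two-component log-normal mixture for serum AFP (ng/mL) in HCC.

    The AFP-high component carries essentially all mass above the 400 ng/mL
    diagnostic cutoff; the AFP-low component supplies the AFP-negative
    (< 20 ng/mL) subgroup. Defaults target roughly 30% of HCC above 400
    and roughly 40% below 20.
    """

    weight_high: float = 0.385
    mu_log_high: float = math.log(1000.0)
    sigma_log_high: float = 1.2
    mu_log_low: float = math.log(15.0)
    sigma_log_low: float = 0.8

    def __post_init__(self):
        if not 0.0 <= self.weight_high <= 1.0:
            raise ValidationError("weight_high must be in [0, 1]")
        if self.sigma_log_high <= 0 or self.sigma_log_low <= 0:
            raise ValidationError("AFP log-scale sigmas must be positive")

    def frac_above(self, cutoff: float) -> float:
        """Population P(AFP > cutoff) under the HCC mixture."""
        hi = stats.norm.sf(math.log(cutoff), self.mu_log_high, self.sigma_log_high)
        lo = stats.norm.sf(math.log(cutoff), self.mu_log_low, self.sigma_log_low)
        return float(self.weight_high * hi + (1.0 - self.weight_high) * lo)

    def frac_below(self, cutoff: float) -> float:
        """Population P(AFP < cutoff) under the HCC mixture."""
        return 1.0 - self.frac_above(cutoff)

    @property
    def target_positive_at_400(self) -> float:
        return self.frac_above(400.0)

    @property
    def target_negative_at_20(self) -> float:
        return self.frac_below(20.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated cohort.

    ``effect_size`` is the log-scale SNR shift of informative proteins in
    HCC samples; with sample-level SD ``sigma_sample`` the standardized
    per-marker effect is ``effect_size / sigma_sample`` and the implied
    fold change is ``exp(effect_size)``.
    """

    n_hcc: int = 282
    n_cirrhotic: int = 130
    n_healthy: int = 164
    n_proteins: int = 100
    n_informative: int = 7
    effect_size: float = 0.35
    cirrhosis_leak: float = 0.3
    duplicate_spots: int = 2
    channels: tuple[str, ...] = ("IgG", "IgM")
    afp_params: AfpParams = field(default_factory=AfpParams)
    stage_probs: tuple[float, float, float, float] = (0.06, 0.44, 0.26, 0.24)
    hbsag_pos_frac: float = 0.70
    seed: int = 0
    phase: str = "test"
    # Seed of the printed-array structure (protein baselines and the
    # informative set). Phases profiled on the same arrays must share it;
    # defaults to ``seed``.
    array_seed: int | None = None
    # Nuisance scales of the latent intensity model.
    baseline_log_snr: float = 0.3
    sigma_protein: float = 0.2
    sigma_sample: float = 0.5
    sigma_spot: float = 0.05
    bg_shape: float = 4.0
    bg_scale: float = 50.0
    informative_channel: str = "IgG"

    def __post_init__(self):
        if min(self.n_hcc, self.n_cirrhotic, self.n_healthy) < 0:
            raise ValidationError("group counts must be non-negative")
        if self.n_proteins <= 0:
            raise ValidationError("n_proteins must be positive")
        if not 0 <= self.n_informative <= self.n_proteins:
            raise ValidationError("n_informative must lie in [0, n_proteins]")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be non-negative")
        if not 0.0 <= self.cirrhosis_leak <= 1.0:
            raise ValidationError("cirrhosis_leak must be in [0, 1]")
        if self.duplicate_spots < 1:
            raise ValidationError("duplicate_spots must be >= 1")
        if not self.channels or not set(self.channels) <= {"IgG", "IgM"}:
            raise ValidationError("channels must be a non-empty subset of {IgG, IgM}")
        if abs(sum(self.stage_probs) - 1.0) > 1e-8 or min(self.stage_probs) < 0:
            raise ValidationError("stage_probs must be a distribution over BCLC 0/A/B/C")
        if not 0.0 <= self.hbsag_pos_frac <= 1.0:
            raise ValidationError("hbsag_pos_frac must be in [0, 1]")

    @property
    def protein_ids(self) -> list[str]:
        return [f"P{i:04d}" for i in range(1, self.n_proteins + 1)]

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


_STAGES = ("0", "A", "B", "C")
# HBsAg positivity in the non-HCC groups (chronic-HBV cirrhosis cohort,
# screened-healthy controls); fixed, not exposed as study conditions.
_HBSAG_FRAC = {"cirrhotic": 0.85, "healthy": 0.02}
_CTRL_AFP = {"cirrhotic": (math.log(6.0), 0.8), "healthy": (math.log(4.0), 0.6)}


def _protein_baselines(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-protein baseline log-SNR and the informative-protein index set."""
    array_seed = config.seed if config.array_seed is None else config.array_seed
    rng = substream(array_seed, 0)
    mu = config.baseline_log_snr + config.sigma_protein * rng.standard_normal(config.n_proteins)
    informative = np.sort(rng.choice(config.n_proteins, size=config.n_informative, replace=False))
    return mu, informative


def _group_shift(config: SimulationConfig, group: str) -> float:
    if group == "HCC":
        return config.effect_size
    if group == "cirrhotic":
        return config.effect_size * config.cirrhosis_leak
    return 0.0


def _sample_spots(
    config: SimulationConfig,
    rng: np.random.Generator,
    mu: np.ndarray,
    informative: np.ndarray,
    group: str,
) -> dict[str, np.ndarray]:
    """Spot-level arrays (one sample, all channels/spots) from one RNG stream."""
    p = config.n_proteins
    fg_parts, bg_parts, chan_parts, spot_parts = [], [], [], []
    for channel in sorted(config.channels):
        latent = mu + config.sigma_sample * rng.standard_normal(p)
        if channel == config.informative_channel:
            latent = latent.copy()
            latent[informative] += _group_shift(config, group)
        for spot in range(1, config.duplicate_spots + 1):
            bg = rng.gamma(config.bg_shape, config.bg_scale, size=p)
            spot_noise = config.sigma_spot * rng.standard_normal(p)
            fg = bg * np.exp(latent + spot_noise)
            fg_parts.append(fg)
            bg_parts.append(bg)
            chan_parts.append(np.full(p, channel, dtype=object))
            spot_parts.append(np.full(p, spot, dtype=np.int64))
    n_blocks = len(fg_parts)
    return {
        "protein_id": np.tile(np.asarray(config.protein_ids, dtype=object), n_blocks),
        "spot_index": np.concatenate(spot_parts),
        "channel": np.concatenate(chan_parts),
        "fg_median": np.concatenate(fg_parts),
        "bg_median": np.concatenate(bg_parts),
    }


def _sample_afp(config: SimulationConfig, rng: np.random.Generator, group: str) -> float:
    if group == "HCC":
        ap = config.afp_params
        if rng.random() < ap.weight_high:
            return float(rng.lognormal(ap.mu_log_high, ap.sigma_log_high))
        return float(rng.lognormal(ap.mu_log_low, ap.sigma_log_low))
    mu_log, sigma_log = _CTRL_AFP[group]
    return float(rng.lognormal(mu_log, sigma_log))


def generate_cohort(config: SimulationConfig):
    """Simulate one cohort.

    Returns
    -------
    spots : pandas.DataFrame
        Long spot table over all samples in the simplified GPR-style
        dialect (columns :data:`SPOT_COLUMNS`).
    metadata : pandas.DataFrame
        One row per sample (columns :data:`METADATA_COLUMNS`).
    truth : set of str
        Protein IDs carrying the planted group effect.
    """
    mu, informative = _protein_baselines(config)
    truth = {config.protein_ids[i] for i in informative}

    spot_frames = []
    meta_rows = []
    counts = {"HCC": config.n_hcc, "cirrhotic": config.n_cirrhotic, "healthy": config.n_healthy}
    for group in GROUPS:
        code = _GROUP_CODE[group]
        for i in range(counts[group]):
            rng = substream(config.seed, code, i)
            sample_id = f"{config.phase}-{group}-{i:04d}"
            arrays = _sample_spots(config, rng, mu, informative, group)
            n = arrays["protein_id"].shape[0]
            arrays["sample_id"] = np.full(n, sample_id, dtype=object)
            spot_frames.append(pd.DataFrame(arrays, columns=list(SPOT_COLUMNS)))

            afp = _sample_afp(config, rng, group)
            if group == "HCC":
                hbsag = "pos" if rng.random() < config.hbsag_pos_frac else "neg"
                stage = _STAGES[rng.choice(4, p=np.asarray(config.stage_probs))]
            else:
                hbsag = "pos" if rng.random() < _HBSAG_FRAC[group] else "neg"
                stage = "NA"
            meta_rows.append((sample_id, group, afp, hbsag, stage, config.phase))

    spots = pd.concat(spot_frames, ignore_index=True) if spot_frames else pd.DataFrame(
        columns=list(SPOT_COLUMNS)
    )
    metadata = pd.DataFrame(meta_rows, columns=list(METADATA_COLUMNS))
    return spots, metadata, truth


def replicate_noise_sd(config: SimulationConfig, target_correlation: float) -> float:
    """Array-level log-scale noise SD hitting a target linear-scale Pearson r.

    For jointly log-normal replicates sharing a latent vector with log-scale
    variance v and carrying independent noise of variance t**2, the
    population linear-scale correlation is (exp(v)-1)/(exp(v+t**2)-1);
    inverting gives t**2 = log((exp(v)-1)/r + 1) - v.
    """
    if not 0.0 < target_correlation <= 1.0:
        raise ValidationError("target_correlation must be in (0, 1]")
    v = config.sigma_protein**2 + config.sigma_sample**2
    t2 = math.log((math.exp(v) - 1.0) / target_correlation + 1.0) - v
    return math.sqrt(max(t2, 0.0))


def generate_replicate_scans(
    config: SimulationConfig,
    n_replicates: int,
    seed: int | None = None,
    target_correlation: float = 0.95,
    noise_sd: float | None = None,
) -> list[pd.DataFrame]:
    """Replicate scans of one latent serum sample on identical arrays.

    Replicates share the sample's latent per-protein log-SNR vector and
    differ only by array-level multiplicative noise (one log-normal factor
    per protein per array). ``noise_sd`` overrides the noise magnitude;
    when omitted it is derived so the expected pairwise linear-scale
    Pearson correlation equals ``target_correlation``. With ``noise_sd=0``
    the replicate SNR profiles are identical.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    if noise_sd is None:
        noise_sd = replicate_noise_sd(config, target_correlation)
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    seed = config.seed if seed is None else seed

    mu, _ = _protein_baselines(config)
    rng = substream(seed, 7)
    latent = mu + config.sigma_sample * rng.standard_normal(config.n_proteins)

    proteins = np.asarray(config.protein_ids, dtype=object)
    scans = []
    for r in range(n_replicates):
        rng_r = substream(seed, 7, 1 + r)
        noise = noise_sd * rng_r.standard_normal(config.n_proteins)
        parts = []
        for channel in sorted(config.channels):
            for spot in range(1, config.duplicate_spots + 1):
                bg = rng_r.gamma(config.bg_shape, config.bg_scale, size=config.n_proteins)
                fg = bg * np.exp(latent + noise)
                parts.append(
                    pd.DataFrame(
                        {
                            "sample_id": f"replicate-{r:02d}",
                            "protein_id": proteins,
                            "spot_index": spot,
                            "channel": channel,
                            "fg_median": fg,
                            "bg_median": bg,
                        },
                        columns=list(SPOT_COLUMNS),
                    )
                )
        scans.append(pd.concat(parts, ignore_index=True))
    return scans


def write_spot_table(spots: pd.DataFrame, path) -> None:
    """Write a spot table in the tab-delimited dialect (fixed float format)."""
    spots.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_spot_table(path) -> pd.DataFrame:
    spots = pd.read_csv(path, sep="\t")
    missing = set(SPOT_COLUMNS) - set(spots.columns)
    if missing:
        raise ValidationError(f"spot table missing columns: {sorted(missing)}")
    return spots[list(SPOT_COLUMNS)]


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    missing = set(METADATA_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"metadata missing columns: {sorted(missing)}")
    if meta["sample_id"].duplicated().any():
        raise ValidationError("duplicate sample_id in metadata")
    return meta[list(METADATA_COLUMNS)]
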