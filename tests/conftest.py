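import numpy as np
import pandas as pd
import pytest

from seropanel import SignalMatrix, SimulationConfig, generate_cohort, normalize_signals, snr_matrix


@pytest.fixture(scope="session")
def small_cohort():
    """A small three-group cohort with 5 strongly planted markers."""
    cfg = SimulationConfig(
        n_hcc=40, n_cirrhotic=20, n_healthy=30, n_proteins=40, n_informative=5,
        effect_size=0.8, cirrhosis_leak=0.0, seed=11,
    )
    spots, metadata, truth = generate_cohort(cfg)
    return cfg, spots, metadata, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, spots, metadata, truth = small_cohort
    matrix = normalize_signals(snr_matrix(spots, channel="IgG"))
    return matrix, metadata, truth


def toy_signal_matrix(values: np.ndarray, normalized: bool = True, prefix: str = "M") -> SignalMatrix:
    """Wrap a plain array as a normalized SignalMatrix with neutral labels."""
    values = np.asarray(values, dtype=float)
    df = pd.DataFrame(
        values,
        index=[f"s{i:03d}" for i in range(values.shape[0])],
        columns=[f"{prefix}{j:03d}" for j in range(values.shape[1])],
    )
    return SignalMatrix(values=df, channel="IgG", normalized=normalized)


def toy_metadata(groups: list[str], afp=None) -> pd.DataFrame:
    n = len(groups)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i:03d}" for i in range(n)],
            "group": groups,
            "afp_ng_ml": afp if afp is not None else np.ones(n),
            "hbsag": ["neg"] * n,
            "bclc_stage": ["A" if g == "HCC" else "NA" for g in groups],
            "phase": ["test"] * n,
        }
    )
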