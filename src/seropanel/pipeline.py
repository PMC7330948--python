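"""End-to-end orchestration: simulate -> quantify -> screen -> select -> train -> evaluate.

The pipeline mirrors the three-phase study design: markers are screened
and the panel and committee are fitted on the test phase, then the frozen
committee is applied blind to the validation phase. Sample IDs of the two
phases must be disjoint (leakage guard), every artifact is stamped with
the configuration hash and master seed, and a rerun with the same
configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from ._utils import spawn_seed
from .committee import NetworkSpec, build_committee
from .errors import LeakageError, ValidationError
from .evaluate import combine_afp_ann, stratified_report
from .panel import panel_report, select_panel
from .screening import screening_report, test_phase_filter
from .signals import normalize_signals, snr_matrix
from .simulate import SimulationConfig, generate_cohort, write_metadata, write_spot_table

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "channel": "IgG",
    "normalization": "quantile",
    "write_spots": False,
    "simulate": {
        "test": {"n_hcc": 282, "n_cirrhotic": 130, "n_healthy": 164},
        "validation": {"n_hcc": 279, "n_cirrhotic": 119, "n_healthy": 179},
        "shared": {"n_proteins": 100, "n_informative": 7, "effect_size": 0.35,
                   "cirrhosis_leak": 0.3},
    },
    "screening": {"alpha": 0.05, "fc_min": 1.2, "sens_min": 0.15, "min_spec": 0.90},
    "panel": {"n_folds": 10, "stratified": True, "mode": "pooled", "criterion": "aic"},
    "committee": {"n_folds": 10, "n_repeats": 50, "learning_rate": 0.05,
                  "max_epochs": 500, "early_stop_patience": 20},
    "vote_threshold": 0.5,
}


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(config: dict | None = None) -> dict:
    """User configuration merged over the documented defaults."""
    return _deep_merge(DEFAULT_CONFIG, config or {})


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def simulation_config(config: dict, phase: str) -> SimulationConfig:
    """The resolved :class:`SimulationConfig` for one phase."""
    sim = config["simulate"]
    fields = {**sim.get("shared", {}), **sim.get(phase, {})}
    offset = {"test": 101, "validation": 102}[phase]
    fields.setdefault("seed", spawn_seed(config["seed"], offset))
    # Both phases are profiled on the same printed arrays.
    fields.setdefault("array_seed", spawn_seed(config["seed"], 100))
    fields.setdefault("phase", phase)
    return SimulationConfig(**fields)


def run_pipeline(config: dict | None = None, outdir="seropanel_out") -> Path:
    """Execute the full pipeline; returns the output directory.

    Writes the normalized signal matrices, metadata, screening and panel
    reports, the serialized committee, per-phase evaluation tables, and a
    provenance record.
    """
    config = resolve_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    channel = config["channel"]

    cohorts = {}
    for phase in ("test", "validation"):
        sim_cfg = simulation_config(config, phase)
        spots, metadata, truth = generate_cohort(sim_cfg)
        cohorts[phase] = (spots, metadata, truth)
        logger.info("%s phase: %d samples, %d proteins", phase, len(metadata), sim_cfg.n_proteins)
        write_metadata(metadata, outdir / f"metadata_{phase}.tsv")
        if config["write_spots"]:
            write_spot_table(spots, outdir / f"spots_{phase}.tsv")

    test_ids = set(cohorts["test"][1]["sample_id"])
    val_ids = set(cohorts["validation"][1]["sample_id"])
    overlap = test_ids & val_ids
    if overlap:
        raise LeakageError(
            f"{len(overlap)} sample ID(s) shared between test and validation phases"
        )

    matrices = {}
    for phase, (spots, metadata, _) in cohorts.items():
        matrix = normalize_signals(snr_matrix(spots, channel=channel), config["normalization"])
        matrix.provenance.update({"phase": phase, "channel": channel})
        matrix.to_tsv(outdir / f"signals_{phase}.tsv", outdir / f"signals_{phase}.json")
        matrices[phase] = (matrix, metadata)

    test_matrix, test_meta = matrices["test"]
    screen_table = test_phase_filter(test_matrix, test_meta, **config["screening"])
    screening_report(screen_table, outdir / "screening_report.tsv")
    n_hits = screen_table.loc[screen_table["hit_class"] != "none", "protein_id"].nunique()
    logger.info("test-phase filter: %d / %d proteins pass", n_hits, len(test_matrix.protein_ids))

    selection = select_panel(
        test_matrix, test_meta, seed=spawn_seed(seed, 103),
        **config["panel"], **config["screening"],
    )
    panel_report(selection, outdir / "panel_report.tsv")
    logger.info("consensus panel: %s", selection.consensus_panel)
    if not selection.consensus_panel:
        raise ValidationError(
            "consensus panel is empty: no marker was selected in every fold "
            "(weak effects or too little data)"
        )

    panel = selection.consensus_panel
    labels = (test_meta.set_index("sample_id").loc[test_matrix.values.index, "group"] == "HCC")
    net_cfg = config["committee"]
    spec = NetworkSpec(
        n_inputs=len(panel),
        learning_rate=net_cfg["learning_rate"],
        max_epochs=net_cfg["max_epochs"],
        early_stop_patience=net_cfg["early_stop_patience"],
    )
    results = build_committee(
        test_matrix.values[panel], labels.to_numpy(float),
        n_folds=net_cfg["n_folds"], n_repeats=net_cfg["n_repeats"],
        spec=spec, seed=spawn_seed(seed, 104), vote_threshold=config["vote_threshold"],
    )
    results.to_json(outdir / "committee_model.json")
    logger.info("committee: %d member networks", results.n_networks)

    # Test-phase evaluation uses out-of-fold votes; the combiner is fitted
    # on the test phase and applied frozen to the blind phase.
    test_afp = test_meta.set_index("sample_id").loc[test_matrix.values.index, "afp_ng_ml"]
    combined_test, combiner = combine_afp_ann(
        test_afp.to_numpy(float), results.oof_votes.to_numpy(), labels.to_numpy(float)
    )
    report_test = stratified_report(
        test_meta, results.oof_votes,
        pd.Series(combined_test, index=results.oof_votes.index),
        vote_threshold=config["vote_threshold"],
    )
    report_test.to_csv(outdir / "evaluation_test.tsv", sep="\t", index=False, float_format="%.10g")

    val_matrix, val_meta = matrices["validation"]
    blind_votes = results.predict(val_matrix.values[panel])
    val_afp = val_meta.set_index("sample_id").loc[val_matrix.values.index, "afp_ng_ml"]
    combined_val = combiner.score(val_afp.to_numpy(float), blind_votes.to_numpy())
    report_val = stratified_report(
        val_meta, blind_votes, pd.Series(combined_val, index=blind_votes.index),
        vote_threshold=config["vote_threshold"],
    )
    report_val.to_csv(
        outdir / "evaluation_validation.tsv", sep="\t", index=False, float_format="%.10g"
    )

    provenance = {
        "seropanel_version": __version__,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "funnel": {
            "proteins": len(test_matrix.protein_ids),
            "test_phase_hits": int(n_hits),
            "consensus_panel": panel,
            "committee_networks": results.n_networks,
        },
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
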