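"""End-to-end pipeline: simulate/score -> cluster -> stability -> importance
-> measures -> SOM -> treatment, with file outputs and a JSON summary.

All stage randomness derives from one global seed via a stable hash
(stage seed = blake2b(global_seed, stage name) mod 2^31), recorded in the
summary so every stage is independently reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from .cluster import PhenotypeClustering, pcoa_bray, unit_scale
from .errors import ConfigurationError, ValidationError
from .importance import select_discriminatory_items
from .instruments import score_dataframe
from .simulate import (
    default_cohort_config,
    generate_cohort_frame,
    generate_treatment_records,
    treatment_frame,
)
from .som import BinSummaryConfig, SOMConfig, SelfOrganizingMap
from .treatment import pairwise_response_tests, responder_proportions, responder_table

__all__ = ["PipelineConfig", "derive_seed", "run_pipeline", "scale_measures"]

log = logging.getLogger("bladderpheno")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31."""
    digest = hashlib.blake2b(f"{global_seed}:{stage}".encode(), digest_size=8).digest()
    return int.from_bytes(digest, "big") % (2**31)


@dataclass
class PipelineConfig:
    """Configuration of the full analysis run (YAML round-trippable)."""

    seed: int = 0
    out_dir: str = "results"
    simulate: bool = True
    cohort_path: str | None = None
    treatment_path: str | None = None
    labels_path: str | None = None
    # generator
    mixed_fraction: float = 0.0
    correlation: float = 0.0
    # clustering
    k: int = 3
    k_max: int = 8
    n_restarts: int = 50
    log_columns: tuple[str, ...] = ()
    # stability
    stability_B: int = 10_000
    stability_restarts: int = 10
    # importance
    n_trees: int = 500
    top_n_items: int = 20
    # SOM
    som_rows: int = 4
    som_cols: int = 6
    som_iterations: int = 1_000_000
    som_alpha0: float = 0.1
    n_metaclusters: int = 4
    bin_low_threshold: float = 0.25
    bin_high_threshold: float = 0.6
    bin_dominance_ratio: float = 2.0

    @classmethod
    def ci_profile(cls, seed: int = 0, out_dir: str = "results", **overrides) -> "PipelineConfig":
        """Reduced-size profile (B=1,000; 100,000 SOM iterations)."""
        kwargs = dict(seed=seed, out_dir=out_dir,
                      stability_B=1_000, som_iterations=100_000)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["log_columns"] = list(self.log_columns)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        if "log_columns" in d:
            d["log_columns"] = tuple(d["log_columns"])
        return cls(**d)


def scale_measures(measured: pd.DataFrame) -> pd.DataFrame:
    """Unit-scale the three phenotype measures over the cohort to [0, 1].

    The non-urologic pain count has a fixed 0-5 scale; the myofascial
    measure is already in [0, 1]; the z-based bladder-pain measure is
    min-max scaled over the cohort.
    """
    out = measured[["bps_measure", "nupp_measure", "mfp_measure"]].copy()
    lo, hi = out["bps_measure"].min(), out["bps_measure"].max()
    if hi <= lo:
        raise ValidationError("degenerate bladder-pain measure (no spread)")
    out["bps_measure"] = (out["bps_measure"] - lo) / (hi - lo)
    out["nupp_measure"] = out["nupp_measure"] / 5.0
    out["mfp_measure"] = out["mfp_measure"].clip(0.0, 1.0)
    if "subject_id" in measured.columns:
        out.index = pd.Index(measured["subject_id"], name="subject_id")
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage, write stage outputs under ``config.out_dir`` and
    return (and write) a machine-readable summary."""
    if not config.simulate and not config.cohort_path:
        raise ConfigurationError("cohort_path required when simulate is false")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: derive_seed(config.seed, stage)
             for stage in ("simulate", "treatment_sim", "cluster", "stability",
                           "importance", "som")}
    log.info("pipeline start; global seed %d; stage seeds %s", config.seed, seeds)

    # --- cohort -----------------------------------------------------------
    true_labels: pd.Series | None = None
    if config.simulate:
        cohort_cfg = default_cohort_config(
            seed=seeds["simulate"], mixed_fraction=config.mixed_fraction,
            correlation=config.correlation,
        )
        cohort, true_labels = generate_cohort_frame(cohort_cfg)
        records = generate_treatment_records(true_labels, seed=seeds["treatment_sim"])
        _io.write_cohort_csv(cohort, out / "cohort.csv")
        _io.write_labels_csv(true_labels, out / "true_labels.csv")
        _io.write_treatment_csv(records, out / "treatment.csv")
    else:
        cohort = _io.read_cohort_csv(config.cohort_path)
        records = (_io.read_treatment_csv(config.treatment_path)
                   if config.treatment_path else [])
        if config.labels_path:
            true_labels = _io.read_labels_csv(config.labels_path)

    # --- scoring ----------------------------------------------------------
    scored = score_dataframe(cohort, with_measures=True)
    scored.to_csv(out / "scored.csv", index=False)

    # --- clustering (cases only) ------------------------------------------
    model = PhenotypeClustering.from_dataframe(cohort, log_columns=config.log_columns)
    curve = model.wss_curve(k_max=config.k_max, seed=seeds["cluster"])
    pd.DataFrame(curve, columns=["k", "wss"]).to_csv(out / "wss_curve.csv", index=False)
    from .cluster import suggest_k
    suggested = suggest_k(curve)
    res = model.fit(k=config.k, seed=seeds["cluster"], n_restarts=config.n_restarts)
    _io.write_labels_csv(res.labels, out / "cluster_labels.csv")
    res.centroids.to_csv(out / "centroids.csv")
    cases = cohort.loc[cohort.get("group_label", "case") == "case"] \
        if "group_label" in cohort.columns else cohort
    pcoa_bray(unit_scale(cases)).to_csv(out / "pcoa.csv")

    # --- stability --------------------------------------------------------
    stab = res.bootstrap_stability(B=config.stability_B, seed=seeds["stability"],
                                   n_restarts=config.stability_restarts)
    (out / "stability.json").write_text(json.dumps(stab.to_dict(), indent=2, sort_keys=True))
    stab.to_frame().to_csv(out / "stability.csv")

    # --- importance -------------------------------------------------------
    imp = res.variable_importance(n_trees=config.n_trees, seed=seeds["importance"])
    imp.table.to_csv(out / "importance.csv")
    zmat = res.phenotype_z_matrix(raw=cases)
    zmat.table.to_csv(out / "zmatrix.csv")
    item_sets, ties = select_discriminatory_items(imp, zmat, top_n=config.top_n_items)

    # --- measures + SOM (cases and controls) ------------------------------
    measures = scale_measures(scored.set_index("subject_id")
                              [["bps_measure", "nupp_measure", "mfp_measure"]])
    measures.to_csv(out / "measures.csv")
    som_cfg = SOMConfig(rows=config.som_rows, cols=config.som_cols,
                        iterations=config.som_iterations, alpha0=config.som_alpha0,
                        seed=seeds["som"])
    som_res = SelfOrganizingMap(measures, som_cfg).fit()
    som_res.codebook.to_csv(out / "som_codebook.csv", index_label="node")
    bins = som_res.classify_bins(cfg=BinSummaryConfig(
        low_threshold=config.bin_low_threshold,
        high_threshold=config.bin_high_threshold,
        dominance_ratio=config.bin_dominance_ratio,
    ))
    bins.table.to_csv(out / "som_bins.csv")
    pd.DataFrame(som_res.neighbor_distance_map()).to_csv(
        out / "som_neighbor_distance.csv", index=False)
    meta = som_res.metacluster(config.n_metaclusters)
    pd.DataFrame({"node": np.arange(len(meta)), "metacluster": meta}).to_csv(
        out / "som_metaclusters.csv", index=False)

    # --- treatment --------------------------------------------------------
    treatment_summary = None
    if records:
        resp_labels = true_labels
        if resp_labels is None:
            resp_labels = res.labels.astype(str)
        tab = responder_table(records, resp_labels.astype(str))
        tab.responders.to_csv(out / "responders.csv")
        tab.attempted.to_csv(out / "attempted.csv")
        wg, wc = responder_proportions(tab)
        wg.to_csv(out / "within_group_proportions.csv")
        wc.to_csv(out / "within_cohort_proportions.csv")
        pairwise_response_tests(tab).to_csv(out / "pairwise_tests.csv", index=False)
        treatment_summary = {
            "totals_responders": {t: int(v) for t, v in tab.totals.loc["responders"].items()},
            "totals_attempted": {t: int(v) for t, v in tab.totals.loc["attempted"].items()},
            "n_with_followup": {p: int(v) for p, v in tab.n_with_followup.items()},
        }

    summary = {
        "seed": config.seed,
        "stage_seeds": seeds,
        "n_subjects": int(len(cohort)),
        "n_cases": int((cohort["group_label"] == "case").sum())
        if "group_label" in cohort.columns else int(len(cohort)),
        "n_controls": int((cohort["group_label"] == "control").sum())
        if "group_label" in cohort.columns else 0,
        "suggested_k": int(suggested),
        "k": int(res.k),
        "cluster_sizes": {int(c): int(n) for c, n in res.cluster_sizes().items()},
        "wss": float(res.wss),
        "stability": stab.to_dict(),
        "discriminatory_items": item_sets,
        "z_ties": ties,
        "som_convergence_index": float(som_res.convergence_index()),
        "som_quantization_error": float(som_res.quantization_error()),
        "pure_or_control_fraction": float(bins.pure_or_control_fraction()),
        "treatment": treatment_summary,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log.info("pipeline done: %d subjects, k=%d", summary["n_subjects"], summary["k"])
    return summary
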