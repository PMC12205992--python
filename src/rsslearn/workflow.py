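"""End-to-end pipelines: train-and-explain runs with reproducible outputs.

``run_h4s2`` executes the single-library pipeline (load or simulate ->
zero completion -> normalization -> stratified rotation split -> train ->
evaluate -> attribution -> CRV -> melting-temperature sweep -> mutation
effect maps) and ``run_cnon`` the multi-nonamer pipeline (replicate
averaging -> dataset-wide normalization -> nonamer-informed training ->
per-group attribution rescaling -> KS matrix -> candidate flags).  Every
stage writes plot-ready TSV/JSON into the output directory, and a
manifest with content hashes plus the fully serialized configuration
makes reruns checkable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import crv as crv_mod
from . import dataset as ds
from . import effects as eff_mod
from . import nonamer as non_mod
from . import simulate as sim
from . import thermo
from .explain import PermutationExplainer, mean_abs_attribution
from .model import EfficiencyRegressor, ModelConfig, evaluate, train
from .sequences import H4S2_POSITIONS, enumerate_library, one_hot_encode

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a pipeline run; fully serialized with the outputs."""

    seed: int = 0
    counts_path: str | None = None  # None -> simulate at the default settings
    k_folds: int = 20
    n_bins: int = 10
    model: ModelConfig = field(default_factory=ModelConfig)
    shap_background_size: int = 64
    shap_n_permutations: int = 2
    shap_sample_size: int | None = None  # None -> all variants
    crv_axis_tolerance_deg: float = 10.0
    run_tm_sweep: bool = True
    run_crv: bool = True

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model"] = self.model.to_dict()
        return d


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))


def _manifest(outdir: Path) -> None:
    entries = {}
    for p in sorted(outdir.iterdir()):
        if p.name == "manifest.json" or p.is_dir():
            continue
        entries[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    _write_json(entries, outdir / "manifest.json")


def _stage(name: str, stages: list, t0: float) -> None:
    stages.append({"stage": name, "elapsed_s": round(time.time() - t0, 3)})
    logger.info("stage %s done (%.1fs)", name, time.time() - t0)


def run_h4s2(config: RunConfig, outdir) -> Path:
    """Run the single-library pipeline; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(config.to_dict(), outdir / "run_config.json")
    stages: list[dict] = []
    t0 = time.time()
    rng = np.random.default_rng(config.seed)

    library = enumerate_library(H4S2_POSITIONS)
    if config.counts_path is not None:
        table = ds.load_read_counts(config.counts_path)
        if "replicate" in table.columns:
            first = sorted(table["replicate"].unique())[0]
            table = table[table["replicate"] == first].drop(columns="replicate")
    else:
        truth = sim.make_truth(seed=config.seed)
        truth.to_json(outdir / "synthetic_truth.json")
        table = sim.simulate_counts(truth, seed=config.seed + 1)
        table = table.drop(columns="replicate")
    table = ds.complete_with_zeros(table, library)
    composition = ds.summarize_distribution(table)
    _write_json(composition, outdir / "composition.json")
    _stage("load_and_complete", stages, t0)

    t0 = time.time()
    norm = ds.minmax_normalize(table, mode="dataset-wide")
    targets = norm.set_index("sequence")["target"]
    encoding = one_hot_encode(norm["sequence"].tolist())
    rotations = ds.stratified_rotations(norm, k=config.k_folds,
                                        n_bins=config.n_bins, seed=config.seed)
    rot = rotations[0]
    masks = rot.role_masks()
    seqs = rot.folds.index
    ks_checks = {
        role: ds.ks_two_sample(targets.loc[seqs[mask]], targets)
        for role, mask in masks.items()
    }
    _write_json({r: {"statistic": s, "p_value": p} for r, (s, p) in ks_checks.items()},
                outdir / "fold_ks_checks.json")
    _stage("normalize_and_stratify", stages, t0)

    t0 = time.time()
    model = train(
        config.model,
        encoding.loc[seqs[masks["train"]]], targets.loc[seqs[masks["train"]]],
        encoding.loc[seqs[masks["validation"]]], targets.loc[seqs[masks["validation"]]],
    )
    model.save(outdir / "model")
    metrics = {
        role: evaluate(model.predict(encoding.loc[seqs[mask]]),
                       targets.loc[seqs[mask]]).to_dict()
        for role, mask in masks.items()
    }
    _write_json(metrics, outdir / "metrics.json")
    predictions = pd.Series(model.predict(encoding), index=encoding.index,
                            name="prediction")
    predictions.rename_axis("sequence").reset_index().to_csv(
        outdir / "predictions.tsv", sep="\t", index=False)
    _stage("train_and_evaluate", stages, t0)

    t0 = time.time()
    bg_idx = rng.choice(len(encoding), size=min(config.shap_background_size,
                                                len(encoding)), replace=False)
    background = encoding.iloc[bg_idx]
    if config.shap_sample_size is not None and config.shap_sample_size < len(encoding):
        samp_idx = rng.choice(len(encoding), size=config.shap_sample_size,
                              replace=False)
        samples = encoding.iloc[samp_idx]
    else:
        samples = encoding
    attr = PermutationExplainer(
        model, background, n_permutations=config.shap_n_permutations,
        random_state=config.seed,
    ).attributions(samples)
    attr.to_tsv(outdir / "attributions.tsv")
    importance = mean_abs_attribution(attr)
    importance.to_csv(outdir / "feature_importance.tsv", sep="\t")
    _write_json({"base_prediction": attr.base_prediction,
                 "global_mean_abs": importance.attrs["global_mean"]},
                outdir / "attribution_meta.json")
    _stage("shap", stages, t0)

    crvs = None
    if config.run_crv:
        t0 = time.time()
        crvs = crv_mod.all_crvs(attr, encoding,
                                axis_tolerance_deg=config.crv_axis_tolerance_deg)
        crvs.to_csv(outdir / "crv_table.tsv", sep="\t", index=False)
        curves = crv_mod.cumulative_curve(crvs, group_by="feature1")
        curves.to_csv(outdir / "crv_cumulative_curves.tsv", sep="\t", index=False)
        crv_mod.quadrant_census(crvs).to_csv(outdir / "crv_quadrant_census.tsv",
                                             sep="\t", index=False)
        groups = {}
        for pos in H4S2_POSITIONS:
            sub = curves[curves["group"].str.startswith(pos + "_")]
            groups[pos] = crv_mod.covariation_groups(sub)
        _write_json(groups, outdir / "crv_covariation_groups.json")
        _stage("crv", stages, t0)

    sweep_agg = None
    if config.run_tm_sweep:
        t0 = time.time()
        tms = thermo.library_tms(predictions.index)
        corr = thermo.tm_prediction_correlation(predictions, tms)
        sweep = thermo.sweep_kmer_regressions(predictions, tms)
        sweep.to_csv(outdir / "tm_regressions.tsv", sep="\t", index=False)
        sweep_agg = thermo.sweep_aggregates(sweep)
        _write_json({"correlation": corr, "aggregates": sweep_agg},
                    outdir / "tm_summary.json")
        _stage("tm_sweep", stages, t0)

    t0 = time.time()
    maps = eff_mod.effect_heatmaps(predictions, H4S2_POSITIONS)
    eff_mod.heatmaps_to_long(maps).to_csv(outdir / "mutation_effects.tsv",
                                          sep="\t", index=False)
    _stage("effect_maps", stages, t0)

    _write_json(stages, outdir / "stages.json")
    write_report(outdir)
    _manifest(outdir)
    return outdir


def run_cnon(config: RunConfig, outdir,
             nonamer_sequences: dict[str, str] | None = None) -> Path:
    """Run the multi-nonamer pipeline; returns the output directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_json(config.to_dict(), outdir / "run_config.json")
    stages: list[dict] = []
    rng = np.random.default_rng(config.seed)
    if nonamer_sequences is None:
        # synthetic stand-ins for the three nonamer groups' N1-N3,N8,N9 bases
        nonamer_sequences = {"CF1": "ACAAA", "Pax3": "ACACT", "LMO2": "GTTTT"}

    t0 = time.time()
    if config.counts_path is not None:
        raw = ds.load_read_counts(config.counts_path)
        tables = {g: sub.drop(columns="nonamer")
                  for g, sub in raw.groupby("nonamer")}
        truth = None
    else:
        truth = sim.make_truth(
            per_position_alphabets={"S1": "A", "S2": "TG"},
            nonamer_scales={"CF1": 1.0, "Pax3": 0.6, "LMO2": 0.25},
            seed=config.seed,
        )
        truth.to_json(outdir / "synthetic_truth.json")
        raw = sim.simulate_counts(truth, replicates=2, seed=config.seed + 1)
        tables = {g: sub.drop(columns="nonamer")
                  for g, sub in raw.groupby("nonamer")}
    table, encoding = non_mod.build_cnon_dataset(tables, nonamer_sequences)
    _stage("assemble_cnon", stages, t0)

    t0 = time.time()
    targets = pd.Series(table["target"].to_numpy(), index=encoding.index)
    n = len(encoding)
    order = rng.permutation(n)
    n_val = max(1, n // 10)
    val_idx, train_idx = order[:n_val], order[n_val:]
    model = train(config.model, encoding.iloc[train_idx], targets.iloc[train_idx],
                  encoding.iloc[val_idx], targets.iloc[val_idx])
    model.save(outdir / "model_cnon")
    metrics = evaluate(model.predict(encoding), targets).to_dict()
    _write_json(metrics, outdir / "metrics.json")
    _stage("train_cnon", stages, t0)

    t0 = time.time()
    bg_idx = rng.choice(n, size=min(config.shap_background_size, n), replace=False)
    attr = PermutationExplainer(
        model, encoding.iloc[bg_idx], n_permutations=config.shap_n_permutations,
        random_state=config.seed,
    ).attributions(encoding)
    groups = pd.Series(table["nonamer"].to_numpy(), index=encoding.index)
    rescaled, divisors = non_mod.rescale_by_global_mean(attr, groups)
    _write_json(divisors, outdir / "rescale_divisors.json")
    ks = non_mod.nonamer_ks_matrix(rescaled)
    ks.to_csv(outdir / "nonamer_ks_matrix.tsv", sep="\t", index=False)
    flags = non_mod.flag_long_distance_candidates(ks)
    flags.to_csv(outdir / "long_distance_candidates.tsv", sep="\t", index=False)
    _stage("shap_rescale_ks", stages, t0)

    _write_json(stages, outdir / "stages.json")
    write_report(outdir)
    _manifest(outdir)
    return outdir


def write_report(outdir) -> Path:
    """Collect stage outputs into one machine-readable summary JSON."""
    outdir = Path(outdir)
    report: dict = {"outputs": sorted(p.name for p in outdir.iterdir()
                                      if p.is_file())}
    for name in ("run_config", "composition", "metrics", "fold_ks_checks",
                 "tm_summary", "attribution_meta", "rescale_divisors"):
        p = outdir / f"{name}.json"
        if p.exists():
            report[name] = json.loads(p.read_text())
        else:
            logger.warning("report: missing stage output %s", p.name)
    census_path = outdir / "crv_quadrant_census.tsv"
    if census_path.exists():
        census = pd.read_csv(census_path, sep="\t")
        report["crv_quadrant_census"] = census.to_dict(orient="records")
        report["crv_total"] = int(census["n_crvs"].sum())
    imp_path = outdir / "feature_importance.tsv"
    if imp_path.exists():
        imp = pd.read_csv(imp_path, sep="\t", index_col=0)
        report["top_features"] = list(imp.index[:5])
    flags_path = outdir / "long_distance_candidates.tsv"
    if flags_path.exists():
        flags = pd.read_csv(flags_path, sep="\t")
        report["long_distance_candidates"] = flags.to_dict(orient="records")
    path = outdir / "report.json"
    _write_json(report, path)
    return path
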