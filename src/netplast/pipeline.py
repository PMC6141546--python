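"""End-to-end orchestration: one config in, a reproducible report bundle out.

Stages: load panel -> damage curves -> robustness ranking -> 14-feature
profiles -> pairwise dissimilarity + dendrogram -> ER/BA null ensembles
(D_ER, D_BA, feature z-scores vs BA) -> predictive models -> optional
accessibility report.  Every stochastic stage draws its seed from the
config's base seed via a SeedSequence spawn, and the manifest records the
config, per-stage seeds, input file hashes, package version and the
measurement conventions, so every table can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, null_models, perturbation, prediction, \
    robustness, topology
from . import dissimilarity as _dsm_module  # noqa: F401 (module handle)
from .dissimilarity import (DEFAULT_WEIGHTS, linkage_to_newick,
    pairwise_dissimilarity)
from . import accessibility as acc

logger = logging.getLogger(__name__)

_STAGES = ("perturb", "nullmodels", "predict", "modularity", "tie_shuffle")


@dataclass
class RunConfig:
    networks_dir: str
    out_dir: str
    pattern: str = "*.txt"
    f_start: float = 0.01
    f_stop: float = 1.0
    f_step: float = 0.01
    error_reps: int = 1000
    attack_strategy: str = "static_degree"
    null_reps: int = 100
    d_weights: tuple = DEFAULT_WEIGHTS
    cv_folds: int = 5
    n_trees: int = 1000
    seed: int = 0
    groups: dict | None = None             # network -> group label (optional)
    accessibility_bed: str | None = None
    accessibility_matrix: str | None = None
    accessibility_groups: str | None = None

    @property
    def f_grid(self):
        n = int(round((self.f_stop - self.f_start) / self.f_step)) + 1
        return np.round(np.linspace(self.f_start, self.f_stop, n), 10)

    def stage_seeds(self):
        ss = np.random.SeedSequence(self.seed)
        children = ss.spawn(len(_STAGES))
        return {name: int(c.generate_state(1)[0] % (2 ** 31))
                for name, c in zip(_STAGES, children)}

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "d_weights" in raw:
            raw["d_weights"] = tuple(raw["d_weights"])
        return cls(**raw)


def _sha256(path):
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_profile(config: RunConfig) -> dict:
    """Run the full framework; returns a dict of output paths."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = config.stage_seeds()
    f_grid = config.f_grid
    timings = {}
    outputs = {}

    def _out(name):
        return os.path.join(config.out_dir, name)

    t0 = time.time()
    panel = io.load_panel(config.networks_dir, pattern=config.pattern)
    logger.info("loaded %d networks from %s", len(panel), config.networks_dir)
    timings["load"] = time.time() - t0

    # --- damage curves + robustness ranking -------------------------------
    t0 = time.time()
    curves = []
    profiles = []
    for i, net in enumerate(panel):
        err = perturbation.simulate_error(
            net, f_grid=f_grid, n_reps=config.error_reps,
            seed=seeds["perturb"] + i)
        atk = perturbation.simulate_attack(
            net, f_grid=f_grid, strategy=config.attack_strategy)
        curves.extend([err, atk])
        profiles.append(robustness.profile_from_curves(err, atk))
    io.write_table(perturbation.curves_to_records(curves), _out("curves.tsv"))
    ranking = robustness.rank_networks(profiles, groups=config.groups)
    ranking.to_csv(_out("profiles.tsv"), sep="\t", index=False,
                   float_format="%.6g")
    outputs["curves"] = _out("curves.tsv")
    outputs["profiles"] = _out("profiles.tsv")
    timings["perturb"] = time.time() - t0

    # --- topological features ---------------------------------------------
    t0 = time.time()
    features = topology.features_table(panel, modularity_seed=seeds["modularity"])
    features.to_csv(_out("features.tsv"), sep="\t", float_format="%.6g")
    outputs["features"] = _out("features.tsv")
    timings["features"] = time.time() - t0

    # --- pairwise dissimilarity + dendrogram ------------------------------
    t0 = time.time()
    matrix, summary, linkage = pairwise_dissimilarity(
        panel, weights=config.d_weights)
    matrix.to_csv(_out("D.tsv"), sep="\t", float_format="%.6g")
    summary.to_csv(_out("D_summary.tsv"), sep="\t", float_format="%.6g")
    with open(_out("tree.nwk"), "w") as fh:
        fh.write(linkage_to_newick(linkage, list(matrix.index)) + "\n")
    outputs["dissimilarity"] = _out("D.tsv")
    outputs["tree"] = _out("tree.nwk")
    timings["dissimilarity"] = time.time() - t0

    # --- null ensembles ----------------------------------------------------
    t0 = time.time()
    d_er, d_ba = {}, {}
    zrows = []
    for i, net in enumerate(panel):
        name = net.graph["name"]
        er = null_models.ensemble_profile(
            net, "ER", n_reps=config.null_reps, seed=seeds["nullmodels"] + 2 * i,
            with_features=False, weights=config.d_weights)
        ba = null_models.ensemble_profile(
            net, "BA", n_reps=config.null_reps,
            seed=seeds["nullmodels"] + 2 * i + 1, weights=config.d_weights,
            modularity_seed=seeds["modularity"])
        d_er[name] = er.mean_d_to_real
        d_ba[name] = ba.mean_d_to_real
        for feat, row in ba.feature_stats.iterrows():
            zrows.append({"network": name, "feature": feat, **row.to_dict()})
    io.write_table(zrows, _out("zscores.tsv"))
    ens = pd.DataFrame({"D_ER": pd.Series(d_er), "D_BA": pd.Series(d_ba)})
    ens.index.name = "network"
    ens.to_csv(_out("ensembles.tsv"), sep="\t", float_format="%.6g")
    outputs["zscores"] = _out("zscores.tsv")
    outputs["ensembles"] = _out("ensembles.tsv")
    timings["nullmodels"] = time.time() - t0

    # --- predictive models -------------------------------------------------
    t0 = time.time()
    vuln = {p.network_name: p.vulnerability for p in profiles}
    fm = prediction.build_feature_matrix(features, d_er, d_ba, vuln)
    scan = prediction.univariate_scan(fm, k_folds=config.cv_folds,
                                      seed=seeds["predict"])
    rf = prediction.fit_random_forest(fm, n_trees=config.n_trees,
                                      k_folds=config.cv_folds,
                                      seed=seeds["predict"])
    scan["model"] = "linear"
    rf_row = pd.DataFrame([{"predictor": "random_forest_14_features",
                            "cv_mse": rf["cv_mse"], "slope": np.nan,
                            "intercept": np.nan, "model": "random_forest"}])
    pred = pd.concat([scan, rf_row], ignore_index=True)
    pred.to_csv(_out("prediction.tsv"), sep="\t", index=False,
                float_format="%.6g")
    rf["importances"].rename("importance").to_csv(
        _out("rf_importances.tsv"), sep="\t", float_format="%.6g")
    outputs["prediction"] = _out("prediction.tsv")
    outputs["rf_importances"] = _out("rf_importances.tsv")
    timings["predict"] = time.time() - t0

    # --- optional accessibility stage (failure does not abort) -------------
    acc_error = None
    if config.accessibility_bed:
        t0 = time.time()
        try:
            am = acc.load_accessibility(config.accessibility_bed,
                                        config.accessibility_matrix,
                                        config.accessibility_groups)
            rows = []
            for cls in acc.REGION_CLASSES:
                try:
                    lvl = acc.compare_group_accessibility(am, cls)
                    ent = acc.compare_group_entropy(am, cls)
                except ValueError:
                    continue
                rows.append({
                    "region_class": cls,
                    "accessibility_ranksum_p": lvl["p_value"],
                    "entropy_ranksum_p": ent["p_value"],
                    "entropy_direction": ent["direction"],
                })
            io.write_table(rows, _out("access_report.tsv"))
            outputs["access_report"] = _out("access_report.tsv")
        except Exception as exc:  # optional stage: report, do not abort
            acc_error = str(exc)
            logger.error("accessibility stage failed: %s", exc)
        timings["accessibility"] = time.time() - t0

    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stage_seeds": seeds,
        "conventions": dict(topology.CONVENTIONS),
        "giant_component": "largest weakly connected component",
        "input_hashes": {name: _sha256(path)
                         for name, path in panel.provenance.items()},
        "accessibility_error": acc_error,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "outputs": outputs,
    }
    with open(_out("manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = _out("manifest.json")
    return outputs
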