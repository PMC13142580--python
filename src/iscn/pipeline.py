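"""End-to-end orchestration of the individualized network analysis.

Stages (each reads and writes files in the run directory, never in-memory
state from another stage):

    preprocess -> network -> gradients + topology -> compare -> pls
    -> subtype -> normative

Every artifact is recorded in ``manifest.json`` with a SHA-256 checksum,
the per-stage seeds and the full configuration, so a rerun with the same
inputs reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import covnet, gradients, inference, normative, pls, preprocess, subtyping, topology
from .atlas import ACC_BASE_NAMES, dk_atlas_fixture, thickness_columns

log = logging.getLogger(__name__)

THK = thickness_columns()
METRICS = ("G1", "G2", "SPL", "CC")


@dataclass
class PipelineConfig:
    """Stage toggles and the main-analysis parameters.

    Defaults reproduce the primary analysis settings: sparsity 0.8 (top
    20% of row entries retained), diffusion anisotropy alpha 0.5, 1,000
    spin rotations, 5,000 bootstrap resamples, k = 2 subtypes.
    """

    sparsity: float = 0.8
    alpha: float = 0.5
    n_components: int = 10
    align_k: int = 2
    n_rot: int = 1000
    n_boot: int = 5000
    n_perm: int = 1000
    n_null: int = 100
    k: int = 2
    n_pc: int = 5
    residualize_sample: str = "pooled"
    stages: tuple = (
        "preprocess", "network", "gradients", "topology",
        "compare", "pls", "subtype", "normative",
    )
    seeds: dict = field(default_factory=lambda: {
        "spin": 11, "pls": 12, "subtype": 13, "null": 14,
    })

    @classmethod
    def demo(cls) -> "PipelineConfig":
        """Reduced resampling depths for the packaged demonstration run."""
        return cls(n_rot=200, n_boot=300, n_perm=200, n_null=20)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineRun:
    def __init__(self, config: PipelineConfig, out_dir: str | Path):
        self.cfg = config
        self.out = Path(out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.artifacts: dict = {}
        self.counts: dict = {}

    def path(self, name: str) -> Path:
        return self.out / name

    def write_frame(self, df: pd.DataFrame, name: str, index=True):
        p = self.path(name)
        df.to_csv(p, sep="\t" if name.endswith(".tsv") else ",", index=index)
        self.artifacts[name] = _sha256(p)

    def read_frame(self, name: str, index_col=0) -> pd.DataFrame:
        p = self.path(name)
        return pd.read_csv(p, sep="\t" if name.endswith(".tsv") else ",",
                           index_col=index_col)

    def write_manifest(self):
        manifest = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.cfg).items()},
            "artifacts": self.artifacts,
            "counts": self.counts,
        }
        p = self.path("manifest.json")
        p.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _individual_metrics(
    residualized: pd.DataFrame, cfg: PipelineConfig, template: gradients.GradientSet,
    ref: covnet.ControlReference,
) -> dict:
    """Per-subject aligned gradients and rescaled topology, subjects x 68 each."""
    n = len(residualized)
    out = {m: np.empty((n, len(THK))) for m in METRICS}
    X = residualized[THK].to_numpy(dtype=float)
    for i in range(n):
        net = covnet.individual_network(X[i], ref)
        sp = covnet.sparsify(net, cfg.sparsity)
        aff = gradients.affinity(sp)
        gs = gradients.diffusion_embedding(aff, alpha=cfg.alpha, n_components=cfg.n_components)
        aligned = gradients.procrustes_align(gs, template, k=cfg.align_k)
        out["G1"][i] = aligned.loadings[:, 0]
        out["G2"][i] = aligned.loadings[:, 1]
        adj = covnet.binary_adjacency(sp)
        out["CC"][i] = topology.minmax_rescale(topology.nodal_clustering(adj)).values
        out["SPL"][i] = topology.minmax_rescale(topology.nodal_shortest_path(adj)).values
    return out


def run_pipeline(
    config: PipelineConfig, cohort: pd.DataFrame, out_dir: str | Path
) -> Path:
    """Execute the configured stages on a cohort table; returns the run dir.

    A stage failure raises with the stage name; artifacts written so far
    stay on disk. Stage toggles skip stages (downstream stages needing
    their outputs will then fail with a clear missing-file error).
    """
    run = PipelineRun(config, out_dir)
    cfg = config
    atlas = dk_atlas_fixture()
    t_start = time.time()

    def stage_on(name):
        return name in cfg.stages

    try:
        if stage_on("preprocess"):
            coh = preprocess.impute_missing(cohort)
            run.counts["subjects_dropped"] = len(cohort) - len(coh)
            if coh["site"].nunique() > 1:
                coh, _ = preprocess.combat_harmonize(coh)
            run.write_frame(coh, "harmonized.csv", index=False)
            resid, _ = preprocess.residualize(coh, sample=cfg.residualize_sample)
            run.write_frame(resid, "residualized.csv", index=False)

        if stage_on("network"):
            resid = run.read_frame("residualized.csv", index_col=None)
            for name, grp in (("controls", 0), ("cases", 1)):
                cov = covnet.group_covariance(resid, group=grp)
                run.write_frame(
                    covnet.matrix_to_frame(cov, atlas.names), f"covariance_{name}.tsv"
                )
            ref = covnet.control_reference(resid)
            run.write_frame(
                pd.DataFrame({"mean": ref.mean, "sd": ref.sd}, index=list(atlas.names)),
                "control_reference.tsv",
            )

        if stage_on("gradients") or stage_on("topology"):
            resid = run.read_frame("residualized.csv", index_col=None)
            cov_ctr = covnet.RegionMatrix(
                run.read_frame("covariance_controls.tsv").to_numpy(), "group_covariance"
            )
            refs = run.read_frame("control_reference.tsv")
            ref = covnet.ControlReference(refs["mean"].to_numpy(), refs["sd"].to_numpy())
            sp_ctr = covnet.sparsify(cov_ctr, cfg.sparsity)
            template = gradients.diffusion_embedding(
                gradients.affinity(sp_ctr), alpha=cfg.alpha, n_components=cfg.n_components
            )
            template = gradients.fix_template_signs(template)
            run.write_frame(
                pd.DataFrame(
                    template.loadings, index=list(atlas.names),
                    columns=[f"G{i+1}" for i in range(template.loadings.shape[1])],
                ),
                "template_gradients.tsv",
            )
            ve = gradients.variance_explained(template, top=2)
            run.counts["template_variance_explained_G1_G2"] = [round(float(v), 4) for v in ve]

            adj_ctr = covnet.binary_adjacency(sp_ctr)
            tmpl_maps = {
                "G1": template.loadings[:, 0],
                "G2": template.loadings[:, 1],
            }
            for metric, fn in (("CC", topology.nodal_clustering),
                               ("SPL", topology.nodal_shortest_path)):
                raw = fn(adj_ctr)
                normed = topology.null_normalize(
                    raw, adj_ctr, n_null=cfg.n_null, seed=cfg.seeds["null"]
                )
                tmpl_maps[metric] = normed.values
            run.write_frame(
                pd.DataFrame(tmpl_maps, index=list(atlas.names)), "template_maps.tsv"
            )

            metrics = _individual_metrics(resid, cfg, template, ref)
            ids = resid["subject_id"]
            for m in METRICS:
                run.write_frame(
                    pd.DataFrame(metrics[m], index=ids, columns=list(atlas.names)),
                    f"metric_{m}.tsv",
                )

        if stage_on("compare"):
            resid = run.read_frame("residualized.csv", index_col=None)
            tmpl = run.read_frame("template_maps.tsv")
            sig_masks = {}
            spatial = {}
            for m in METRICS:
                feat = run.read_frame(f"metric_{m}.tsv").to_numpy()
                res = inference.fit_region_models(feat, resid, formula="base")
                run.write_frame(res.to_frame(atlas.names), f"case_control_{m}.tsv")
                sig_masks[m] = res.p_fdr < 0.05
                rep = inference.spatial_correlation_report(
                    res.cohens_d, {m: tmpl[m].to_numpy()}, atlas,
                    n_rot=cfg.n_rot, seed=cfg.seeds["spin"],
                )
                spatial[m] = rep.loc[m]
            run.write_frame(pd.DataFrame(spatial).T, "spatial_correlations.tsv")
            run.write_frame(
                pd.DataFrame(sig_masks, index=list(atlas.names)), "significant_features.tsv"
            )
            run.counts["n_significant_features"] = int(
                sum(int(v.sum()) for v in sig_masks.values())
            )

        if stage_on("pls"):
            coh = run.read_frame("harmonized.csv", index_col=None)
            panss_cols = [c for c in coh.columns if c.startswith("panss_")]
            if panss_cols:
                cases = coh["dx"] == 1
                have = cases & coh[panss_cols].notna().all(axis=1)
                Y = pls.factor_scores(coh.loc[have]).to_numpy()
                case_ids = coh.loc[coh["dx"] == 1, "subject_id"]
                for m in METRICS:
                    feat = run.read_frame(f"metric_{m}.tsv")
                    X = feat.loc[coh.loc[have, "subject_id"]].to_numpy()
                    res = pls.bootstrap_pls(
                        X, Y, n_boot=cfg.n_boot, seed=cfg.seeds["pls"],
                        n_perm=cfg.n_perm,
                    )
                    out = pd.DataFrame(
                        {
                            "salience_lv1": res.brain_saliences[:, 0],
                            "ci_lo": res.brain_ci[:, 0, 0],
                            "ci_hi": res.brain_ci[:, 0, 1],
                            "significant": res.significant_brain(0),
                        },
                        index=list(atlas.names),
                    )
                    run.write_frame(out, f"pls_{m}.tsv")
                    run.counts[f"pls_{m}_lv1_p_perm"] = float(res.lv_p_perm[0])
            else:
                log.info("pls: no PANSS items present, stage skipped")

        if stage_on("subtype"):
            sig = run.read_frame("significant_features.tsv")
            resid = run.read_frame("residualized.csv", index_col=None)
            cases = resid["dx"] == 1
            feats = {
                m: run.read_frame(f"metric_{m}.tsv").loc[resid.loc[cases, "subject_id"]].to_numpy()
                for m in METRICS
            }
            M, names = subtyping.build_feature_matrix(
                feats, {m: sig[m].to_numpy() for m in METRICS}
            )
            scores, var_frac = subtyping.pca_reduce(M, n_pc=cfg.n_pc)
            result = subtyping.kmeans_scan(scores, seed=cfg.seeds["subtype"], chosen_k=cfg.k)
            conc = subtyping.split_half_concordance(scores, k=cfg.k, seed=cfg.seeds["subtype"])
            acc = resid.loc[cases, [THK[i] for i in atlas.match(ACC_BASE_NAMES)]].mean(axis=1)
            labels = subtyping.anchor_subtype_labels(result.labels, acc.to_numpy())
            run.write_frame(
                pd.DataFrame(
                    {"subject_id": resid.loc[cases, "subject_id"],
                     "subtype": [f"S{l}" for l in labels]}
                ),
                "subtypes.csv", index=False,
            )
            run.write_frame(
                pd.DataFrame(
                    {"sse": list(result.sse_curve.values())},
                    index=list(result.sse_curve.keys()),
                ),
                "sse_curve.tsv",
            )
            run.counts["split_half_concordance"] = [round(c, 4) for c in conc]
            run.counts["pc_variance_fractions"] = [round(float(v), 4) for v in var_frac]
            run.counts["subtype_sizes"] = {
                "S1": int((labels == 1).sum()), "S2": int((labels == 2).sum())
            }

        if stage_on("normative"):
            coh = run.read_frame("harmonized.csv", index_col=None)
            model = normative.fit_normative(coh[coh["dx"] == 0])
            dev = normative.deviation_scores(model, coh)
            dev.insert(0, "subject_id", coh["subject_id"].to_numpy())
            run.write_frame(dev, "deviations.csv", index=False)
            het = {
                "controls": normative.heterogeneity(dev, coh["dx"] == 0),
            }
            sub = run.read_frame("subtypes.csv", index_col=None)
            merged = coh.merge(sub, on="subject_id", how="inner")
            dev_cases = dev.set_index("subject_id").loc[merged["subject_id"]]
            labels = (merged["subtype"] == "S2").to_numpy().astype(int) + 1
            for s in (1, 2):
                het[f"S{s}"] = normative.heterogeneity(
                    dev_cases.reset_index(drop=True), labels == s
                )
            run.counts["heterogeneity"] = {k: round(v, 4) for k, v in het.items()}
            tmpl = run.read_frame("template_maps.tsv")
            table, report = normative.subtype_profile_compare(
                dev_cases.reset_index(drop=True), labels,
                templates={m: tmpl[m].to_numpy() for m in METRICS},
                n_rot=cfg.n_rot, seed=cfg.seeds["spin"],
            )
            run.write_frame(table, "subtype_profile.tsv")
            run.write_frame(report, "subtype_spatial_correlations.tsv")
            strat = normative.stratified_compare(
                dev_cases.reset_index(drop=True), labels,
                merged, strata="duration",
            )
            run.counts["duration_bins"] = {
                f"[{lo},{hi}]": [n1, n2] for (lo, hi), (n1, n2, _) in strat.items()
            }

    except Exception as err:
        run.write_manifest()
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    run.counts["runtime_s"] = round(time.time() - t_start, 1)
    run.write_manifest()
    return run.out
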