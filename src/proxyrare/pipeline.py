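"""End-to-end pipeline: simulate -> predict -> define phenotypes -> associate
-> meta-analyze -> report.

Every stage logs its seed and output counts; rerunning with the same config
is bit-identical for the deterministic stages.  Stage failures halt with the
stage name attached.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from proxyrare import assoc, meta, phenotypes, postprocess, predict, simulate
from proxyrare.io import PipelineConfig, write_table

log = logging.getLogger("proxyrare")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _hash(arr) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run the full pipeline; returns the results directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, object] = {"seed": config.seed}

    stage = "simulate"
    try:
        spec = simulate.VariantSpec(
            n_common=config.n_common, n_rare=config.n_rare,
            n_ultra_rare=config.n_ultra_rare, n_genes=config.n_genes,
        )
        cfg = simulate.EffectConfig(
            n_causal_common=config.n_causal_common, beta_common=config.beta_common,
            n_causal_rare=config.n_causal_rare, beta_rare=config.beta_rare,
            n_causal_genes=config.n_causal_genes, beta_gene=config.beta_gene,
            diagnosis_sensitivity=config.diagnosis_sensitivity,
            imaging_fraction=config.imaging_fraction,
            steatosis_threshold=config.steatosis_threshold,
        )
        data = simulate.simulate_dataset(
            n=config.n_participants, spec=spec, cfg=cfg, seed=config.seed
        )
        simulate.write_dataset(data, out / "dataset")
        log.info("simulate: n=%d, variants=%d, genotype_hash=%s",
                 len(data.cohort), len(data.variants), _hash(data.genotypes))
        counts["n_participants"] = len(data.cohort)
        counts["n_variants"] = len(data.variants)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "predict"
    try:
        feature_cols = [n for n, _, _, _ in simulate.FEATURE_PANEL]
        eligible = predict.inclusion_filter(
            data.features, countable_columns=feature_cols,
            min_present=config.min_features_present,
        )
        imaging_ids = data.phenotypes.index[data.phenotypes["imaging"]]
        train_ids = eligible.intersection(imaging_ids)
        X_cols = feature_cols + ["time_gap_years", "age", "sex", "fasting_time_h"]
        X_train = data.features.loc[train_ids, X_cols]
        y_train = np.log(data.phenotypes.loc[train_ids, "true_pdff"].to_numpy())
        model = predict.NestedCVRegressor(
            k_outer=config.k_outer, k_inner=config.k_inner, seed=config.seed
        )
        model.fit(X_train, y_train,
                  time_gaps=data.features.loc[train_ids, "time_gap_years"].to_numpy())
        model.save(out / "model")
        # baseline-visit predictions for the whole eligible cohort
        table = model.predict_table(data.features.loc[eligible, X_cols], timepoint="baseline")
        write_table(table, out / "predictions.tsv")
        metrics = predict.evaluate_predictions(
            model.holdout_prediction_,
            data.phenotypes.loc[train_ids, "true_pdff"],
            steatosis_threshold=config.steatosis_threshold,
            n_bootstrap=200, seed=config.seed,
        )
        with open(out / "prediction_metrics.json", "w") as fh:
            json.dump({k: v for k, v in metrics.items()}, fh, indent=1)
        log.info("predict: %d models, holdout r=%.3f", model.n_models_, metrics["r"])
        counts["n_models"] = model.n_models_
        counts["holdout_r"] = metrics["r"]
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "define-phenotypes"
    try:
        pheno = data.phenotypes
        true_status = phenotypes.define_true_masld(
            pheno["diagnosed_masld"], pheno["cardiometabolic_ok"],
            pheno["exclusionary_dx"], overlap_ids=set(imaging_ids),
        )
        pred_pdff_pct = np.exp(table["prediction"])
        pred_status = phenotypes.assign_predicted_status(
            pred_pdff_pct, pheno["cardiometabolic_ok"],
            lower=config.predicted_control_max, upper=config.predicted_case_min,
        )
        write_table(true_status, out / "true_masld_status.tsv")
        write_table(pred_status, out / "predicted_masld_status.tsv")
        counts["true_cases"] = int((true_status["status"] == "case").sum())
        counts["predicted_cases"] = int((pred_status["status"] == "case").sum())
        log.info("phenotypes: %s true cases, %s predicted cases",
                 counts["true_cases"], counts["predicted_cases"])
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "assoc"
    try:
        G = data.genotypes.astype(float)
        cov_cols = ["age", "sex", "alcohol_g_week"] + [f"pc{i}" for i in range(1, 11)]
        covs = data.cohort[cov_cols].to_numpy(dtype=float)
        covs = np.column_stack([covs, data.features["bmi"].fillna(0).to_numpy()])
        chroms = data.variants["chrom"].to_numpy()

        keep_step1, step1_report = assoc.variant_qc(
            G, assoc.QCRules.step1(), list(data.variants["variant_id"])
        )
        counts["step1_kept"] = int(keep_step1.sum())
        offsets = None
        if config.run_loco and keep_step1.sum() >= 20:
            # predicted log-PDFF as the step-1 trait over the eligible cohort
            trait_full = pd.Series(np.nan, index=data.cohort.index)
            trait_full.loc[table.index] = table["prediction"]
            ok = trait_full.notna().to_numpy()
            loco = assoc.ridge_loco(
                G[np.ix_(ok, keep_step1)], chroms[keep_step1],
                trait_full.to_numpy()[ok], covariates=covs[ok],
                block_size=config.loco_block_size, seed=config.seed,
            )
            offsets = pd.DataFrame(np.nan, index=data.cohort.index, columns=loco.columns)
            offsets.loc[trait_full.index[ok], :] = loco.to_numpy()

        # analysis 1: common-variant replication scan against predicted PDFF (INT)
        keep_common, _ = assoc.variant_qc(
            G, assoc.QCRules.common_replication(), list(data.variants["variant_id"])
        )
        # analysis 2: rare/ultra-rare single variants against predicted PDFF (INT)
        keep_rare, _ = assoc.variant_qc(
            G, assoc.QCRules.rare_single_variant(), list(data.variants["variant_id"])
        )
        coding = data.variants["consequence"].isin(
            assoc.PTV_CONSEQUENCES | {"missense"}
        ).to_numpy()
        keep_rare &= coding
        trait_full = pd.Series(np.nan, index=data.cohort.index)
        trait_full.loc[table.index] = table["prediction"]
        ok = trait_full.notna().to_numpy()
        y_int = phenotypes.rank_inverse_normal(trait_full.to_numpy()[ok])
        off_vec = None
        scan = assoc.association_scan(
            G[np.ix_(ok, keep_rare)], y_int, covariates=covs[ok],
            variant_ids=list(data.variants.loc[keep_rare, "variant_id"]),
            trait_name="predicted_pdff",
        )
        write_table(scan, out / "single_variant_predicted_pdff.tsv")
        counts["rare_variants_tested"] = len(scan)
        scan_common = assoc.association_scan(
            G[np.ix_(ok, keep_common)], y_int, covariates=covs[ok],
            variant_ids=list(data.variants.loc[keep_common, "variant_id"]),
            trait_name="predicted_pdff",
        )
        write_table(scan_common, out / "common_variant_predicted_pdff.tsv")
        counts["common_variants_tested"] = len(scan_common)

        # true-PDFF scan over the imaging subsample
        img = pheno["imaging"].to_numpy()
        y_true_int = phenotypes.rank_inverse_normal(
            np.log(pheno.loc[img, "true_pdff"].to_numpy())
        )
        scan_true = assoc.association_scan(
            G[np.ix_(img, keep_rare)], y_true_int, covariates=covs[img],
            variant_ids=list(data.variants.loc[keep_rare, "variant_id"]),
            trait_name="true_pdff",
        )
        write_table(scan_true, out / "single_variant_true_pdff.tsv")

        # analysis 3: gene-level tests of ultra-rare PTV + deleterious missense
        masks, dropped = assoc.build_masks(
            data.variants.assign(variant_id=data.variants["variant_id"]), G,
            min_cumulative_mac=config.gene_min_cmac,
        )
        vindex = {v: j for j, v in enumerate(data.variants["variant_id"])}
        gene_records = []
        for mask in masks:
            for method in ("burden", "skat", "skato", "acat"):
                rec = assoc.gene_test(
                    mask, G[ok], vindex, y_int, covariates=covs[ok],
                    method=method, trait_name="predicted_pdff",
                    min_cumulative_mac=config.gene_min_cmac,
                )
                gene_records.append(rec.to_dict())
        gene_df = pd.DataFrame(gene_records)
        write_table(gene_df, out / "gene_level_predicted_pdff.tsv", index=False)
        counts["genes_tested"] = len(masks)
        counts["genes_dropped_cmac"] = len(dropped)
        log.info("assoc: %d rare variants, %d gene masks (%d dropped)",
                 len(scan), len(masks), len(dropped))
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "meta"
    try:
        # two "cohorts": true-PDFF imaging subsample and predicted-PDFF cohort
        meta_records = []
        for vid in scan.index:
            recs = []
            for name, df, n_eff in (
                ("true_pdff", scan_true, int(img.sum())),
                ("predicted_pdff", scan, int(ok.sum())),
            ):
                row = df.loc[vid]
                if np.isnan(row["p"]):
                    continue
                recs.append(meta.CohortResult(
                    cohort=name, z=float(row["z"]), n_eff=n_eff,
                    beta=float(row["beta"]), se=float(row["se"]),
                ))
            if recs:
                meta_records.append(meta.stouffer_meta(recs, target=vid))
        meta_df = meta.meta_table(meta_records)
        write_table(meta_df, out / "meta_single_variant.tsv", index=False)
        counts["meta_targets"] = len(meta_df)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    stage = "report"
    try:
        lam = postprocess.genomic_inflation(scan["p"].dropna().to_numpy())
        thresholds = postprocess.significance_thresholds(max(len(masks), 1))
        known = pd.DataFrame(
            {"direction": [np.sign(b) or 1 for b in data.truth.causal_variants.values()]},
            index=pd.Index(list(data.truth.causal_variants), name="variant_id"),
        )
        all_scans = pd.concat([scan_common, scan[~scan.index.isin(scan_common.index)]])
        rep = postprocess.replication_score(all_scans, known)
        report = {
            "lambda_gc": lam,
            "gene_bonferroni": thresholds.gene_bonferroni,
            "replication": {k: v for k, v in rep.items() if k not in ("table",)},
            "counts": counts,
        }
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, default=str)
        log.info("report: lambda_GC=%.3f", lam)
    except Exception as e:  # noqa: BLE001
        raise StageError(stage, e) from e

    return out
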