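"""End-to-end orchestration of the resistance-discovery pipeline.

``run_pipeline`` executes, on synthetic inputs generated from a single
config: signature derivation (patient cohort and cell-line panel),
single-cell CNV scoring and subcluster classification, spatial projection,
the differential-IC50 drug screen with BBB filter, ZIP synergy with optimal
combination selection, and the assay statistics (ELDA comparison, survival
log-rank, H-score examples). Every stage is a pure function of (config,
seed); the report is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import assays, cnv, io, pharm, signature, spatial, subclusters, synthetic

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class PipelineConfig:
    """All pipeline inputs and thresholds, validated in one pass."""

    seed: int = 0
    # synthetic input sizes
    n_samples: int = 200
    n_genes: int = 600
    n_lines: int = 20
    n_drugs: int = 30
    n_cells: int = 400
    n_spots: int = 200
    # stage thresholds
    survival_rule: str = "median"
    survival_q: float = 0.5
    de_method: str = "welch"
    lfc_min: float = 0.5
    p_max: float = 0.05
    alpha: float = 0.05
    window: int = 51
    noise_filter: float = 0.2
    clip: float = 1.0
    min_frac: float = 0.25
    min_inhibition: float = 50.0
    synergy_magnitude: float = 0.2

    def validate(self) -> None:
        errors = []
        if self.n_samples < 8:
            errors.append("n_samples must be >= 8")
        if self.n_genes < 50:
            errors.append("n_genes must be >= 50")
        if self.n_lines < 4:
            errors.append("n_lines must be >= 4")
        if self.n_drugs < 1:
            errors.append("n_drugs must be >= 1")
        if self.n_cells < 20:
            errors.append("n_cells must be >= 20")
        if self.n_spots < 10:
            errors.append("n_spots must be >= 10")
        if self.survival_rule not in ("median", "quantile"):
            errors.append("survival_rule must be 'median' or 'quantile'")
        if not (0.0 < self.survival_q < 1.0):
            errors.append("survival_q must lie in (0, 1)")
        if self.de_method not in ("welch", "moderated"):
            errors.append("de_method must be 'welch' or 'moderated'")
        if self.lfc_min <= 0:
            errors.append("lfc_min must be positive")
        if not (0.0 < self.p_max <= 1.0):
            errors.append("p_max must lie in (0, 1]")
        if not (0.0 <= self.alpha <= 1.0):
            errors.append("alpha must lie in [0, 1]")
        if self.window < 1:
            errors.append("window must be >= 1")
        if not (0.0 <= self.noise_filter <= self.clip):
            errors.append("noise_filter must lie in [0, clip]")
        if self.clip <= 0:
            errors.append("clip must be positive")
        if not (0.0 <= self.min_frac <= 1.0):
            errors.append("min_frac must lie in [0, 1]")
        if not (0.0 <= self.min_inhibition <= 100.0):
            errors.append("min_inhibition must lie in [0, 100]")
        if errors:
            raise ValueError("invalid config: " + "; ".join(errors))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"invalid config: unknown keys {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg


def _seeds(master: int) -> dict:
    ss = np.random.SeedSequence(master)
    names = ["truth", "bulk", "panel", "sc", "spatial", "dose", "dilution_a",
             "dilution_b"]
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31)) for n, c in
            zip(names, children)}


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run every stage on synthetic inputs; optionally write the report bundle."""
    config.validate()
    seeds = _seeds(config.seed)
    truth = synthetic.default_truth(
        n_genes=config.n_genes, n_spots=config.n_spots,
        n_drugs=config.n_drugs, synergy_magnitude=config.synergy_magnitude,
        seed=seeds["truth"])
    results: dict = {}

    # --- stage 1: dual-cohort signature derivation -------------------------
    bulk_expr, cohort = synthetic.gen_bulk_cohort(
        config.n_samples, config.n_genes, truth, seed=seeds["bulk"])
    labeled = signature.stratify_by_survival(cohort, rule=config.survival_rule,
                                             q=config.survival_q)
    de_patients = signature.differential_expression(
        io.ExpressionMatrix(bulk_expr.data[labeled.index], scale="lognorm"),
        labeled["group"], method=config.de_method)
    sig_patients = signature.volcano_filter(
        de_patients, config.lfc_min, config.p_max, provenance="patients")

    panel_expr, apoptosis, viability = synthetic.gen_cellline_panel(
        config.n_lines, config.n_genes, config.n_drugs, truth,
        seed=seeds["panel"])
    apop_labels = signature.stratify_by_apoptosis(apoptosis, alpha=config.alpha)
    de_lines = signature.differential_expression(
        panel_expr, apop_labels["label"], method=config.de_method)
    sig_lines = signature.volcano_filter(
        de_lines, config.lfc_min, config.p_max, provenance="cell_lines")

    common = signature.intersect_signatures(sig_patients, sig_lines)
    driver = truth.driver_gene if truth.driver_gene in common else \
        (common.genes[0] if common.genes else None)
    results["signature"] = {
        "n_patient_genes": len(sig_patients),
        "n_line_genes": len(sig_lines),
        "n_common": len(common),
        "common_genes": list(common.genes),
        "driver_candidate": driver,
        "driver_recovered": truth.driver_gene in common,
    }
    results["de_patients"] = de_patients.round(10)

    # survival comparison between the stratified groups
    surv = assays.km_logrank(labeled["survival_time"],
                             np.ones(len(labeled), dtype=int),
                             labeled["group"])
    results["survival"] = {"logrank_chi2": surv.chi2, "logrank_p": surv.p}

    # --- stage 2: single-cell CNV and subclusters --------------------------
    counts, cells, positions = synthetic.gen_sc_dataset(
        config.n_cells, config.n_genes, truth, seed=seeds["sc"])
    ref_cells = cells.index[cells["is_reference"]]
    profiles = cnv.infer_cnv_profile(counts, ref_cells, positions,
                                     window=config.window,
                                     noise_filter=config.noise_filter,
                                     clip=config.clip)
    scores = cnv.cnv_score(profiles)
    calls = cnv.classify_cnv(scores, scores.loc[ref_cells])
    results["cnv"] = {
        "max_abs_entry": float(np.abs(profiles.to_numpy()).max()),
        "frac_tumor_cnv_pos": float(
            (calls.loc[cells.index[cells["is_tumor"]], "cnv_class"] == "CNV+")
            .mean()),
        "frac_reference_cnv_pos": float(
            (calls.loc[ref_cells, "cnv_class"] == "CNV+").mean()),
    }

    tumor_cells = cells.index[cells["is_tumor"]]
    tumor_expr = io.ExpressionMatrix(counts.data[tumor_cells], scale="counts")
    tumor_clusters = cells.loc[tumor_cells, "cluster"]
    driver_means = subclusters.cluster_mean_expression(
        tumor_expr, tumor_clusters, truth.driver_gene)
    msn_groups = subclusters.mean_sem_grouping(driver_means)
    sig_for_sc = common if common.genes else sig_patients
    sig_scores = subclusters.signature_score_clusters(
        tumor_expr, tumor_clusters, sig_for_sc)
    resist_groups = subclusters.mean_sem_grouping(
        sig_scores, high_label="resistant", low_label="sensitive")
    groups = subclusters.intersect_groups(msn_groups, resist_groups)
    results["subclusters"] = {
        "driver_means": driver_means.round(10),
        "msn_groups": msn_groups,
        "resist_groups": resist_groups,
        "high_msn_resistant": sorted(groups["high_msn_resistant"]),
        "low_msn_sensitive": sorted(groups["low_msn_sensitive"]),
        "planted_cluster_recovered":
            truth.resistant_cluster in groups["high_msn_resistant"],
    }

    # --- stage 3: spatial projection ---------------------------------------
    spatial_ds = synthetic.gen_spatial_dataset(config.n_spots, truth,
                                               seed=seeds["spatial"])
    hvgs = spatial.select_shared_hvgs(tumor_expr, spatial_ds.expression,
                                      n_top=min(2000, config.n_genes))
    spot_scores = spatial.transfer_scores(tumor_expr, tumor_clusters,
                                          spatial_ds, genes=hvgs, per_spot=True)
    region_groups = {
        "resistant": sorted(groups["high_msn_resistant"]) or
        [truth.resistant_cluster],
        "sensitive": sorted(groups["low_msn_sensitive"]) or
        [c for c in truth.tumor_clusters if c != truth.resistant_cluster],
    }
    enrich = spatial.region_enrichment(spot_scores, spatial_ds.regions,
                                       region_groups)
    top2 = list(enrich["z"]["resistant"].nlargest(2).index)
    results["spatial"] = {
        "region_enrichment_z": enrich["z"].round(10),
        "resistant_top2_regions": top2,
        "mp_pseu_top2": set(top2) == {"MP", "PSEU"},
    }

    # --- stage 4: drug screen and synergy ----------------------------------
    ic50_grid = {}
    for drug, grid in viability.items():
        per_line = {}
        for line in grid.index:
            doses = grid.columns.to_numpy(dtype=float)
            est, _curve = pharm.ic50_from_viability(doses, grid.loc[line])
            per_line[line] = np.nan if est is None else est
        ic50_grid[drug] = per_line
    ic50_table = pd.DataFrame(ic50_grid)
    driver_expr = panel_expr.data.loc[truth.driver_gene]
    screen = pharm.differential_ic50_screen(ic50_table, driver_expr,
                                            alpha=config.alpha)
    bbb_flags = pd.Series({d: d in truth.bbb_drugs for d in ic50_table.columns})
    bbb_hits = pharm.filter_bbb(screen, bbb_flags)
    results["screen"] = {
        "n_drugs_tested": int(len(screen)),
        "n_sensitive": int(screen["msn_sensitive"].sum()),
        "sensitive_drugs": sorted(screen.index[screen["msn_sensitive"]]),
        "bbb_hits": sorted(bbb_hits.index),
    }

    dose_matrix = synthetic.gen_dose_matrix(
        synergy_magnitude=truth.synergy_magnitude, noise_sd=2.0,
        seed=seeds["dose"])
    synergy = pharm.zip_delta(dose_matrix)
    combo = pharm.select_optimal_combo(synergy, dose_matrix,
                                       min_inhibition=config.min_inhibition)
    results["synergy"] = {
        "summary_score": round(synergy.summary, 10),
        "optimal_combo": combo,
    }

    # --- stage 5: assay statistics -----------------------------------------
    dil_a = synthetic.gen_dilution_assay(truth.stem_frequency["control"],
                                         seed=seeds["dilution_a"])
    dil_b = synthetic.gen_dilution_assay(truth.stem_frequency["knockdown"],
                                         seed=seeds["dilution_b"])
    est_a, est_b = assays.elda_fit(dil_a), assays.elda_fit(dil_b)
    comparison = assays.elda_compare(dil_a, dil_b)
    results["elda"] = {
        "control": dataclasses.asdict(est_a),
        "knockdown": dataclasses.asdict(est_b),
        "comparison": comparison,
    }
    results["h_score_example"] = assays.h_score(0.2, 0.3, 0.4)

    if outdir is not None:
        io.write_report(results, outdir, config=dataclasses.asdict(config),
                        seed=config.seed)
    return results
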