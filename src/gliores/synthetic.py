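"""Synthetic-data generators with planted, recorded ground truth.

Every pipeline input — treated bulk cohort, cell-line panel, single-cell counts
with copy-number-bearing tumor clusters, spatial spot mixtures, dose-response
grids and limiting-dilution plates — can be generated here so the downstream
stages are testable without any external cohort. Each generator is a pure
function of its parameters and a seed, and the planted effects are recorded in
a :class:`SyntheticTruth` so recovery tests can check against ground truth.

The distributional choices (log-normal bulk baselines, exponential survival,
negative-binomial counts, additive Gaussian noise on inhibition percentages,
single-hit Poisson dilution wells) are desk-scale surrogates for real data,
not estimates from any cohort; see docs/methods.md for what they do and do
not emulate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

MES_MARKERS = ("CD44", "YKL40", "TIMP1", "TGFB1")
PN_MARKERS = ("OLIG2", "DLL3", "SOX2", "ASCL1")
REGIONS = ("CT", "IT", "LE", "MP", "PSEU")

THERAPIES = ("chemoradiotherapy", "radiotherapy_only", "chemotherapy_only", "other")


@dataclasses.dataclass
class SyntheticTruth:
    """Planted ground truth shared across all generators.

    resistance_genes maps gene id -> planted log2 effect (resistant vs
    sensitive); cnv_segments are (chromosome, start gene index, end gene
    index, log2 gain) in position order, half-open; spot_mixtures rows are
    per-spot cluster weights summing to 1.
    """

    resistance_genes: dict
    driver_gene: str
    cnv_segments: list
    cluster_profiles: pd.DataFrame  # clusters x genes, linear-scale means
    spot_mixtures: pd.DataFrame     # spots x clusters
    synergy_magnitude: float
    stem_frequency: dict            # group -> frequency in (0, 1]
    seed: int
    reference_clusters: tuple = ()
    tumor_clusters: tuple = ()
    resistant_cluster: str = ""
    spot_regions: pd.Series | None = None
    driver_sensitive_drugs: tuple = ()
    bbb_drugs: tuple = ()
    marker_genes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        effects = np.asarray(list(self.resistance_genes.values()), dtype=float)
        if effects.size and not np.isfinite(effects).all():
            raise ValueError("resistance-gene effect sizes must be finite")
        if self.driver_gene not in self.resistance_genes:
            raise ValueError("driver gene must carry a planted effect")
        w = self.spot_mixtures.to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("spot mixture weights must be nonnegative")
        if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("spot mixture weights must sum to 1 per spot")
        for group, f in self.stem_frequency.items():
            if not (0.0 < f <= 1.0):
                raise ValueError(f"stem frequency for {group!r} outside (0, 1]: {f}")

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = dataclasses.asdict(self)
        payload["cluster_profiles"] = self.cluster_profiles.to_dict()
        payload["spot_mixtures"] = self.spot_mixtures.to_dict()
        payload["spot_regions"] = (None if self.spot_regions is None
                                   else self.spot_regions.to_dict())
        path.write_text(json.dumps(payload, indent=1, sort_keys=True, default=list))
        return path


def gene_universe(n_genes: int) -> list[str]:
    """Gene ids shared by every generator: driver, subtype markers, filler."""
    named = ["MSN", *MES_MARKERS, *PN_MARKERS]
    if n_genes < len(named):
        raise ValueError(f"n_genes must be >= {len(named)}")
    filler = [f"G{i:04d}" for i in range(n_genes - len(named))]
    return named + filler


def default_truth(n_genes: int = 600, n_resistance_genes: int = 12,
                  effect_size: float = 1.0, n_tumor_clusters: int = 4,
                  n_spots: int = 200, n_drugs: int = 30,
                  synergy_magnitude: float = 0.2,
                  seed: int = 0) -> SyntheticTruth:
    """Build the default planted truth used by the end-to-end pipeline.

    The driver gene ("MSN" in the synthetic namespace) is always one of the
    planted resistance genes. One tumor cluster is double-positive (high
    driver and enriched for the whole resistance signature); spots dominated
    by that cluster are placed in the MP/PSEU regions.
    """
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    filler = [g for g in genes if g.startswith("G")]
    others = list(rng.choice(filler, size=n_resistance_genes - 1, replace=False))
    resistance_genes = {"MSN": float(effect_size)}
    resistance_genes.update({g: float(effect_size) for g in others})

    # Gene blocks with copy-number shifts, in position order (see gen_sc_dataset
    # for the deterministic chromosome layout: 6 equal blocks chr1..chr6).
    per_chrom = n_genes // 6
    gain_len = min(200, max(20, per_chrom - 10))
    cnv_segments = [
        ("chr2", per_chrom + 5, per_chrom + 5 + gain_len, 0.58),   # ~1.5x gain
        ("chr5", 4 * per_chrom + 5, 4 * per_chrom + 5 + gain_len // 2, -0.58),
    ]

    ref_clusters = ("NT1", "NT2")
    tumor = tuple(f"T{i + 1}" for i in range(n_tumor_clusters))
    clusters = list(ref_clusters) + list(tumor)
    base = rng.lognormal(mean=1.0, sigma=0.6, size=n_genes)
    profiles = pd.DataFrame(
        np.tile(base, (len(clusters), 1)) *
        rng.lognormal(mean=0.0, sigma=0.25, size=(len(clusters), n_genes)),
        index=clusters, columns=genes)
    # Double-positive tumor cluster: driver and full signature shifted up.
    resistant_cluster = tumor[0]
    for g, eff in resistance_genes.items():
        profiles.loc[resistant_cluster, g] *= 2.0 ** (eff + 1.0)
        for other in tumor[1:]:
            profiles.loc[other, g] *= 2.0 ** rng.normal(0.0, 0.1)
    # Subtype markers: tumor clusters split MES-like vs PN-like.
    for c in tumor:
        mes_like = c == resistant_cluster
        for g in MES_MARKERS:
            profiles.loc[c, g] *= 4.0 if mes_like else 0.5
        for g in PN_MARKERS:
            profiles.loc[c, g] *= 0.5 if mes_like else 4.0

    # Spot mixtures: each spot dominated by one cluster plus Dirichlet dust.
    dominant = rng.choice(clusters, size=n_spots)
    alpha = np.full(len(clusters), 0.3)
    w = rng.dirichlet(alpha, size=n_spots) * 0.15
    mix = np.zeros((n_spots, len(clusters)))
    for i, d in enumerate(dominant):
        mix[i] = w[i]
        mix[i, clusters.index(d)] += 0.85
    mix /= mix.sum(axis=1, keepdims=True)
    spot_mixtures = pd.DataFrame(mix, index=[f"spot{i:04d}" for i in range(n_spots)],
                                 columns=clusters)
    # Regions: resistant-cluster spots sit in MP/PSEU, the rest in CT/IT/LE.
    regions = []
    for d in dominant:
        if d == resistant_cluster:
            regions.append(rng.choice(["MP", "PSEU"]))
        else:
            regions.append(rng.choice(["CT", "IT", "LE"]))
    spot_regions = pd.Series(regions, index=spot_mixtures.index, name="region")

    # Driver-sensitive drugs spread across the panel; exactly one of them
    # (the GNE-317 analog) crosses the blood-brain barrier.
    if n_drugs < 4:
        raise ValueError("n_drugs must be >= 4")
    sens_idx = sorted({3 % n_drugs, (n_drugs // 2) % n_drugs,
                       (n_drugs - 6) % n_drugs})
    sensitive = tuple(f"drug{i:03d}" for i in sens_idx)
    non_sens = [i for i in range(n_drugs) if i not in sens_idx]
    bbb = tuple(f"drug{i:03d}" for i in
                sorted([sens_idx[min(1, len(sens_idx) - 1)]] + non_sens[:2]))

    return SyntheticTruth(
        resistance_genes=resistance_genes,
        driver_gene="MSN",
        cnv_segments=cnv_segments,
        cluster_profiles=profiles,
        spot_mixtures=spot_mixtures,
        synergy_magnitude=float(synergy_magnitude),
        stem_frequency={"control": 0.1, "knockdown": 0.02},
        seed=int(seed),
        reference_clusters=ref_clusters,
        tumor_clusters=tumor,
        resistant_cluster=resistant_cluster,
        spot_regions=spot_regions,
        driver_sensitive_drugs=sensitive,
        bbb_drugs=bbb,
        marker_genes={"MES": list(MES_MARKERS), "PN": list(PN_MARKERS)},
    )


# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------

def gen_bulk_cohort(n_samples: int, n_genes: int, truth: SyntheticTruth,
                    seed: int, sigma: float = 0.3,
                    median_survival: tuple[float, float] = (4.0, 40.0),
                    frac_crt_dead: float = 0.7) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Generate a treated cohort with survival-linked expression of planted genes.

    Dead, chemoradiotherapy-treated samples are split 50/50 into resistant /
    sensitive; resistant samples draw shorter exponential survival (group
    median ``median_survival[0]`` months vs ``median_survival[1]``) and carry
    the planted log2 effects on top of a log-scale Gaussian baseline
    (log-normal expression). Returns a log-scale matrix tagged "lognorm" and
    the clinical table.
    """
    if n_samples < 8:
        raise ValueError("n_samples must be >= 8")
    genes = gene_universe(n_genes)
    missing = [g for g in truth.resistance_genes if g not in genes]
    if missing:
        raise ValueError(f"effect genes not in gene universe: {missing[:5]}")
    rng = np.random.default_rng(seed)
    samples = [f"S{i:04d}" for i in range(n_samples)]

    n_crt_dead = max(4, int(round(frac_crt_dead * n_samples)))
    status = np.array(["dead"] * n_crt_dead +
                      list(rng.choice(["dead", "alive"], size=n_samples - n_crt_dead)))
    therapy = np.array(["chemoradiotherapy"] * n_crt_dead +
                       list(rng.choice(THERAPIES, size=n_samples - n_crt_dead)))
    group = np.array([""] * n_samples, dtype=object)
    half = n_crt_dead // 2
    group[:half] = "resistant"
    group[half:n_crt_dead] = "sensitive"

    rate_res = np.log(2.0) / median_survival[0]
    rate_sen = np.log(2.0) / median_survival[1]
    surv = rng.exponential(1.0 / rate_sen, size=n_samples)
    surv[group == "resistant"] = rng.exponential(1.0 / rate_res, size=half)
    surv = np.maximum(surv, 0.05)

    baseline = rng.normal(7.0, 1.0, size=n_genes)
    expr = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_samples))
    expr_df = pd.DataFrame(expr, index=genes, columns=samples)
    res_cols = [s for s, g in zip(samples, group) if g == "resistant"]
    for g, eff in truth.resistance_genes.items():
        expr_df.loc[g, res_cols] += eff
    expr_df = expr_df.clip(lower=0.0)

    cohort = pd.DataFrame({
        "sample": samples,
        "survival_time": surv,
        "vital_status": status,
        "therapy": therapy,
        "group": group,
    }).set_index("sample")
    return ExpressionMatrix(expr_df, scale="lognorm"), cohort


# ---------------------------------------------------------------------------
# Cell-line panel
# ---------------------------------------------------------------------------

def gen_cellline_panel(n_lines: int, n_genes: int, n_drugs: int,
                       truth: SyntheticTruth, seed: int, sigma: float = 0.3,
                       apoptosis_coupling: float = 1.0, ic50_ratio: float = 4.0,
                       ic50_sigma_log: float = 0.1, n_replicates: int = 3,
                       doses: tuple = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
                       viability_noise: float = 2.0,
                       ) -> tuple[ExpressionMatrix, pd.DataFrame, dict]:
    """Generate a cell-line panel: expression, apoptosis table, per-drug viability.

    Half the lines are high-driver (the planted signature, driver included, is
    shifted up); high-driver lines show blunted treatment-induced apoptosis
    (scaled by ``apoptosis_coupling``; 0 decouples apoptosis from the driver)
    and an ``ic50_ratio``-fold lower IC50 for the planted driver-sensitive
    drugs. Viability tables are log-logistic responses in percent plus
    Gaussian noise, anchored at ~100% at dose 0.
    """
    if n_lines < 4:
        raise ValueError("n_lines must be >= 4 (2 per group)")
    rng = np.random.default_rng(seed)
    genes = gene_universe(n_genes)
    lines = [f"L{i:02d}" for i in range(n_lines)]
    half = n_lines // 2
    high = set(lines[:half])

    baseline = rng.normal(7.0, 1.0, size=n_genes)
    expr = baseline[:, None] + rng.normal(0.0, sigma, size=(n_genes, n_lines))
    expr_df = pd.DataFrame(expr, index=genes, columns=lines)
    for g, eff in truth.resistance_genes.items():
        expr_df.loc[g, list(high)] += eff
    expr_df = expr_df.clip(lower=0.0)

    rows = []
    for line in lines:
        resistant = line in high
        for cond in ("control", "RT", "TMZ"):
            if cond == "control":
                mean = 0.05
            else:
                # coupling=1: high-driver lines stay near control (resistant);
                # coupling=0: apoptosis independent of the driver.
                mean = 0.05 + 0.40 * (1.0 - apoptosis_coupling * resistant)
            for rep in range(n_replicates):
                frac = float(np.clip(rng.normal(mean, 0.02), 0.0, 1.0))
                rows.append((line, cond, rep, frac))
    apoptosis = pd.DataFrame(rows, columns=["line", "condition", "replicate",
                                            "apoptosis_fraction"])

    drugs = [f"drug{i:03d}" for i in range(n_drugs)]
    doses = np.asarray(doses, dtype=float)
    if doses.min() != 0.0:
        raise ValueError("dose grid must include 0")
    viability: dict[str, pd.DataFrame] = {}
    for drug in drugs:
        base_ic50 = float(rng.lognormal(np.log(4.0), 0.3))
        h = float(rng.uniform(1.5, 2.5))
        grid = np.empty((n_lines, doses.size))
        for i, line in enumerate(lines):
            m = base_ic50 * float(rng.lognormal(0.0, ic50_sigma_log))
            if drug in truth.driver_sensitive_drugs and line in high:
                m /= ic50_ratio
            with np.errstate(divide="ignore"):
                y = 100.0 * (1.0 - doses ** h / (doses ** h + m ** h))
            y[doses == 0] = 100.0
            grid[i] = np.clip(y + rng.normal(0.0, viability_noise, size=doses.size),
                              0.0, 120.0)
            grid[i, doses == 0] = np.clip(
                100.0 + rng.normal(0.0, viability_noise), 90.0, 110.0)
        viability[drug] = pd.DataFrame(grid, index=lines, columns=doses)
    return ExpressionMatrix(expr_df, scale="lognorm"), apoptosis, viability


# ---------------------------------------------------------------------------
# Single-cell dataset
# ---------------------------------------------------------------------------

def gen_positions(genes: list[str], n_chroms: int = 6) -> pd.DataFrame:
    """Deterministic gene layout: contiguous equal blocks on chr1..chrN."""
    n = len(genes)
    per = int(np.ceil(n / n_chroms))
    rows = []
    for i, g in enumerate(genes):
        chrom = f"chr{i // per + 1}"
        start = (i % per) * 10_000
        rows.append((chrom, start, start + 1_000, g))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


def gen_sc_dataset(n_cells: int, n_genes: int, truth: SyntheticTruth, seed: int,
                   dispersion: float = 0.3, library_size: float = 3000.0,
                   ) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate single-cell counts with CNV-bearing tumor clusters.

    Counts are negative binomial around cluster profile means (gamma-Poisson
    with shape 1/``dispersion``); tumor-cluster cells carry multiplicative
    2**gain shifts on the contiguous position-ordered gene blocks recorded in
    ``truth.cnv_segments``. Returns (counts, cell annotation, position table).
    """
    clusters = list(truth.cluster_profiles.index)
    if len(clusters) < 2 or not truth.reference_clusters:
        raise ValueError("need >=2 clusters with >=1 designated reference cluster")
    genes = list(truth.cluster_profiles.columns)
    if len(genes) != n_genes:
        raise ValueError("n_genes must match truth.cluster_profiles")
    positions = gen_positions(genes)
    ordered = positions["gene"].tolist()
    for chrom, lo, hi, _gain in truth.cnv_segments:
        if not (0 <= lo < hi <= n_genes):
            raise ValueError(f"cnv segment indices out of range: {(lo, hi)}")
        seg_chroms = set(positions.iloc[lo:hi]["chrom"])
        if seg_chroms != {chrom}:
            raise ValueError(f"cnv segment {(chrom, lo, hi)} crosses chromosomes")

    rng = np.random.default_rng(seed)
    assign = rng.choice(clusters, size=n_cells)
    cells = [f"C{i:05d}" for i in range(n_cells)]
    counts = np.empty((n_cells, n_genes), dtype=np.int64)
    order_idx = {g: i for i, g in enumerate(ordered)}
    shape = 1.0 / dispersion
    for ci, cluster in enumerate(assign):
        mu = truth.cluster_profiles.loc[cluster, ordered].to_numpy(dtype=float).copy()
        if cluster in truth.tumor_clusters:
            for _chrom, lo, hi, gain in truth.cnv_segments:
                mu[lo:hi] *= 2.0 ** gain
        mu = mu / mu.sum() * library_size
        lam = rng.gamma(shape, mu / shape)
        counts[ci] = rng.poisson(lam)
    counts_df = pd.DataFrame(counts.T, index=ordered, columns=cells)
    annotation = pd.DataFrame({
        "cell": cells,
        "cluster": assign,
        "is_reference": [c in truth.reference_clusters for c in assign],
        "is_tumor": [c in truth.tumor_clusters for c in assign],
    }).set_index("cell")
    return ExpressionMatrix(counts_df, scale="counts"), annotation, positions


# ---------------------------------------------------------------------------
# Spatial dataset
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpatialDataset:
    """Spots x genes expression with coordinates, spot clusters and regions."""

    expression: pd.DataFrame       # spots x genes
    coordinates: pd.DataFrame      # spots x (x, y)
    spot_clusters: pd.Series       # spot -> spatial cluster id
    regions: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.expression.to_numpy() < 0).any():
            raise ValueError("spatial expression must be nonnegative")
        if not self.spot_clusters.index.equals(self.expression.index):
            raise ValueError("every spot must carry a cluster label")
        if self.regions is not None:
            bad = set(self.regions) - set(REGIONS)
            if bad:
                raise ValueError(f"unknown region labels: {sorted(bad)}")


def gen_spatial_dataset(n_spots: int, truth: SyntheticTruth, seed: int,
                        noise_sigma: float = 0.1) -> SpatialDataset:
    """Generate spots as noisy mixtures of the truth's cluster profiles.

    Spot expression = mixture of log-scale cluster profiles given by
    ``truth.spot_mixtures`` plus Gaussian noise; spot clusters are the
    dominant mixture component and regions come from ``truth.spot_regions``.
    """
    mixtures = truth.spot_mixtures
    if n_spots > len(mixtures):
        raise ValueError(f"truth defines only {len(mixtures)} spot mixtures")
    mixtures = mixtures.iloc[:n_spots]
    w = mixtures.to_numpy(dtype=float)
    if not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    log_profiles = np.log2(truth.cluster_profiles.to_numpy(dtype=float) + 1.0)
    expr = w @ log_profiles + rng.normal(0.0, noise_sigma, size=(n_spots,
                                                                log_profiles.shape[1]))
    expr = np.clip(expr, 0.0, None)
    expr_df = pd.DataFrame(expr, index=mixtures.index,
                           columns=truth.cluster_profiles.columns)
    coords = pd.DataFrame(rng.uniform(0, 100, size=(n_spots, 2)),
                          index=mixtures.index, columns=["x", "y"])
    spot_clusters = pd.Series(mixtures.idxmax(axis=1), index=mixtures.index,
                              name="spot_cluster")
    regions = None
    if truth.spot_regions is not None:
        regions = truth.spot_regions.iloc[:n_spots]
    return SpatialDataset(expr_df, coords, spot_clusters, regions)


# ---------------------------------------------------------------------------
# Dose-response matrices and limiting-dilution plates
# ---------------------------------------------------------------------------

DEFAULT_DOSES_A = (0.0, 4.0, 8.0, 12.0, 16.0)      # RT, Gy
DEFAULT_DOSES_B = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0)  # partner drug, uM


def loglogistic_fraction(doses: np.ndarray, h: float, m: float,
                         lower: float = 0.0, upper: float = 1.0) -> np.ndarray:
    """Inhibition fraction y(d) = L + (U-L) d^h / (d^h + m^h)."""
    d = np.asarray(doses, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = d ** h / (d ** h + m ** h)
    frac = np.where(d == 0, 0.0, frac)
    return lower + (upper - lower) * frac


def gen_dose_matrix(doses_a=DEFAULT_DOSES_A, doses_b=DEFAULT_DOSES_B,
                    curve_a: dict | None = None, curve_b: dict | None = None,
                    synergy_magnitude: float = 0.0, noise_sd: float = 0.0,
                    seed: int = 0):
    """Generate a combination inhibition grid around a Bliss-independence surface.

    Combination fraction = clamp(yA + yB - yA*yB + magnitude * [both doses > 0],
    0, 1), reported as a percentage with additive Gaussian noise truncated to
    [0, 100]. With magnitude 0 and no noise the grid is the exact Bliss surface.
    """
    from .pharm import DoseResponseMatrix

    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if (doses_a < 0).any() or (doses_b < 0).any():
        raise ValueError("doses must be nonnegative")
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise ValueError("dose grids must include 0")
    # Defaults mirror a potent partner drug (IC50 ~2.5 uM) combined with
    # radiotherapy (D50 ~5 Gy at 48 h), so both margins traverse their full
    # response range within the printed dose grids.
    curve_a = curve_a or {"h": 2.0, "m": 5.0}
    curve_b = curve_b or {"h": 2.0, "m": 2.5}
    ya = loglogistic_fraction(doses_a, **curve_a)
    yb = loglogistic_fraction(doses_b, **curve_b)
    bliss = ya[:, None] + yb[None, :] - ya[:, None] * yb[None, :]
    both = (doses_a[:, None] > 0) & (doses_b[None, :] > 0)
    combo = np.clip(bliss + synergy_magnitude * both, 0.0, 1.0) * 100.0
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        combo = np.clip(combo + rng.normal(0.0, noise_sd, size=combo.shape),
                        0.0, 100.0)
    return DoseResponseMatrix(doses_a, doses_b, combo)


def gen_dilution_assay(frequency: float, doses=(0, 1, 5, 10, 20, 50),
                       n_wells: int = 16, seed: int = 0) -> pd.DataFrame:
    """Generate a limiting-dilution plate under the single-hit Poisson model.

    Each well seeded with x cells responds independently with probability
    1 - (1 - frequency)^x.
    """
    if not (0.0 < frequency <= 1.0):
        raise ValueError("frequency must be in (0, 1]")
    doses = np.asarray(doses)
    if (doses < 0).any() or not np.issubdtype(doses.dtype, np.integer):
        raise ValueError("doses must be nonnegative integers")
    rng = np.random.default_rng(seed)
    rows = []
    for x in doses:
        p = 1.0 - (1.0 - frequency) ** int(x)
        responding = int(rng.binomial(n_wells, p))
        rows.append((int(x), int(n_wells), responding))
    return pd.DataFrame(rows, columns=["cells_per_well", "wells_tested",
                                       "wells_responding"])
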