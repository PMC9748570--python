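"""Synthetic cohorts with known planted structure for pipeline validation.

Participant-level MRI and genotype data of the kind this pipeline analyses
are access-restricted, so every downstream stage is exercised against
synthetic data with planted ground truth:

* **Connectomes** — a stochastic block model on 90 nodes in which a designated
  hub community receives inflated connection probability and edge weight.
  NS weights are log-normal (rounded to positive integers), FA weights are
  Beta-distributed in (0, 1) and share the NS edge support, mimicking that
  both weightings describe one tractogram.  The hub community produces a
  heavy-tailed strength distribution and a non-empty mean + 1 SD hub set.
* **Covariates** — sex (62% male by default) and diffusion scan type (30 vs
  60 directions, 39% sixty-direction); the scan type adds a small
  multiplicative effect (+5% by default) to NS weights so covariate
  adjustment is testable.
* **PRS vectors** — Gaussian-copula mixing plants an exact target correlation
  between a score vector and any pipeline-computable phenotype.
* **Genotype panels** — blocky LD (all SNP pairs within a block share one
  dosage r-squared), a chosen fraction of causal SNPs driving a Gaussian
  liability, and marginal-regression GWAS summary statistics computed on the
  panel itself, so effect sizes and p-values are mutually consistent.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, in a fixed documented order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import metrics
from .hubs import HubPartition, class_connectivity, identify_hubs, node_hubness
from .networks import (ConnectivityMatrix, DEFAULT_THRESHOLD, SUBNETWORKS,
                       apply_streamline_threshold, load_atlas, threshold_with_mask)
from .prs import GenotypePanel

#: study-condition defaults emulating the cohort under analysis
DEFAULT_N_PARTICIPANTS = 562
DEFAULT_MALE_FRACTION = 0.62
DEFAULT_SIXTY_DIR_FRACTION = 219 / 562


class SyntheticConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of one synthetic connectome cohort.

    ``hub_boost`` multiplies the connection propensity per hub endpoint of an
    edge; ``hub_weight_boost`` multiplies NS weights the same way.  Both
    default to values that make the planted hub community recoverable by the
    mean + 1 SD hubness rule without claiming anatomical realism.
    """

    n_participants: int = DEFAULT_N_PARTICIPANTS
    n_nodes: int = 90
    edge_density: float = 0.30
    hub_fraction: float = 13 / 90
    weight_model: str = "NS"
    male_fraction: float = DEFAULT_MALE_FRACTION
    sixty_direction_fraction: float = DEFAULT_SIXTY_DIR_FRACTION
    scan_effect: float = 0.05
    hub_boost: float = 2.5
    hub_weight_boost: float = 1.6
    ns_log_mu: float = math.log(25.0)
    ns_log_sigma: float = 0.8
    fa_beta_a: float = 8.0
    fa_beta_b: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise SyntheticConfigError("n_participants must be >= 3")
        if not 0 < self.edge_density <= 1:
            raise SyntheticConfigError("edge_density must lie in (0, 1]")
        if not 0 < self.hub_fraction < 0.5:
            raise SyntheticConfigError("hub_fraction must lie in (0, 0.5)")
        if self.weight_model not in ("NS", "FA"):
            raise SyntheticConfigError("weight_model must be 'NS' or 'FA'")


@dataclass
class Cohort:
    """A generated cohort: NS and FA matrices, covariates, planted hub set."""

    ns_matrices: list[ConnectivityMatrix]
    fa_matrices: list[ConnectivityMatrix]
    covariates: pd.DataFrame
    planted_hubs: tuple[str, ...]
    config: CohortConfig = field(repr=False)

    @property
    def matrices(self) -> list[ConnectivityMatrix]:
        return self.ns_matrices if self.config.weight_model == "NS" else self.fa_matrices

    @property
    def participant_ids(self) -> pd.Index:
        return self.covariates.index


def _edge_probabilities(cfg: CohortConfig, is_hub: np.ndarray) -> np.ndarray:
    """Per-pair connection probabilities matching the target overall density."""
    n = cfg.n_nodes
    n_hub_ends = is_hub.astype(int)[:, None] + is_hub.astype(int)[None, :]
    propensity = cfg.hub_boost ** n_hub_ends
    iu = np.triu_indices(n, k=1)
    target = cfg.edge_density * len(iu[0])

    def realized(c):
        return np.minimum(1.0, c * propensity[iu]).sum()

    lo, hi = 0.0, 1.0
    while realized(hi) < target - 1e-9:
        hi *= 2.0
        if hi > 1e9:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target:
            lo = mid
        else:
            hi = mid
    p = np.minimum(1.0, hi * propensity)
    np.fill_diagonal(p, 0.0)
    return p


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a cohort of symmetric, zero-diagonal, nonnegative connectomes.

    Identical config (including seed) yields byte-identical output.  Seed
    splitting order: hub assignment, covariates, then per-participant
    (edges, NS weights, FA weights).
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_hub, rng_cov, rng_part = (np.random.default_rng(s) for s in ss.spawn(3))

    atlas = load_atlas()
    if cfg.n_nodes == 90:
        labels = list(atlas.region_names)
    else:
        labels = [f"node{i:03d}" for i in range(cfg.n_nodes)]
    n = cfg.n_nodes
    n_hubs = max(1, round(cfg.hub_fraction * n))
    hub_idx = np.sort(rng_hub.permutation(n)[:n_hubs])
    is_hub = np.zeros(n, dtype=bool)
    is_hub[hub_idx] = True

    sex = (rng_cov.random(cfg.n_participants) < cfg.male_fraction).astype(int)
    scan = (rng_cov.random(cfg.n_participants) < cfg.sixty_direction_fraction).astype(int)
    ids = [f"sub{i:04d}" for i in range(cfg.n_participants)]
    covariates = pd.DataFrame({"sex": sex, "scan_type": scan},
                              index=pd.Index(ids, name="participant"))

    p_edge = _edge_probabilities(cfg, is_hub)
    n_hub_ends = is_hub.astype(int)[:, None] + is_hub.astype(int)[None, :]
    weight_mult = cfg.hub_weight_boost ** n_hub_ends
    iu = np.triu_indices(n, k=1)

    ns_mats, fa_mats = [], []
    for pid, scan_i in zip(ids, scan):
        rng = np.random.default_rng(rng_part.integers(0, 2**31 - 1))
        present = rng.random(len(iu[0])) < p_edge[iu]
        raw = rng.lognormal(cfg.ns_log_mu, cfg.ns_log_sigma, size=len(iu[0]))
        raw *= weight_mult[iu]
        if scan_i:
            raw *= 1.0 + cfg.scan_effect
        ns_vals = np.where(present, np.maximum(1, np.rint(raw)), 0.0)
        fa_raw = rng.beta(cfg.fa_beta_a, cfg.fa_beta_b, size=len(iu[0]))
        fa_raw = np.clip(fa_raw + 0.03 * n_hub_ends[iu], 1e-4, 1 - 1e-4)
        fa_vals = np.where(present, fa_raw, 0.0)
        ns = np.zeros((n, n))
        fa = np.zeros((n, n))
        ns[iu] = ns_vals
        fa[iu] = fa_vals
        ns += ns.T
        fa += fa.T
        ns_mats.append(ConnectivityMatrix(ns, labels, "NS", pid))
        fa_mats.append(ConnectivityMatrix(fa, labels, "FA", pid))

    planted = tuple(labels[i] for i in hub_idx)
    return Cohort(ns_mats, fa_mats, covariates, planted, cfg)


# ---------------------------------------------------------------------------
# Phenotype resolution
# ---------------------------------------------------------------------------

_METRIC_KEYS = ("mean_strength", "mean_clustering", "mean_betweenness",
                "characteristic_path_length", "global_efficiency")


def _thresholded(cohort: Cohort, weighting: str, threshold: int) -> list[ConnectivityMatrix]:
    out = []
    for ns, fa in zip(cohort.ns_matrices, cohort.fa_matrices):
        if weighting == "NS":
            out.append(apply_streamline_threshold(ns, threshold, override=True))
        else:
            out.append(threshold_with_mask(fa, ns, threshold, override=True))
    return out


def cohort_hub_partition(cohort: Cohort, weighting: str = "NS",
                         threshold: int = DEFAULT_THRESHOLD,
                         hub_sample: int | None = None) -> HubPartition:
    """Identify hubs from cohort-averaged composite hubness.

    ``hub_sample`` caps the number of participants entering the hubness
    average (hub sets are stable across subsamples; smaller samples keep the
    betweenness/local-efficiency cost of large simulated cohorts down).
    """
    mats = _thresholded(cohort, weighting, threshold)
    if hub_sample is not None:
        mats = mats[:hub_sample]
    rows = [node_hubness(metrics.node_metric_table(m)) for m in mats]
    hubness = pd.DataFrame(rows, index=[m.participant_id for m in mats])
    return identify_hubs(hubness)


def resolve_phenotype(cohort: Cohort, name: str, weighting: str = "NS",
                      threshold: int = DEFAULT_THRESHOLD,
                      partition: HubPartition | None = None,
                      hub_sample: int | None = None) -> pd.Series:
    """Compute a named phenotype vector (one value per participant).

    Names are ``{network}_{metric}`` (network in whole_brain/dmn/limbic/
    visual, metric in mean_strength, mean_clustering, mean_betweenness,
    characteristic_path_length, global_efficiency) or
    ``{rich_club,feeder,local}_connectivity``.
    """
    mats = _thresholded(cohort, weighting, threshold)
    ids = [m.participant_id for m in mats]
    if name.endswith("_connectivity"):
        cls = name[: -len("_connectivity")]
        if cls not in ("rich_club", "feeder", "local"):
            raise SyntheticConfigError(f"unknown connectivity class in {name!r}")
        if partition is None:
            partition = cohort_hub_partition(cohort, weighting, threshold, hub_sample)
        vals = [class_connectivity(m, partition)[cls] for m in mats]
        return pd.Series(vals, index=ids, name=name)
    for net in SUBNETWORKS:
        if name.startswith(net + "_"):
            metric = name[len(net) + 1:]
            if metric not in _METRIC_KEYS:
                raise SyntheticConfigError(f"unknown metric in phenotype {name!r}")
            atlas = load_atlas()
            sub = atlas.subnetwork(net)
            vals = []
            for m in mats:
                w = m.weights[np.ix_(sub.node_indices, sub.node_indices)]
                if metric == "mean_strength":
                    vals.append(metrics.nodal_strength(w).mean())
                elif metric == "mean_clustering":
                    vals.append(metrics.clustering_coefficient(w).mean())
                elif metric == "mean_betweenness":
                    vals.append(metrics.betweenness_centrality(w).mean())
                elif metric == "characteristic_path_length":
                    vals.append(metrics.characteristic_path_length(w).value)
                else:
                    vals.append(metrics.global_efficiency(w))
            return pd.Series(vals, index=ids, name=name)
    raise SyntheticConfigError(f"phenotype {name!r} does not resolve to a computable quantity")


# ---------------------------------------------------------------------------
# Effect planting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedEffect:
    """A correlation to plant between a PRS vector and a phenotype."""

    target_phenotype: str
    effect_r: float
    noise_model: str = "gaussian_copula"

    def __post_init__(self) -> None:
        if not abs(self.effect_r) < 1:
            raise SyntheticConfigError("|effect_r| must be < 1")


def plant_prs_effect(phenotype, effect: PlantedEffect, seed=0, **resolve_kwargs) -> pd.Series:
    """A standard-normal PRS vector correlating ``effect_r`` with the phenotype.

    ``phenotype`` is either a per-participant vector or a :class:`Cohort`,
    in which case ``effect.target_phenotype`` is resolved first.
    Gaussian-copula mixing: the phenotype's rank-based normal scores are
    mixed with independent noise, so the target correlation holds regardless
    of the phenotype's marginal distribution (up to sampling noise at the
    given n).
    """
    if isinstance(phenotype, Cohort):
        phenotype = resolve_phenotype(phenotype, effect.target_phenotype, **resolve_kwargs)
    y = pd.Series(phenotype)
    n = len(y)
    ranks = y.rank(method="average").to_numpy()
    z = sps.norm.ppf(ranks / (n + 1.0))
    z = (z - z.mean()) / z.std()
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal(n)
    eps = (eps - eps.mean()) / eps.std()
    r = effect.effect_r
    score = r * z + math.sqrt(1.0 - r * r) * eps
    return pd.Series(score, index=y.index, name="prs")


def simulate_score_panel(index, planted: dict[str, pd.Series] | None = None,
                         cross_threshold_r: float = 0.9,
                         apoe_excl_r: float = 0.95, seed: int = 0) -> pd.DataFrame:
    """Simulate the full 160-column score grid directly (no genotypes).

    Null score definitions get a per-definition base vector mixed with fresh
    noise per threshold (correlation ``cross_threshold_r`` with the base,
    emulating the strong dependence of scores across p-value thresholds).
    A planted definition's APOE-included columns carry the planted vector at
    every threshold, so the planted correlation is exact wherever tested;
    APOE-excluded columns are attenuated copies (correlation ``apoe_excl_r``),
    emulating effects that persist without the APOE locus.
    """
    from .prs import P_THRESHOLDS, PRSConfig, SCORE_NAMES

    planted = planted or {}
    index = pd.Index(index)
    n = len(index)
    rng = np.random.default_rng(seed)

    def _std(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    def _mix(base, rho):
        eps = _std(rng.standard_normal(n))
        return rho * base + math.sqrt(1.0 - rho * rho) * eps

    cols = {}
    for name in SCORE_NAMES:
        if name in planted:
            base = _std(pd.Series(planted[name]).loc[index].to_numpy())
            incl = {pt: base for pt in P_THRESHOLDS}
        else:
            b = _std(rng.standard_normal(n))
            incl = {pt: _mix(b, cross_threshold_r) for pt in P_THRESHOLDS}
        for pt in P_THRESHOLDS:
            cols[PRSConfig(name, True, pt).column] = incl[pt]
            cols[PRSConfig(name, False, pt).column] = _mix(incl[pt], apoe_excl_r)
    return pd.DataFrame(cols, index=index)


# ---------------------------------------------------------------------------
# Genotype panel
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenotypePanelConfig:
    """Configuration of a blocky-LD genotype panel with GWAS summary stats."""

    n_individuals: int = 2000
    n_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    within_block_r2: float = 0.4
    causal_fraction: float = 0.2
    heritability: float = 0.5
    low_info_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SyntheticConfigError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.within_block_r2 <= 1:
            raise SyntheticConfigError("within_block_r2 must lie in [0, 1]")
        if not 0 <= self.causal_fraction <= 1:
            raise SyntheticConfigError("causal_fraction must lie in [0, 1]")


@dataclass
class GenotypePanelResult:
    """Generated dosages, GWAS-like summary statistics and ground truth."""

    genotypes: GenotypePanel
    sumstats: pd.DataFrame
    causal_snps: tuple[str, ...]
    blocks: pd.DataFrame
    liability: pd.Series


def generate_genotype_panel(config: GenotypePanelConfig) -> GenotypePanelResult:
    """Blocky-LD dosage panel with marginal-GWAS summary statistics.

    Within a block every SNP copies a latent block haplotype with probability
    ``within_block_r2 ** 0.25`` (per haplotype), giving every SNP pair the
    same expected dosage r-squared, ``within_block_r2``.  Blocks sit 2 Mb
    apart on one chromosome so a 500 kb clumping window never spans blocks.
    The liability is a standardised sum of causal-SNP dosages plus Gaussian
    noise at the configured heritability; summary statistics are the
    marginal regressions of that liability on each SNP in this same panel.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_pheno, rng_info = (np.random.default_rng(s) for s in ss.spawn(3))
    n, m = cfg.n_individuals, cfg.n_snps
    n_blocks = math.ceil(m / cfg.ld_block_size)
    block_of = np.repeat(np.arange(n_blocks), cfg.ld_block_size)[:m]
    copy_prob = cfg.within_block_r2 ** 0.25

    block_maf = rng_geno.uniform(*cfg.maf_range, size=n_blocks)
    dose = np.empty((n, m))
    for b in range(n_blocks):
        cols = np.flatnonzero(block_of == b)
        p = block_maf[b]
        for hap in range(2):
            latent = rng_geno.random(n) < p
            fresh = rng_geno.random((n, len(cols))) < p
            copied = rng_geno.random((n, len(cols))) < copy_prob
            alleles = np.where(copied, latent[:, None], fresh)
            if hap == 0:
                dose[:, cols] = alleles
            else:
                dose[:, cols] += alleles

    snp_ids = [f"rs{b:03d}_{j:02d}" for b, j in zip(block_of, range(m))]
    positions = (block_of * 2_000_000 + (np.arange(m) % cfg.ld_block_size) * 10_000
                 + 1_000_000)
    ids = [f"ind{i:05d}" for i in range(n)]
    snp_info = pd.DataFrame({
        "SNP": snp_ids, "CHR": 1, "BP": positions, "A1": "A", "A2": "G",
    }).set_index("SNP", drop=False).rename_axis(None)

    n_causal = round(cfg.causal_fraction * m)
    causal = np.sort(rng_pheno.permutation(m)[:n_causal])
    beta_true = np.zeros(m)
    if n_causal:
        beta_true[causal] = rng_pheno.standard_normal(n_causal)
    genetic = dose @ beta_true
    if genetic.std() > 0 and cfg.heritability > 0:
        genetic = (genetic - genetic.mean()) / genetic.std() * math.sqrt(cfg.heritability)
        noise_sd = math.sqrt(1.0 - cfg.heritability)
    else:
        genetic = np.zeros(n)
        noise_sd = 1.0
    liability = genetic + rng_pheno.standard_normal(n) * noise_sd

    # marginal GWAS on the panel itself
    d_sd = dose.std(axis=0)
    d_sd_safe = np.where(d_sd > 0, d_sd, 1.0)
    y_c = liability - liability.mean()
    r = (dose - dose.mean(axis=0)).T @ y_c / (n * d_sd_safe * y_c.std())
    r = np.clip(np.where(d_sd > 0, r, 0.0), -0.999999, 0.999999)
    tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
    pvals = 2.0 * sps.t.sf(np.abs(tstat), n - 2)
    beta_hat = r * y_c.std() / d_sd_safe

    af = dose.mean(axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    n_low = round(cfg.low_info_fraction * m)
    info = rng_info.uniform(0.9, 1.0, size=m)
    low_idx = rng_info.permutation(m)[:n_low]
    info[low_idx] = rng_info.uniform(0.5, 0.9, size=n_low)

    sumstats = pd.DataFrame({
        "SNP": snp_ids, "CHR": 1, "BP": positions, "A1": "A", "A2": "G",
        "BETA": beta_hat, "P": np.clip(pvals, np.finfo(float).tiny, 1.0),
        "MAF": maf, "INFO": info,
    })
    blocks = pd.DataFrame({"SNP": snp_ids, "block": block_of})
    panel = GenotypePanel(pd.DataFrame(dose, index=ids, columns=snp_ids), snp_info)
    return GenotypePanelResult(
        genotypes=panel,
        sumstats=sumstats,
        causal_snps=tuple(snp_ids[i] for i in causal),
        blocks=blocks,
        liability=pd.Series(liability, index=ids, name="liability"),
    )
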