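"""Polygenic risk scoring from GWAS summary statistics and dosage genotypes.

The scoring pipeline mirrors standard practice for Alzheimer's-disease PRS:
summary-statistic QC (drop MAF < 0.1 or imputation INFO < 0.9), greedy LD
clumping in a 500 kb window (most significant SNP retained per LD
neighbourhood), p-value thresholding at eight progressive cutoffs
(primary 0.001), and per-individual scoring as the mean effect per
non-missing allele.  Scores come in twenty definitions — genome-wide plus
nine disease-pathway restrictions, each with and without the APOE locus —
for a 20 x 8 grid of 160 score columns.

Summary statistics are tab-delimited with columns
``SNP CHR BP A1 A2 BETA P MAF INFO`` (A1 = effect allele).  Genotypes are an
individuals-by-SNP dosage matrix in [0, 2] counting the panel's A1 allele.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "MAF", "INFO")

#: the eight GWAS p-value thresholds; 0.001 is the primary analysis
P_THRESHOLDS = (1e-5, 1e-4, 1e-3, 1e-2, 0.05, 0.1, 0.3, 0.5)
PRIMARY_THRESHOLD = 1e-3

#: the nine disease-pathway score restrictions
PATHWAYS = (
    "protein_lipid_complex_assembly",
    "regulation_of_beta_amyloid_formation",
    "protein_lipid_complex",
    "regulation_of_app_catabolic_process",
    "tau_protein_binding",
    "reverse_cholesterol_transport",
    "protein_lipid_complex_subunit_organization",
    "plasma_lipoprotein_particle_assembly",
    "activation_of_the_immune_response",
)

SCORE_NAMES = ("genome_wide",) + PATHWAYS

#: APOE locus on chromosome 19, GRCh37 convention (closed interval, bp)
APOE_REGION = (19, 44_400_000, 46_500_000)

#: strand-ambiguous allele pairs, dropped during alignment
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


class PRSError(ValueError):
    """Raised for invalid PRS configuration or inputs."""


@dataclass(frozen=True)
class PRSConfig:
    """One cell of the score grid."""

    score_name: str
    include_apoe: bool
    p_threshold: float
    clump_window_kb: float = 500.0
    clump_r2: float = 0.1

    def __post_init__(self) -> None:
        if self.score_name not in SCORE_NAMES:
            raise PRSError(f"unknown score {self.score_name!r}")
        if self.p_threshold not in P_THRESHOLDS:
            raise PRSError(f"p_threshold must be one of {P_THRESHOLDS}")

    @property
    def column(self) -> str:
        apoe = "inclAPOE" if self.include_apoe else "exclAPOE"
        return f"{self.score_name}.{apoe}.pt{self.p_threshold:g}"


def enumerate_configs(clump_r2: float = 0.1) -> list[PRSConfig]:
    """The full grid: (1 genome-wide + 9 pathways) x {incl, excl APOE} x 8 thresholds."""
    return [
        PRSConfig(name, apoe, pt, clump_r2=clump_r2)
        for name, apoe, pt in itertools.product(SCORE_NAMES, (True, False), P_THRESHOLDS)
    ]


@dataclass
class GenotypePanel:
    """Dosage matrix plus per-SNP metadata.

    ``dosages``: individuals x SNPs, values in [0, 2] or NaN for missing,
    counting the allele in ``snp_info['A1']``.  ``snp_info`` is indexed by
    SNP id with columns CHR, BP, A1, A2.
    """

    dosages: pd.DataFrame
    snp_info: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.dosages.columns.duplicated().any():
            raise PRSError("duplicate SNP ids in dosage matrix")
        vals = self.dosages.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise PRSError("dosages must lie in [0, 2]")
        missing = set(self.dosages.columns) - set(self.snp_info.index)
        if missing:
            raise PRSError(f"{len(missing)} dosage columns lack SNP metadata")


def read_genotypes_vcf(path) -> GenotypePanel:
    """Read dosages from a VCF with a per-sample ``DS`` FORMAT field."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, info_rows = {}, []
    for var in vcf:
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        ds = var.format("DS")
        if ds is None:
            raise PRSError(f"variant {snp} has no DS field")
        cols[snp] = np.asarray(ds, dtype=float).reshape(-1)
        info_rows.append((snp, int(str(var.CHROM).lstrip("chr")), var.POS,
                          var.ALT[0], var.REF))
    info = pd.DataFrame(info_rows, columns=["SNP", "CHR", "BP", "A1", "A2"]).set_index("SNP")
    return GenotypePanel(pd.DataFrame(cols, index=samples), info)


def write_genotypes_vcf(genotypes: GenotypePanel, path) -> None:
    """Write a dosage panel as an uncompressed VCF with a ``DS`` FORMAT field.

    A1 (the counted allele) becomes ALT, A2 becomes REF; hard genotypes are
    emitted as rounded dosages alongside DS.
    """
    info = genotypes.snp_info
    samples = list(genotypes.dosages.index)
    order = info.loc[list(genotypes.dosages.columns)].sort_values(["CHR", "BP"])
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        for chrom in sorted(order["CHR"].unique()):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for snp, row in order.iterrows():
            fields = []
            for d in genotypes.dosages[snp]:
                if np.isfinite(d):
                    fields.append(f"{gt_map[int(round(d))]}:{d:g}")
                else:
                    fields.append("./.:.")
            fh.write(f"{row['CHR']}\t{row['BP']}\t{snp}\t{row['A2']}\t{row['A1']}"
                     f"\t.\tPASS\t.\tGT:DS\t" + "\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Record filters
# ---------------------------------------------------------------------------

def qc_filter(records: pd.DataFrame, maf_min: float = 0.1,
              info_min: float = 0.9) -> pd.DataFrame:
    """Drop SNPs with low minor-allele frequency or poor imputation quality.

    Records with missing MAF or INFO are rejected and logged.
    """
    maf = pd.to_numeric(records["MAF"], errors="coerce")
    info = pd.to_numeric(records["INFO"], errors="coerce")
    n_missing = int((maf.isna() | info.isna()).sum())
    if n_missing:
        logger.warning("qc_filter: rejecting %d records with missing MAF/INFO", n_missing)
    keep = (maf >= maf_min) & (info >= info_min)
    return records.loc[keep.fillna(False)]


def exclude_apoe(records: pd.DataFrame, region=APOE_REGION) -> pd.DataFrame:
    """Remove SNPs inside the APOE region (closed base-pair interval)."""
    chrom, start, end = region
    inside = (records["CHR"] == chrom) & (records["BP"] >= start) & (records["BP"] <= end)
    return records.loc[~inside]


def restrict_to_pathway(records: pd.DataFrame, pathway_snps) -> pd.DataFrame:
    """Keep only the SNPs named in a pathway list (intersection by id)."""
    wanted = set(pathway_snps)
    if not wanted:
        raise PRSError("pathway SNP list is empty")
    out = records.loc[records["SNP"].isin(wanted)]
    if out.empty:
        logger.warning("pathway restriction left no SNPs; score will be missing")
    return out


def ld_clump(records: pd.DataFrame, genotypes: GenotypePanel,
             window_kb: float = 500.0, r2_cutoff: float = 0.1,
             on_missing_genotype: str = "fail") -> pd.DataFrame:
    """Greedy LD clumping: keep the most significant SNP per LD neighbourhood.

    SNPs are visited by ascending p-value (position, then id, break ties).
    Each index SNP removes unprocessed SNPs within ``window_kb`` on the same
    chromosome whose dosage r-squared with it reaches ``r2_cutoff``.  Returns
    the index SNPs, in ascending (CHR, BP) order.
    """
    if on_missing_genotype not in ("fail", "skip"):
        raise PRSError("on_missing_genotype must be 'fail' or 'skip'")
    have = records["SNP"].isin(genotypes.dosages.columns)
    if not have.all():
        if on_missing_genotype == "fail":
            missing = records.loc[~have, "SNP"].tolist()[:5]
            raise PRSError(f"no genotypes for {int((~have).sum())} SNPs (e.g. {missing})")
        records = records.loc[have]
    ordered = records.sort_values(["P", "CHR", "BP", "SNP"], kind="stable")
    window_bp = window_kb * 1000.0
    dose = genotypes.dosages
    alive = pd.Series(True, index=ordered.index)
    kept_idx = []
    for idx in ordered.index:
        if not alive[idx]:
            continue
        alive[idx] = False
        kept_idx.append(idx)
        row = ordered.loc[idx]
        near = ordered.index[
            alive.loc[ordered.index].to_numpy()
            & (ordered["CHR"] == row["CHR"]).to_numpy()
            & (np.abs(ordered["BP"] - row["BP"]) <= window_bp).to_numpy()
        ]
        if len(near) == 0:
            continue
        x = dose[row["SNP"]].to_numpy(dtype=float)
        for other in near:
            y = dose[ordered.loc[other, "SNP"]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or x[ok].std() == 0 or y[ok].std() == 0:
                continue
            r = np.corrcoef(x[ok], y[ok])[0, 1]
            if r * r >= r2_cutoff:
                alive[other] = False
    return records.loc[kept_idx].sort_values(["CHR", "BP"], kind="stable")


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def align_alleles(records: pd.DataFrame, genotypes: GenotypePanel) -> pd.DataFrame:
    """Orient summary-stat effect alleles to the genotype panel's counted allele.

    Matching orientations pass through; swapped orientations have their
    effect size re-expressed for the panel's counted allele (beta negated,
    recorded in a ``FLIP`` column), so scoring is invariant to how the input
    file orients its allele columns; strand-ambiguous (A/T, C/G) and
    mismatching records are dropped.
    """
    info = genotypes.snp_info
    rows = []
    n_ambig = n_mismatch = 0
    for _, rec in records.iterrows():
        snp = rec["SNP"]
        if snp not in info.index:
            n_mismatch += 1
            continue
        if frozenset((rec["A1"], rec["A2"])) in _AMBIGUOUS:
            n_ambig += 1
            continue
        g1, g2 = info.loc[snp, "A1"], info.loc[snp, "A2"]
        if (rec["A1"], rec["A2"]) == (g1, g2):
            rows.append((snp, rec["BETA"], False))
        elif (rec["A1"], rec["A2"]) == (g2, g1):
            rows.append((snp, -rec["BETA"], True))
        else:
            n_mismatch += 1
    if n_ambig or n_mismatch:
        logger.info("align_alleles: dropped %d ambiguous, %d mismatching SNPs",
                    n_ambig, n_mismatch)
    return pd.DataFrame(rows, columns=["SNP", "BETA", "FLIP"])


def compute_score(records: pd.DataFrame, genotypes: GenotypePanel,
                  convention: str = "mean") -> pd.Series:
    """Per-individual PRS over the given (QC'd, clumped, thresholded) records.

    ``mean`` convention: score_i = sum_j dosage_ij * beta_j / (2 * m_i) with
    m_i the number of non-missing SNPs for individual i; ``sum`` omits the
    denominator.  Individuals with no non-missing SNP get NaN.
    """
    if convention not in ("mean", "sum"):
        raise PRSError("convention must be 'mean' or 'sum'")
    aligned = records if "FLIP" in records.columns else align_alleles(records, genotypes)
    if aligned.empty:
        return pd.Series(np.nan, index=genotypes.dosages.index, name="score")
    d = genotypes.dosages[aligned["SNP"].tolist()].to_numpy(dtype=float)
    beta = aligned["BETA"].to_numpy(dtype=float)  # already panel-oriented
    mask = np.isfinite(d)
    contrib = np.where(mask, d, 0.0) @ beta
    m = mask.sum(axis=1)
    if convention == "mean":
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(m > 0, contrib / (2.0 * np.maximum(m, 1)), np.nan)
    else:
        vals = np.where(m > 0, contrib, np.nan)
    return pd.Series(vals, index=genotypes.dosages.index, name="score")


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

@dataclass
class ScorePanel:
    """Participant-by-score table for the full 20 x 8 grid plus SNP counts."""

    scores: pd.DataFrame
    snp_counts: pd.DataFrame

    def column(self, score_name: str, include_apoe: bool, p_threshold: float) -> pd.Series:
        cfg = PRSConfig(score_name, include_apoe, p_threshold)
        return self.scores[cfg.column]


def build_score_panel(sumstats: pd.DataFrame, genotypes: GenotypePanel,
                      pathway_snps: dict[str, list[str]] | None = None,
                      clump_r2: float = 0.1, window_kb: float = 500.0,
                      convention: str = "mean",
                      on_missing_genotype: str = "skip") -> ScorePanel:
    """Compute every score of the grid for every individual.

    For each of the 20 score definitions: QC filter, optional APOE exclusion,
    optional pathway restriction, LD clumping; then the eight p-value
    thresholds slice the clumped record set and each slice is scored.
    """
    pathway_snps = pathway_snps or {}
    qc = qc_filter(sumstats)
    scores, counts = {}, {}
    for name in SCORE_NAMES:
        base = qc
        if name != "genome_wide":
            if name not in pathway_snps:
                logger.warning("no SNP list for pathway %s; scores set to missing", name)
                base = None
            else:
                base = restrict_to_pathway(qc, pathway_snps[name])
        for include_apoe in (True, False):
            if base is None or base.empty:
                clumped = None
            else:
                recs = base if include_apoe else exclude_apoe(base)
                clumped = ld_clump(recs, genotypes, window_kb=window_kb,
                                   r2_cutoff=clump_r2,
                                   on_missing_genotype=on_missing_genotype)
                clumped = align_alleles(clumped, genotypes).merge(
                    clumped[["SNP", "P"]], on="SNP")
            for pt in P_THRESHOLDS:
                cfg = PRSConfig(name, include_apoe, pt, clump_r2=clump_r2)
                if clumped is None:
                    scores[cfg.column] = pd.Series(np.nan, index=genotypes.dosages.index)
                    counts[cfg.column] = 0
                    continue
                sel = clumped.loc[clumped["P"] <= pt]
                scores[cfg.column] = compute_score(sel, genotypes, convention=convention)
                counts[cfg.column] = len(sel)
    score_df = pd.DataFrame(scores, index=genotypes.dosages.index)
    count_df = pd.DataFrame([counts])
    return ScorePanel(score_df, count_df)


# ---------------------------------------------------------------------------
# Optional individual-level genotype QC
# ---------------------------------------------------------------------------

def individual_genotype_qc(genotypes: GenotypePanel, call_rate_min: float = 0.95,
                           het_sd: float = 3.0, hwe_p_min: float = 5e-7) -> GenotypePanel:
    """Optional pre-filters: individual call rate, heterozygosity, per-SNP HWE.

    Dosages are rounded to hard genotypes for the heterozygosity and HWE
    checks.  These are upstream conveniences, not core pipeline stages.
    """
    from scipy.stats import chi2

    d = genotypes.dosages
    call_rate = d.notna().mean(axis=1)
    keep_ind = call_rate >= call_rate_min
    hard = d.round()
    het = (hard == 1).sum(axis=1) / hard.notna().sum(axis=1)
    z = (het - het.mean()) / (het.std(ddof=1) if het.std(ddof=1) > 0 else 1.0)
    keep_ind &= z.abs() <= het_sd
    d = d.loc[keep_ind]
    hard = hard.loc[keep_ind]
    keep_snp = []
    for snp in d.columns:
        g = hard[snp].dropna()
        n = len(g)
        if n == 0:
            continue
        counts = np.array([(g == k).sum() for k in (0, 1, 2)], dtype=float)
        p = (2 * counts[2] + counts[1]) / (2 * n)
        exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        with np.errstate(invalid="ignore", divide="ignore"):
            stat = np.nansum(np.where(exp > 0, (counts - exp) ** 2 / np.where(exp > 0, exp, 1), 0))
        if chi2.sf(stat, 1) > hwe_p_min:
            keep_snp.append(snp)
    return GenotypePanel(d[keep_snp], genotypes.snp_info.loc[keep_snp])
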