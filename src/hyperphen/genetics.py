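"""Genetic analysis of hyperspectral indices.

Covers the population-genetics side of the pipeline: SNP panel filtering,
the genomic relationship matrix, bivariate REML heritability / genetic
correlation (see :mod:`hyperphen.reml`), hyper-trait selection, a per-SNP
linear association scan (plumbing so the pipeline runs end to end; a
kinship-corrected mixed model is deliberately out of scope), multiple-test
thresholds from an effective SNP number, LD clumping of association
results, merging associated SNPs into loci, candidate-gene windows around
lead SNPs, and haplotype group contrasts.

Conventions
-----------
* Dosages are minor-allele counts in {0, 1, 2}; NaN marks missing.
* A locus merges associated SNPs whose adjacent gaps are below 300 kb;
  distinct loci on a chromosome are therefore >= 300 kb apart.
* The suggestive/significant genome-wide thresholds are 1/N and 0.05/N for
  an externally estimated effective SNP number N, so significant is always
  exactly 0.05 x suggestive.
* LD r2 is the squared Pearson correlation of (mean-imputed) dosages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .reml import BivariateEstimate, reml_bivariate, reml_univariate

__all__ = [
    "GenotypeMatrix",
    "LocusSet",
    "HaplotypeResult",
    "read_vcf",
    "filter_snps",
    "compute_grm",
    "association_scan",
    "thresholds_from_N",
    "ld_r2",
    "clump_leads",
    "define_loci",
    "load_annotation",
    "candidate_window",
    "haplotype_compare",
    "select_hyper_traits",
    "reml_bivariate",
    "reml_univariate",
    "BivariateEstimate",
]


@dataclass
class GenotypeMatrix:
    """A biallelic SNP panel as accession x SNP dosages.

    ``dosage`` holds allele counts (float so NaN can mark missing);
    positions must be sorted within each chromosome.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray  # n_accessions x n_snps
    accessions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2 or self.dosage.shape[1] != len(self.snp_ids):
            raise ValueError("dosage must be n_accessions x n_snps")
        if len(self.chrom) != len(self.snp_ids) or len(self.pos) != len(self.snp_ids):
            raise ValueError("snp metadata length mismatch")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted on chromosome {c}")
        if not self.accessions:
            self.accessions = [f"acc{i:04d}" for i in range(self.dosage.shape[0])]

    @property
    def n_accessions(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per SNP."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.allele_freq
        return np.minimum(f, 1.0 - f)

    def oriented_to_minor(self) -> "GenotypeMatrix":
        """Flip dosages so the counted allele is the minor one (freq <= 0.5)."""
        flip = self.allele_freq > 0.5
        dosage = self.dosage.copy()
        dosage[:, flip] = 2.0 - dosage[:, flip]
        return GenotypeMatrix(
            self.snp_ids, self.chrom, self.pos, dosage, list(self.accessions)
        )

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            self.snp_ids[keep], self.chrom[keep], self.pos[keep],
            self.dosage[:, keep], list(self.accessions),
        )

    def column(self, snp_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.snp_ids == snp_id)
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return self.dosage[:, idx[0]]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load dosages from the GT field of a VCF."""
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    accessions = list(vcf.samples)
    ids, chroms, poss, rows = [], [], [], []
    for v in vcf:
        ids.append(v.ID or f"{v.CHROM}_{v.POS}")
        chroms.append(v.CHROM)
        poss.append(v.POS)
        gt = v.gt_types.astype(float)  # 0/1/2, 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
    if not rows:
        raise ValueError(f"no variants in {path}")
    return GenotypeMatrix(
        np.array(ids, dtype=object),
        np.array(chroms, dtype=object),
        np.array(poss, dtype=np.int64),
        np.vstack(rows).T,
        accessions,
    )


def filter_snps(
    geno: GenotypeMatrix, maf_min: float = 0.05, mac_min: int = 6
) -> GenotypeMatrix:
    """Apply the standard panel filters.

    SNPs are first oriented to the minor allele; those with minor allele
    frequency below ``maf_min`` or carried by fewer than ``mac_min``
    accessions are dropped.
    """
    g = geno.oriented_to_minor()
    carriers = np.nansum(g.dosage > 0, axis=0)
    keep = (g.maf >= maf_min) & (carriers >= mac_min)
    if not keep.any():
        warnings.warn("all SNPs removed by filters", stacklevel=2)
    return g.subset(keep)


def _imputed_standardized(dosage: np.ndarray):
    """Mean-impute missing dosages and z-score columns; returns (Z, keep)."""
    X = dosage.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    sd = X.std(axis=0)
    keep = sd > 0
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return Z, keep


def compute_grm(geno: GenotypeMatrix) -> np.ndarray:
    """Genomic relationship matrix from standardized dosages.

    K = Z Z' / m with Z the column-standardized (mean-imputed) dosage
    matrix; monomorphic SNPs are excluded.  K is symmetric positive
    semi-definite with diagonal mean ~ 1.
    """
    Z, keep = _imputed_standardized(geno.dosage)
    m = keep.sum()
    if m == 0:
        raise ValueError("no polymorphic SNPs")
    return Z @ Z.T / m


def association_scan(
    geno: GenotypeMatrix,
    phenotype: np.ndarray | pd.Series,
    trait_id: str = "trait",
    population: str = "all",
) -> pd.DataFrame:
    """Per-SNP linear-regression scan (slope t-test P-values).

    Plumbing for end-to-end runs on synthetic panels; it does not correct
    for population structure or kinship.
    """
    y = np.asarray(phenotype, dtype=float)
    if len(y) != geno.n_accessions:
        raise ValueError("phenotype length != accession count")
    if y.std() == 0:
        raise ValueError("zero-variance phenotype")
    Z, keep = _imputed_standardized(geno.dosage)
    n = len(y)
    yc = (y - y.mean()) / y.std()
    r = (Z.T @ yc) / n
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    tstat = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(tstat), n - 2)
    p = np.maximum(p, np.finfo(float).tiny)  # keep P in (0, 1]
    return pd.DataFrame(
        {
            "snp": geno.snp_ids[keep],
            "chrom": geno.chrom[keep],
            "pos": geno.pos[keep],
            "p": p,
            "trait": trait_id,
            "population": population,
        }
    )


def thresholds_from_N(n_effective: float) -> tuple[float, float]:
    """Genome-wide (suggestive, significant) P thresholds = (1/N, 0.05/N)."""
    if n_effective <= 0:
        raise ValueError("effective SNP number must be positive")
    return 1.0 / n_effective, 0.05 / n_effective


def ld_r2(geno: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD r2: squared dosage correlation (mean-imputed)."""
    a = geno.column(snp_a)
    b = geno.column(snp_b)
    a = np.where(np.isnan(a), np.nanmean(a), a)
    b = np.where(np.isnan(b), np.nanmean(b), b)
    if a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def clump_leads(
    assoc: pd.DataFrame,
    geno: GenotypeMatrix,
    suggestive: float,
    r2_max: float = 0.25,
    support_p: float = 1e-4,
    min_support: int = 5,
) -> pd.DataFrame:
    """LD-clump an association table into independent lead SNPs.

    Greedy by ascending P among SNPs below the suggestive threshold: the
    best remaining SNP becomes a lead and every unprocessed candidate with
    r2 > ``r2_max`` to it is absorbed into its clump.  Leads supported by
    fewer than ``min_support`` SNPs at P < ``support_p`` in LD with them
    are then dropped.  Result order is by ascending P and is independent of
    the input row order.  SNPs missing from the genotype panel are excluded
    with a warning.
    """
    df = assoc.copy()
    have = np.isin(df["snp"].to_numpy(), geno.snp_ids)
    if not have.all():
        warnings.warn(
            f"{int((~have).sum())} association SNPs missing from genotypes",
            stacklevel=2,
        )
        df = df[have]
    df = df.sort_values(["p", "chrom", "pos"], kind="mergesort")

    col_of = {s: i for i, s in enumerate(geno.snp_ids)}
    X = geno.dosage.copy()
    mu = np.nanmean(X, axis=0)
    idx_nan = np.isnan(X)
    X[idx_nan] = np.take(mu, np.nonzero(idx_nan)[1])
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))

    def r2_vector(lead_col: int) -> np.ndarray:
        v = Xc[:, lead_col]
        nv = norms[lead_col]
        if nv == 0:
            return np.zeros(Xc.shape[1])
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (Xc.T @ v) / (norms * nv)
        return np.nan_to_num(r) ** 2

    support_snps = df.loc[df["p"] < support_p, "snp"].to_numpy()
    support_cols = np.array([col_of[s] for s in support_snps], dtype=int)

    cand = df[df["p"] < suggestive]
    removed: set[str] = set()
    leads = []
    for row in cand.itertuples(index=False):
        if row.snp in removed:
            continue
        lead_col = col_of[row.snp]
        r2 = r2_vector(lead_col)
        # absorb dependent candidates
        for other in cand["snp"]:
            if other != row.snp and r2[col_of[other]] > r2_max:
                removed.add(other)
        n_support = int(
            np.sum(
                (r2[support_cols] > r2_max)
                & (support_snps != row.snp)
            )
        )
        leads.append(
            {
                "snp": row.snp,
                "chrom": row.chrom,
                "pos": row.pos,
                "p": row.p,
                "n_support": n_support,
            }
        )
    out = pd.DataFrame(leads, columns=["snp", "chrom", "pos", "p", "n_support"])
    return out[out["n_support"] >= min_support].reset_index(drop=True)


@dataclass
class LocusSet:
    """Merged genomic intervals of associated SNPs with lead SNPs.

    ``loci`` has one row per locus (chrom, start, end, n_snps, lead_snp,
    lead_p); ``assignment`` maps every input SNP to its locus id.  Loci are
    disjoint and adjacent loci on a chromosome are at least ``gap_bp``
    apart.
    """

    loci: pd.DataFrame
    assignment: pd.Series  # snp id -> locus id
    gap_bp: int

    def validate(self) -> None:
        for c, grp in self.loci.groupby("chrom"):
            g = grp.sort_values("start")
            if np.any(g["start"].to_numpy() > g["end"].to_numpy()):
                raise AssertionError("locus with start > end")
            gaps = g["start"].to_numpy()[1:] - g["end"].to_numpy()[:-1]
            if np.any(gaps < self.gap_bp):
                raise AssertionError(f"adjacent loci closer than {self.gap_bp} bp")


def define_loci(snps: pd.DataFrame, gap_kb: float = 300.0) -> LocusSet:
    """Merge associated SNPs into loci by single-linkage along each chromosome.

    SNPs whose adjacent distance is below ``gap_kb`` kilobases fall into
    the same locus; the lead SNP of a locus is its lowest-P member (ties
    broken by position).  ``snps`` needs columns ``snp, chrom, pos`` and
    optionally ``p``.
    """
    gap_bp = int(round(gap_kb * 1000))
    df = snps.copy()
    if "p" not in df.columns:
        df["p"] = np.nan
    loci_rows = []
    assign = {}
    locus_id = 0
    for c in pd.unique(df["chrom"]):
        sub = df[df["chrom"] == c].sort_values("pos", kind="mergesort")
        pos = sub["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) >= gap_bp)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            block = sub.iloc[s : e + 1]
            if block["p"].notna().any():
                lead = block.sort_values(["p", "pos"], kind="mergesort").iloc[0]
            else:
                lead = block.iloc[0]
            loci_rows.append(
                {
                    "locus_id": locus_id,
                    "chrom": c,
                    "start": int(block["pos"].min()),
                    "end": int(block["pos"].max()),
                    "n_snps": len(block),
                    "lead_snp": lead["snp"],
                    "lead_p": lead["p"],
                }
            )
            for snp in block["snp"]:
                assign[snp] = locus_id
            locus_id += 1
    loci = pd.DataFrame(
        loci_rows,
        columns=["locus_id", "chrom", "start", "end", "n_snps", "lead_snp", "lead_p"],
    )
    return LocusSet(loci, pd.Series(assign, dtype=int), gap_bp)


def load_annotation(path: str | Path):
    """Load a GFF3 gene annotation into an in-memory feature database."""
    import gffutils

    return gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )


def candidate_window(
    chrom: str,
    pos: int,
    annotation,
    flank_kb: float = 100.0,
    featuretype: str = "gene",
) -> list[str]:
    """Genes overlapping the window ``flank_kb`` either side of a lead SNP.

    ``annotation`` is a gffutils FeatureDB (see :func:`load_annotation`) or
    a path to a GFF3 file.  Returns gene IDs sorted by start position; an
    absent chromosome yields an empty list with a warning.
    """
    if isinstance(annotation, (str, Path)):
        annotation = load_annotation(annotation)
    flank = int(round(flank_kb * 1000))
    lo, hi = max(1, pos - flank), pos + flank
    seqids = {f.seqid for f in annotation.all_features()}
    if chrom not in seqids:
        warnings.warn(f"chromosome {chrom!r} absent from annotation", stacklevel=2)
        return []
    hits = annotation.region(seqid=chrom, start=lo, end=hi,
                             featuretype=featuretype, completely_within=False)
    genes = sorted(hits, key=lambda f: f.start)
    return [g.id for g in genes]


@dataclass
class HaplotypeResult:
    """Haplotype group contrast for one gene's significant SNPs."""

    groups: pd.DataFrame  # haplotype, n, mean
    t_stat: float
    p_value: float
    compared: tuple[str, str]


def haplotype_compare(
    dosages: np.ndarray,
    phenotype: np.ndarray | pd.Series,
    min_group: int = 30,
) -> HaplotypeResult:
    """Group accessions by their multi-SNP genotype and test the top two.

    Accessions sharing an identical dosage string across the supplied SNPs
    form a haplotype group; groups smaller than ``min_group`` are dropped.
    The two largest remaining groups are compared with a Welch t-test on
    the phenotype.
    """
    dosages = np.atleast_2d(np.asarray(dosages, dtype=float))
    if dosages.ndim != 2:
        raise ValueError("dosages must be accessions x SNPs")
    y = np.asarray(phenotype, dtype=float)
    if len(y) != dosages.shape[0]:
        raise ValueError("phenotype length != accession count")
    complete = ~np.isnan(dosages).any(axis=1) & ~np.isnan(y)
    dosages, y = dosages[complete], y[complete]
    keys = np.array(
        ["/".join(f"{int(v)}" for v in row) for row in dosages], dtype=object
    )
    table = pd.DataFrame({"haplotype": keys, "y": y})
    sizes = table.groupby("haplotype").size()
    eligible = sizes[sizes >= min_group]
    if len(eligible) < 2:
        raise ValueError(
            f"need >=2 haplotype groups with >= {min_group} accessions, "
            f"found {len(eligible)}"
        )
    top2 = eligible.sort_values(ascending=False).index[:2]
    a = table.loc[table["haplotype"] == top2[0], "y"]
    b = table.loc[table["haplotype"] == top2[1], "y"]
    t, p = stats.ttest_ind(a, b, equal_var=False)
    groups = (
        table[table["haplotype"].isin(eligible.index)]
        .groupby("haplotype")["y"]
        .agg(n="size", mean="mean")
        .reset_index()
        .sort_values("n", ascending=False, ignore_index=True)
    )
    return HaplotypeResult(groups, float(t), float(p), (str(top2[0]), str(top2[1])))


def select_hyper_traits(
    index_table: pd.DataFrame,
    trait: np.ndarray | pd.Series,
    grm: np.ndarray | None = None,
    estimates: dict[str, BivariateEstimate] | None = None,
    r_p_min: float = 0.5,
    r_g_min: float = 0.5,
    h2_min: float = 0.5,
) -> pd.DataFrame:
    """Flag indices that qualify as hyper-traits.

    An index passes when |r_p| (Pearson correlation with the agronomic
    trait), |r_g| (genetic correlation from bivariate REML) and h2 (the
    index's own heritability) all reach 0.5.  Absolute correlations are
    used: a strongly negatively correlated index is as informative as a
    positive one.  Either precomputed ``estimates`` (index name ->
    BivariateEstimate of (index, trait)) or a ``grm`` to fit them must be
    given; indices without an estimate are skipped with a warning.
    """
    if estimates is None and grm is None:
        raise ValueError("need either precomputed estimates or a GRM")
    y = np.asarray(trait, dtype=float)
    meta = {"accession", "stage", "S"}
    cols = [c for c in index_table.columns if c not in meta]
    rows = []
    for c in cols:
        x = index_table[c].to_numpy(dtype=float)
        if x.std() == 0:
            warnings.warn(f"index {c} has zero variance; skipped", stacklevel=2)
            continue
        if estimates is not None:
            est = estimates.get(c)
            if est is None:
                warnings.warn(f"no REML estimate for index {c}; skipped",
                              stacklevel=2)
                continue
        else:
            est = reml_bivariate(x, y, grm)
        r_p = float(np.corrcoef(x, y)[0, 1])
        passed = (
            abs(r_p) >= r_p_min
            and abs(est.r_g) >= r_g_min
            and est.h2_1 >= h2_min
        )
        rows.append(
            {
                "index": c,
                "r_p": r_p,
                "r_g": est.r_g,
                "h2": est.h2_1,
                "pass": passed,
            }
        )
    return pd.DataFrame(rows, columns=["index", "r_p", "r_g", "h2", "pass"])
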