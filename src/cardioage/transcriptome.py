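"""Ageing-transcriptome analytics for bulk cardiac RNA-seq.

The pipeline takes a gene x sample count matrix with a genotype (wild-type
FVB vs the transgenic HF model Tgaq*44) and age (4-14 months) design and

1. normalises library composition with TMM (trimmed mean of M-values):
   per sample, the weighted mean of trimmed log-ratios against a reference
   sample gives a scaling factor applied to the library size;
2. filters genes by coverage (cpm > 0.5 in more than 3 samples of at least
   one genotype x age group);
3. calls differential expression with a deliberately simple engine (Welch t
   on log2(cpm + 0.5), Benjamini-Hochberg adjustment) and the DEG criteria
   |log2FC| > 1 (strict) and adjusted p < 0.05 (strict); any externally
   produced table with the same columns can be substituted;
4. classifies the wild-type ageing signature: DEGs of the 14-month vs
   4-month comparison that also appear at a younger age are 'genes of the
   ageing heart', those exclusive to 14 months are 'genes of the aged
   heart', and their union is the 'cardiac ageing' set;
5. quantifies how much of a HF-vs-control DEG list that signature explains
   (contribution fraction), tests annotated gene sets for over-
   representation with one-sided Fisher exact tests + BH, and ordinates
   samples by PCA after per-gene rank normalisation.

The same classifier applies verbatim to over-represented process term ids
per age group ('processes of ageing / aged heart').
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix",
    "NormalizationResult",
    "AgeingPartition",
    "PCAResult",
    "normalize_counts",
    "filter_genes",
    "differential_expression",
    "classify_ageing_genes",
    "contribution_fraction",
    "overrepresentation",
    "fisher_enrichment_p",
    "annotation_coverage",
    "ageing_pca",
    "read_gmt",
    "read_counts_tsv",
    "write_counts_tsv",
]

#: DEG thresholds: |log2 fold change| > 1 and BH-adjusted p < 0.05, both strict.
LOGFC_THRESHOLD = 1.0
ADJP_THRESHOLD = 0.05

#: Coverage filter: cpm > 0.5 in (strictly) more than 3 samples of a group.
FILTER_CPM = 0.5
FILTER_MIN_SAMPLES = 3

#: Offset added to cpm before log2, avoiding log(0).
LOG_CPM_OFFSET = 0.5


@dataclass(frozen=True)
class CountMatrix:
    """Raw counts (genes x samples) plus per-sample genotype/age metadata."""

    counts: pd.DataFrame
    samples: pd.DataFrame       # index = sample id; columns: genotype, age

    def __post_init__(self):
        c, s = self.counts, self.samples
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if c.index.has_duplicates or c.columns.has_duplicates:
            raise ValueError("gene and sample ids must be unique")
        if not {"genotype", "age"} <= set(s.columns):
            raise ValueError("sample metadata needs 'genotype' and 'age' columns")
        if list(c.columns) != list(s.index):
            raise ValueError("counts columns and sample metadata rows must match")

    def group_labels(self) -> pd.Series:
        return self.samples["genotype"].astype(str) + ":" + self.samples["age"].astype(str)

    def samples_of(self, genotype, age) -> list:
        s = self.samples
        return list(s.index[(s["genotype"] == genotype) & (s["age"] == age)])


@dataclass(frozen=True)
class NormalizationResult:
    factors: pd.Series          # TMM factors, geometric mean 1
    lib_sizes: pd.Series
    cpm: pd.DataFrame           # against factor-adjusted library sizes
    samples: pd.DataFrame

    def log_cpm(self) -> pd.DataFrame:
        return np.log2(self.cpm + LOG_CPM_OFFSET)


@dataclass(frozen=True)
class AgeingPartition:
    """Ageing/aged split of the oldest-age wild-type DEG set."""

    aged_only: frozenset
    ageing: frozenset

    def __post_init__(self):
        if self.aged_only & self.ageing:
            raise ValueError("aged_only and ageing must be disjoint")
        object.__setattr__(self, "aged_only", frozenset(self.aged_only))
        object.__setattr__(self, "ageing", frozenset(self.ageing))

    @property
    def cardiac_ageing(self) -> frozenset:
        return self.aged_only | self.ageing


@dataclass(frozen=True)
class PCAResult:
    scores: pd.DataFrame            # samples x PCs
    variance_fractions: np.ndarray  # non-increasing, sums to <= 1
    genes_used: tuple


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _tmm_pair(obs, ref, n_obs, n_ref, trim_m=0.30, trim_a=0.05):
    """TMM factor of one sample against the reference: precision-weighted
    mean of M-values after two-sided trimming (30% on M, 5% on A)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (binomial) variance of M; weights are its inverse
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(m)) < 1e-6:        # identical composition
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = stats.rankdata(m)
    rank_a = stats.rankdata(a)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 1.0
    f = np.sum(m[keep] / v[keep]) / np.sum(1.0 / v[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def normalize_counts(cm: CountMatrix) -> NormalizationResult:
    """TMM normalisation with the published defaults.

    The reference is the sample whose 75th percentile of library-scaled
    counts is closest to the mean such percentile; factors are rescaled to
    geometric mean 1; cpm is computed against effective (factor-adjusted)
    library sizes.
    """
    x = cm.counts.to_numpy(dtype=float)
    if x.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = x.sum(axis=0)
    if np.any(lib <= 0):
        bad = list(cm.counts.columns[lib <= 0])
        raise ValueError(f"samples with zero library size: {bad}")

    f75 = np.array([np.quantile(x[:, j] / lib[j], 0.75) for j in range(x.shape[1])])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.array([
        1.0 if j == ref else _tmm_pair(x[:, j], x[:, ref], lib[j], lib[ref])
        for j in range(x.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))

    eff_lib = lib * factors
    cpm = pd.DataFrame(x / eff_lib * 1e6, index=cm.counts.index,
                       columns=cm.counts.columns)
    return NormalizationResult(
        factors=pd.Series(factors, index=cm.counts.columns, name="tmm_factor"),
        lib_sizes=pd.Series(lib, index=cm.counts.columns, name="lib_size"),
        cpm=cpm, samples=cm.samples.copy())


# ---------------------------------------------------------------------------
# Coverage filter
# ---------------------------------------------------------------------------

def filter_genes(norm: NormalizationResult, groups: pd.Series | None = None,
                 min_cpm: float = FILTER_CPM,
                 min_samples: int = FILTER_MIN_SAMPLES) -> pd.Index:
    """Genes with cpm > ``min_cpm`` in strictly more than ``min_samples``
    samples of at least one group (default: genotype x age groups)."""
    if groups is None:
        groups = (norm.samples["genotype"].astype(str) + ":"
                  + norm.samples["age"].astype(str))
    groups = pd.Series(groups, index=norm.cpm.columns)
    passing = norm.cpm > min_cpm
    keep = np.zeros(norm.cpm.shape[0], dtype=bool)
    for _, cols in passing.T.groupby(groups, sort=False):
        keep |= (cols.sum(axis=0) > min_samples).to_numpy()
    return norm.cpm.index[keep]


# ---------------------------------------------------------------------------
# Differential expression (simplified engine)
# ---------------------------------------------------------------------------

def differential_expression(norm: NormalizationResult, group_a, group_b,
                            genes=None, label: str = "A_vs_B") -> pd.DataFrame:
    """Welch-t differential expression on log2(cpm + 0.5).

    logFC is mean(A) - mean(B) (positive = higher in ``group_a``); p-values
    are two-sided Welch t, BH-adjusted within the comparison.  Genes whose
    Welch standard error underflows (zero variance in both groups) get a
    minimal-variance floor and are flagged.  is_deg applies the strict DEG
    criteria |logFC| > 1 and adjusted p < 0.05.
    """
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("both groups need at least 2 samples")
    logcpm = norm.log_cpm()
    if genes is not None:
        logcpm = logcpm.loc[list(genes)]
    xa = logcpm[group_a].to_numpy()
    xb = logcpm[group_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    ma, mb = xa.mean(axis=1), xb.mean(axis=1)
    va = xa.var(axis=1, ddof=1)
    vb = xb.var(axis=1, ddof=1)

    se2 = va / na + vb / nb
    flagged = se2 <= 1e-12
    se2 = np.maximum(se2, 1e-12)
    tstat = (ma - mb) / np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df)
    adj_p = multipletests(p, method="fdr_bh")[1]
    logfc = ma - mb

    return pd.DataFrame({
        "gene": logcpm.index,
        "comparison": label,
        "logFC": logfc,
        "p": p,
        "adj_p": adj_p,
        "is_deg": (np.abs(logfc) > LOGFC_THRESHOLD) & (adj_p < ADJP_THRESHOLD),
        "flagged": flagged,
    }).set_index("gene")


def deg_set(table: pd.DataFrame) -> frozenset:
    """The DEG gene set of a DEG table (any table with an ``is_deg`` column)."""
    return frozenset(table.index[table["is_deg"]])


# ---------------------------------------------------------------------------
# Ageing classification
# ---------------------------------------------------------------------------

def classify_ageing_genes(deg_sets: dict) -> AgeingPartition:
    """Partition the oldest-age DEG set into aged-only and ageing genes.

    ``deg_sets`` maps age (months) to the DEG set of the wild-type
    age-vs-youngest comparison; all of 6, 8, 10, 12 and 14 must be present
    (empty sets are allowed).  Items found only at 14 months are
    'aged_only'; items shared with at least one younger comparison are
    'ageing'.  Works identically on over-represented-process term ids.
    """
    required = {6, 8, 10, 12, 14}
    missing = required - set(deg_sets)
    if missing:
        raise KeyError(f"missing comparisons for ages: {sorted(missing)}")
    oldest = frozenset(deg_sets[14])
    younger = frozenset().union(*(frozenset(deg_sets[a]) for a in (6, 8, 10, 12)))
    return AgeingPartition(aged_only=oldest - younger, ageing=oldest & younger)


def contribution_fraction(partition: AgeingPartition, hf_degs) -> float:
    """Percent of a HF-vs-control DEG list covered by the cardiac-ageing set."""
    hf_degs = frozenset(hf_degs)
    if not hf_degs:
        warnings.warn("empty DEG list: contribution fraction undefined", RuntimeWarning)
        return float("nan")
    return 100.0 * len(partition.cardiac_ageing & hf_degs) / len(hf_degs)


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def fisher_enrichment_p(overlap, n_background, term_size, query_size):
    """One-sided (enrichment) Fisher exact p: the hypergeometric upper tail
    P(X >= overlap) for drawing ``query_size`` genes from a background of
    ``n_background`` containing ``term_size`` term members.  Vectorised."""
    return stats.hypergeom.sf(np.asarray(overlap) - 1, n_background,
                              term_size, query_size)


def overrepresentation(query, background, annotation: dict,
                       alpha: float = ADJP_THRESHOLD,
                       use_adjusted: bool = True) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of annotated terms in a query set.

    Each term is intersected with the background; the one-sided p-value is
    the hypergeometric upper tail P(X >= overlap) of drawing |query| genes
    from the background.  BH adjustment across terms; a term is flagged
    over-represented when the (adjusted, by default) p is below ``alpha``.
    """
    query = frozenset(query)
    background = frozenset(background)
    if not background:
        raise ValueError("background must be non-empty")
    if not query <= background:
        raise ValueError("query must be a subset of the background")
    n_bg, n_q = len(background), len(query)

    rows = []
    for term, genes in annotation.items():
        term_bg = frozenset(genes) & background
        k = len(term_bg & query)
        p = float(fisher_enrichment_p(k, n_bg, len(term_bg), n_q))
        rows.append((term, len(term_bg), k, p))
    out = pd.DataFrame(rows, columns=["term", "term_size", "overlap", "p"]
                       ).set_index("term")
    out["adj_p"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] \
        if len(out) else []
    crit = out["adj_p"] if use_adjusted else out["p"]
    out["over_represented"] = crit < alpha
    return out


def annotation_coverage(background, annotation: dict) -> float:
    """Percent of background genes annotated to at least one term."""
    background = frozenset(background)
    if not background:
        raise ValueError("background must be non-empty")
    annotated = frozenset().union(*map(frozenset, annotation.values())) \
        if annotation else frozenset()
    return 100.0 * len(annotated & background) / len(background)


# ---------------------------------------------------------------------------
# Rank-normalised PCA
# ---------------------------------------------------------------------------

def ageing_pca(data, gene_subset, n_components: int | None = None) -> PCAResult:
    """PCA of samples on a gene subset after per-gene rank normalisation.

    Per gene, expression is ranked across samples (mid-ranks on ties),
    mapped through the inverse normal transform Phi^-1((r - 0.5)/n) and
    standardised; the sample scores come from the SVD of the centred
    samples x genes matrix.  Genes constant across samples carry no rank
    information and are dropped with a warning.
    """
    expr = data.cpm if isinstance(data, NormalizationResult) else data
    genes = [g for g in gene_subset if g in expr.index]
    if len(genes) < 2:
        raise ValueError("need at least 2 genes from the subset present in the data")
    x = expr.loc[genes].to_numpy(dtype=float)       # genes x samples
    n_samp = x.shape[1]
    if n_samp < 3:
        raise ValueError("need at least 3 samples")

    const = np.all(x == x[:, :1], axis=1)
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant gene(s) from the PCA",
                      RuntimeWarning)
        x = x[~const]
        genes = [g for g, c in zip(genes, const) if not c]
    ranks = np.apply_along_axis(stats.rankdata, 1, x)
    z = stats.norm.ppf((ranks - 0.5) / n_samp)
    sd = z.std(axis=1, ddof=0, keepdims=True)
    z = (z - z.mean(axis=1, keepdims=True)) / np.where(sd > 0, sd, 1.0)

    mat = z.T                                       # samples x genes
    mat = mat - mat.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(mat, full_matrices=False)
    var = s ** 2 / (n_samp - 1)
    frac = var / max(var.sum(), np.finfo(float).tiny)
    k = len(s) if n_components is None else min(n_components, len(s))
    scores = pd.DataFrame(u[:, :k] * s[:k], index=expr.columns,
                          columns=[f"PC{i + 1}" for i in range(k)])
    return PCAResult(scores=scores, variance_fractions=frac[:k],
                     genes_used=tuple(genes))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT annotation (term <tab> description <tab> gene...)."""
    out = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3 and parts[0]:
                out[parts[0]] = frozenset(g for g in parts[2:] if g)
    return out


def write_counts_tsv(cm: CountMatrix, counts_path, samples_path):
    cm.counts.to_csv(counts_path, sep="\t", index_label="gene")
    cm.samples.to_csv(samples_path, sep="\t", index_label="sample")


def read_counts_tsv(counts_path, samples_path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col="gene")
    samples = pd.read_csv(samples_path, sep="\t", index_col="sample")
    return CountMatrix(counts=counts, samples=samples)
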