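"""Compositional signatures and enrichment of topologically associated domains.

Genes resident in one TAD tend to share nucleotide composition.  Two
complementary statistics probe this:

* signature tests — for every TAD with enough genes and every composition
  variable, a two-sample Kolmogorov-Smirnov test compares the in-TAD gene
  values with all other genes, Benjamini-Hochberg corrected over all
  (TAD, variable) pairs jointly; a TAD "has a signature" if any q < 0.05;
* group enrichment — for every well-predicted gene group and every TAD, an
  upper-tail hypergeometric test of the group/TAD overlap; the headline
  summary is the fraction of groups with at least one enriched TAD at
  raw p < 0.05 (BH q-values are emitted alongside).

The module also carries two small utilities used around these analyses:
interval densities (e.g. eQTLs or enhancer base pairs per region base
pair) and the Gini coefficient of per-sample expression as an expression
ubiquity measure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .grouping import GeneGroup
from .intervals import GenomicInterval, intersect_length, total_length

logger = logging.getLogger(__name__)


@dataclass
class TadSignature:
    tests: pd.DataFrame  # columns: tad, variable, D, p, q
    flagged_tads: list[str]  # any q < 0.05
    excluded_tads: list[str]  # below the gene-count filter

    @property
    def flag_fraction(self) -> float:
        n_tads = self.tests["tad"].nunique()
        return len(self.flagged_tads) / n_tads if n_tads else float("nan")


@dataclass
class EnrichmentResult:
    tests: pd.DataFrame  # columns: group, tad, k, n, K, N, p, q
    fraction_enriched: float  # groups with >= 1 TAD at raw p < 0.05


def assign_genes_to_tads(
    genes: dict[str, GenomicInterval], tads: dict[str, GenomicInterval]
) -> pd.Series:
    """Gene -> TAD by span midpoint: a gene belongs to the TAD containing it."""
    assignment: dict[str, str] = {}
    for gid, span in genes.items():
        mid = (span.start + span.end) // 2
        for tad_id, tad in tads.items():
            if tad.chrom == span.chrom and tad.start <= mid < tad.end:
                assignment[gid] = tad_id
                break
    return pd.Series(assignment, name="tad")


def tad_signature_tests(
    features: pd.DataFrame,
    tad_membership: pd.Series,
    min_genes: int = 10,
    fdr: float = 0.05,
) -> TadSignature:
    """KS tests of in-TAD vs all-other gene composition, BH-corrected jointly.

    Only TADs containing strictly more than ``min_genes`` member genes (among
    the feature-matrix genes) are tested; smaller TADs are reported as
    excluded.
    """
    membership = tad_membership.reindex(features.index).dropna()
    counts = membership.value_counts()
    qualifying = counts.index[counts > min_genes].tolist()
    excluded = counts.index[counts <= min_genes].tolist()
    if len(qualifying) < 1:
        raise ValueError(f"no TAD passes the > {min_genes} gene filter")

    rows = []
    for tad in qualifying:
        in_genes = membership.index[membership == tad]
        out_genes = features.index.difference(in_genes)
        for var in features.columns:
            a = features.loc[in_genes, var].dropna().to_numpy()
            b = features.loc[out_genes, var].dropna().to_numpy()
            res = stats.ks_2samp(a, b, method="asymp")
            rows.append((tad, var, float(res.statistic), float(res.pvalue)))
    tests = pd.DataFrame(rows, columns=["tad", "variable", "D", "p"])
    tests["q"] = multipletests(tests["p"], method="fdr_bh")[1]
    flagged = sorted(tests.loc[tests["q"] < fdr, "tad"].unique())
    logger.info(
        "TAD signatures: %d/%d TADs flagged at FDR < %g (%d excluded)",
        len(flagged), len(qualifying), fdr, len(excluded),
    )
    return TadSignature(tests=tests, flagged_tads=flagged, excluded_tads=list(excluded))


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def tad_group_enrichment(
    groups: list[GeneGroup],
    tad_membership: pd.Series,
    min_genes: int = 10,
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Upper-tail hypergeometric TAD over-representation within each group."""
    universe = set(tad_membership.index)
    counts = tad_membership.value_counts()
    qualifying = counts.index[counts > min_genes].tolist()
    rows = []
    enriched_groups: set[str] = set()
    kept_groups: list[str] = []
    for group in groups:
        members = set(group.genes) & universe
        if not members:
            logger.warning("group %s has no genes in the TAD universe; skipped", group.group_id)
            continue
        kept_groups.append(group.group_id)
        for tad in qualifying:
            tad_genes = set(tad_membership.index[tad_membership == tad])
            k = len(members & tad_genes)
            p = hypergeom_upper_tail(k, len(universe), len(tad_genes), len(members))
            rows.append((group.group_id, tad, k, len(members), len(tad_genes), len(universe), p))
            if p < alpha:
                enriched_groups.add(group.group_id)
    tests = pd.DataFrame(rows, columns=["group", "tad", "k", "n", "K", "N", "p"])
    tests["q"] = multipletests(tests["p"], method="fdr_bh")[1] if len(tests) else []
    fraction = len(enriched_groups) / len(kept_groups) if kept_groups else float("nan")
    return EnrichmentResult(tests=tests, fraction_enriched=fraction)


def interval_density(
    query: list[GenomicInterval],
    regions: dict[str, list[GenomicInterval]],
    mode: str = "count",
) -> float:
    """Query density per region base pair, pooled over genes.

    ``count`` mode counts query items whose midpoint falls in a gene's
    region intervals (suited to point features such as eQTLs or SNPs);
    ``length`` mode sums intersection lengths (suited to enhancer spans).
    Both are divided by the total region length over all genes.
    """
    denom = sum(total_length(ivs) for ivs in regions.values())
    if denom == 0:
        raise ValueError("total region length is zero; density undefined")
    num = 0.0
    for ivs in regions.values():
        for q in query:
            if mode == "count":
                mid = (q.start + q.end) // 2
                if any(iv.chrom == q.chrom and iv.start <= mid < iv.end for iv in ivs):
                    num += 1
            elif mode == "length":
                num += sum(intersect_length(q, iv) for iv in ivs)
            else:
                raise ValueError(f"unknown density mode {mode!r}")
    return num / denom


def gini(values: np.ndarray | pd.Series) -> float:
    """Gini coefficient of non-negative per-sample expression of one gene.

    The relative mean absolute difference
    ``sum_ij |x_i - x_j| / (2 n^2 mean(x))``: 0 for a gene expressed
    equally in all samples, (n-1)/n for expression in a single sample.
    """
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("Gini coefficient requires non-negative values")
    if x.sum() == 0:
        return float("nan")
    xs = np.sort(x)
    n = x.size
    # identity: sum_ij |x_i - x_j| = 2 * sum_i (2i - n + 1) * xs_i  (0-based i)
    mad_sum = 2.0 * np.sum((2 * np.arange(n) - n + 1) * xs)
    return float(mad_sum / (2 * n * n * xs.mean()))


def error_ubiquity_correlation(
    gini_values: pd.Series, abs_error: pd.Series
) -> dict[str, float]:
    """Spearman correlation of ubiquity vs model error, plus a quartile test.

    Returns the correlation over common genes together with a two-sided
    rank-sum comparison of the errors in the bottom vs top quartile of the
    Gini distribution.
    """
    common = gini_values.index.intersection(abs_error.index)
    if len(common) < 10:
        raise ValueError(f"only {len(common)} common genes; need >= 10")
    g = gini_values.loc[common]
    e = abs_error.loc[common]
    rho = float(stats.spearmanr(g, e).statistic)
    q1, q3 = g.quantile(0.25), g.quantile(0.75)
    low, high = e[g <= q1], e[g >= q3]
    test = stats.mannwhitneyu(low, high, alternative="two-sided")
    return {
        "spearman_rho": rho,
        "ranksum_stat": float(test.statistic),
        "ranksum_p": float(test.pvalue),
    }
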