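"""Pairwise two-locus LD: D, D', r, r², exact-test significance, grids.

For every pair of usable biallelic sites the 2x2 haplotype table is formed
(allele "A"/"B" = the alphabetically first state at each site, a
deterministic labeling), LD statistics are computed from haplotype and
allele frequencies, and two-tailed significance is assessed with Fisher's
exact test under the probability-mass convention, Bonferroni-corrected
within the gene x species dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alignment_io import (
    USABLE_BIALLELIC,
    HaplotypeAlignment,
    SiteTable,
    extract_sites,
)
from .errors import FilterError, InsufficientDataError, UndefinedStatisticError


@dataclass(frozen=True)
class TwoLocusTable:
    """Haplotype counts for allele combinations (A,B), (A,b), (a,B), (a,b)."""

    site_i: int
    site_j: int
    allele_a: str  # "A": alphabetically first state at site_i
    allele_b: str  # "B": alphabetically first state at site_j
    n11: int
    n12: int
    n21: int
    n22: int

    @property
    def n(self) -> int:
        return self.n11 + self.n12 + self.n21 + self.n22

    def as_array(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


@dataclass(frozen=True)
class PairwiseLD:
    site_i: int
    site_j: int
    distance: int
    D: float
    d_prime: float
    r: float
    r2: float
    fisher_p: float
    significant_nominal: bool
    significant_bonferroni: bool


@dataclass(frozen=True)
class ScanSummary:
    """Per-dataset roll-up mirroring one cell of a pair-count table."""

    gene_id: str
    species_id: str
    n_sequences: int
    n_usable_sites: int
    n_pairs: int
    n_significant_nominal: int
    n_significant_bonferroni: int
    mean_r2: float  # nan when n_pairs == 0
    sd_r2: float  # nan when n_pairs < 2
    alpha: float

    @property
    def bonferroni_alpha(self) -> float:
        return self.alpha / self.n_pairs if self.n_pairs else float("nan")

    def to_dict(self) -> dict:
        return {
            "gene": self.gene_id,
            "species": self.species_id,
            "n": self.n_sequences,
            "n_usable_sites": self.n_usable_sites,
            "n_pairs": self.n_pairs,
            "n_sig_bonferroni": self.n_significant_bonferroni,
            "n_sig_nominal": self.n_significant_nominal,
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
        }


def two_locus_counts(
    aln: HaplotypeAlignment,
    site_i: int,
    site_j: int,
    site_table: SiteTable | None = None,
) -> TwoLocusTable:
    """2x2 haplotype table for two usable biallelic sites.

    Haplotypes with a gap/N at either site are excluded pairwise (cannot
    occur for usable sites under the default filter but matters if the
    filter is relaxed).
    """
    if site_table is None:
        site_table = extract_sites(aln)
    for s in (site_i, site_j):
        if site_table.site(s).site_class != USABLE_BIALLELIC:
            raise FilterError(
                f"site {s} is {site_table.site(s).site_class}, not usable_biallelic"
            )
    col_i = aln.column(site_i)
    col_j = aln.column(site_j)
    allele_a = min(site_table.site(site_i).alleles)
    allele_b = min(site_table.site(site_j).alleles)
    n11 = n12 = n21 = n22 = 0
    for x, y in zip(col_i, col_j):
        if x not in "ACGT" or y not in "ACGT":
            continue
        if x == allele_a:
            if y == allele_b:
                n11 += 1
            else:
                n12 += 1
        else:
            if y == allele_b:
                n21 += 1
            else:
                n22 += 1
    return TwoLocusTable(site_i, site_j, allele_a, allele_b, n11, n12, n21, n22)


def ld_stats(table: TwoLocusTable) -> tuple[float, float, float, float]:
    """(D, D', r, r²) from a two-locus haplotype table.

    D = p_AB - p_A p_B; D' = |D| / D_max with the usual frequency bound;
    r = D / sqrt(p_A p_a p_B p_b); r² = r².  Raises
    :class:`UndefinedStatisticError` if either margin is monomorphic.
    """
    n = table.n
    if n == 0:
        raise UndefinedStatisticError("empty two-locus table")
    p_a = (table.n11 + table.n12) / n
    p_b = (table.n11 + table.n21) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise UndefinedStatisticError("monomorphic margin; LD undefined")
    p_ab = table.n11 / n
    D = p_ab - p_a * p_b
    if D > 0:
        d_max = min(p_a * (1 - p_b), (1 - p_a) * p_b)
    else:
        d_max = min(p_a * p_b, (1 - p_a) * (1 - p_b))
    d_prime = abs(D) / d_max if d_max > 0 else 0.0
    r = D / math.sqrt(p_a * (1 - p_a) * p_b * (1 - p_b))
    return D, d_prime, r, r * r


def fisher_exact_2x2(table: TwoLocusTable, method: str = "probability") -> float:
    """Two-tailed Fisher exact p for a 2x2 haplotype table.

    ``method='probability'`` (default) sums hypergeometric probabilities of
    all margin-fixed tables whose point probability does not exceed the
    observed table's; ``method='doubling'`` doubles the smaller one-tailed
    probability (capped at 1).
    """
    arr = table.as_array()
    if method == "probability":
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    if method == "doubling":
        n = table.n
        row1 = table.n11 + table.n12
        col1 = table.n11 + table.n21
        hg = stats.hypergeom(n, row1, col1)
        lower = hg.cdf(table.n11)
        upper = hg.sf(table.n11 - 1)
        return float(min(1.0, 2.0 * min(lower, upper)))
    raise ValueError(f"unknown two-tailed method {method!r}")


def pairwise_ld_scan(
    aln: HaplotypeAlignment,
    alpha: float = 0.05,
    site_table: SiteTable | None = None,
    drop_singletons: bool = False,
    compute_fisher: bool = True,
    fisher_method: str = "probability",
) -> tuple[list[PairwiseLD], ScanSummary]:
    """All-pairs LD over the usable sites of one dataset.

    The Bonferroni family is the k(k-1)/2 tests of this dataset; the
    corrected threshold is ``alpha / n_pairs``.  With fewer than two usable
    sites the summary reports 0 pairs and NA means (a monomorphic dataset
    is a valid, degenerate outcome, not an error).
    """
    if site_table is None:
        site_table = extract_sites(aln)
    cols = site_table.usable_columns(drop_singletons=drop_singletons)
    k = len(cols)
    n_pairs = k * (k - 1) // 2
    if n_pairs == 0:
        summary = ScanSummary(
            aln.gene_id, aln.species_id, aln.n, k, 0, 0, 0,
            float("nan"), float("nan"), alpha,
        )
        return [], summary

    # 0/1 coding: 1 where the haplotype carries the alphabetically first allele
    first_allele = {c: min(site_table.site(c).alleles) for c in cols}
    X = np.empty((aln.n, k), dtype=float)
    for idx, c in enumerate(cols):
        col = aln.column(c)
        X[:, idx] = [1.0 if ch == first_allele[c] else 0.0 for ch in col]
    n = aln.n
    p = X.mean(axis=0)
    p_ab = (X.T @ X) / n
    bonf = alpha / n_pairs

    pairs: list[PairwiseLD] = []
    for ii, jj in itertools.combinations(range(k), 2):
        pa, pb = p[ii], p[jj]
        D = p_ab[ii, jj] - pa * pb
        if D > 0:
            d_max = min(pa * (1 - pb), (1 - pa) * pb)
        else:
            d_max = min(pa * pb, (1 - pa) * (1 - pb))
        d_prime = abs(D) / d_max if d_max > 0 else 0.0
        r = D / math.sqrt(pa * (1 - pa) * pb * (1 - pb))
        r2 = r * r
        if compute_fisher:
            n11 = int(round(p_ab[ii, jj] * n))
            n12 = int(round(pa * n)) - n11
            n21 = int(round(pb * n)) - n11
            n22 = n - n11 - n12 - n21
            tab = TwoLocusTable(cols[ii], cols[jj], "", "", n11, n12, n21, n22)
            pval = fisher_exact_2x2(tab, method=fisher_method)
        else:
            pval = float("nan")
        sig_nom = bool(pval < alpha) if compute_fisher else False
        sig_bon = bool(pval < bonf) if compute_fisher else False
        pairs.append(
            PairwiseLD(
                site_i=cols[ii], site_j=cols[jj], distance=cols[jj] - cols[ii],
                D=D, d_prime=d_prime, r=r, r2=r2, fisher_p=pval,
                significant_nominal=sig_nom, significant_bonferroni=sig_bon,
            )
        )
    r2s = np.array([pr.r2 for pr in pairs])
    summary = ScanSummary(
        gene_id=aln.gene_id,
        species_id=aln.species_id,
        n_sequences=aln.n,
        n_usable_sites=k,
        n_pairs=n_pairs,
        n_significant_nominal=sum(pr.significant_nominal for pr in pairs),
        n_significant_bonferroni=sum(pr.significant_bonferroni for pr in pairs),
        mean_r2=float(r2s.mean()),
        sd_r2=float(r2s.std(ddof=1)) if n_pairs > 1 else float("nan"),
        alpha=alpha,
    )
    return pairs, summary


def filter_pairs_by_maf(
    pairs: list[PairwiseLD],
    site_table: SiteTable,
    n: int,
    min_maf: float = 0.1,
) -> list[PairwiseLD]:
    """Pairs whose two sites both have minor-allele frequency >= ``min_maf``.

    Rare alleles bound r² far below 1 whatever the recombination distance,
    which biases decay-curve fitting; restricting the fit to common variants
    is the standard practice.  The full pair list (and all pair counts)
    remain unfiltered.
    """
    min_count = math.ceil(min_maf * n)
    ok = set()
    for s in site_table.sites:
        if s.site_class != USABLE_BIALLELIC:
            continue
        minor = min(c for a, c in s.counts if a in "ACGT")
        if minor >= min_count:
            ok.add(s.column)
    return [p for p in pairs if p.site_i in ok and p.site_j in ok]


def pairs_to_frame(pairs: list[PairwiseLD]) -> pd.DataFrame:
    cols = [
        "site_i", "site_j", "distance_bp", "D", "D_prime", "r", "r2",
        "fisher_p", "sig_nominal", "sig_bonferroni",
    ]
    rows = [
        {
            "site_i": p.site_i, "site_j": p.site_j, "distance_bp": p.distance,
            "D": p.D, "D_prime": p.d_prime, "r": p.r, "r2": p.r2,
            "fisher_p": p.fisher_p, "sig_nominal": p.significant_nominal,
            "sig_bonferroni": p.significant_bonferroni,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=cols)


@dataclass
class LDGrid:
    """Symmetric r² matrix over usable sites plus detected haploblocks.

    ``blocks`` lists maximal runs of consecutive usable sites whose
    within-run pairwise r² all reach the block threshold; each block spans
    >= 2 sites and blocks are disjoint.
    """

    site_columns: tuple[int, ...]
    matrix: np.ndarray  # diagonal = 1 by convention
    block_r2_threshold: float
    blocks: list[tuple[int, int]]  # inclusive (first, last) site indices

    def block_spans_bp(self) -> list[int]:
        return [
            self.site_columns[b] - self.site_columns[a] for a, b in self.blocks
        ]

    def to_frame(self) -> pd.DataFrame:
        labels = [str(c) for c in self.site_columns]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def build_grid(
    pairs: list[PairwiseLD], block_r2_threshold: float = 0.8
) -> LDGrid:
    """Assemble the r² matrix over usable sites and detect haploblocks."""
    if not pairs:
        raise InsufficientDataError("need >= 2 usable sites (>= 1 pair) for a grid")
    cols = sorted({p.site_i for p in pairs} | {p.site_j for p in pairs})
    index = {c: i for i, c in enumerate(cols)}
    k = len(cols)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for p in pairs:
        i, j = index[p.site_i], index[p.site_j]
        mat[i, j] = mat[j, i] = p.r2

    blocks: list[tuple[int, int]] = []
    start = 0
    while start < k - 1:
        end = start
        while end + 1 < k and all(
            mat[a, end + 1] >= block_r2_threshold for a in range(start, end + 1)
        ):
            end += 1
        if end > start:
            blocks.append((start, end))
            start = end + 1
        else:
            start += 1
    return LDGrid(
        site_columns=tuple(cols),
        matrix=mat,
        block_r2_threshold=block_r2_threshold,
        blocks=blocks,
    )
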