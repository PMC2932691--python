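"""Two-dimensional annotation distribution analysis.

Each annotation term (GO/KEGG/CORUM set, or the chromosome of the encoding
gene as a pseudo-term) splits the matched proteins into members and
complement. A rank-based two-sample test asks whether the members are
shifted in the joint (copy log2, protein log2) space: per dimension the
standardized, tie-corrected Mann-Whitney U statistic z_d is computed, and
z_1^2 + z_2^2 is referred to a chi-square distribution with 2 degrees of
freedom (exact under independence of the dimensions and large n; an exact
label-permutation p-value is available as an alternative). Benjamini-
Hochberg controls the FDR over terms at 5%. Per dimension a difference
score rescales the members' mean rank to [-1, 1]: 1 means all members are
the largest values, 0 means they are distributed like the background, -1
means all are the smallest.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

__all__ = [
    "rank_dimensions",
    "mannwhitney_2d",
    "score_2d",
    "bh_adjust",
    "chromosome_terms",
    "run_annotation_analysis",
    "plot_scores",
]


def rank_dimensions(matched: pd.DataFrame,
                    dims: tuple[str, str] = ("copy_log2", "protein_log2")) -> pd.DataFrame:
    """Ascending 1..n ranks per dimension, ties averaged."""
    if len(matched) < 2:
        raise ValueError("need at least 2 genes to rank")
    out = pd.DataFrame(index=matched.index)
    for d in dims:
        out[d] = stats.rankdata(matched[d].to_numpy(float))
    return out


def _tie_term(ranks: np.ndarray) -> float:
    """sum(t^3 - t) over tied groups, from the rank multiset."""
    _, counts = np.unique(ranks, return_counts=True)
    t = counts[counts > 1].astype(float)
    return float(np.sum(t ** 3 - t))


def _mw_z(rank_sum: float, m: int, n: int, tie_term: float) -> float:
    """Standardized Mann-Whitney U for the member group, tie-corrected."""
    u = rank_sum - m * (m + 1) / 2.0
    mu = m * (n - m) / 2.0
    var = m * (n - m) / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return 0.0
    return (u - mu) / np.sqrt(var)


def mannwhitney_2d(member_mask: np.ndarray, ranks: pd.DataFrame) -> tuple[float, float, float]:
    """(z_copy, z_protein, p) for one term.

    p refers z_1^2 + z_2^2 to chi-square with 2 df; two-sided by
    construction.
    """
    n = len(ranks)
    m = int(member_mask.sum())
    if not 0 < m < n:
        raise ValueError("term must be a proper nonempty subset")
    zs = []
    for d in ranks.columns:
        r = ranks[d].to_numpy()
        zs.append(_mw_z(r[member_mask].sum(), m, n, _tie_term(r)))
    p = float(stats.chi2.sf(zs[0] ** 2 + zs[1] ** 2, df=2))
    return zs[0], zs[1], p


def score_2d(member_mask: np.ndarray, ranks_1d: np.ndarray) -> float:
    """Rescaled mean rank of the members in one dimension, in [-1, 1].

    score = (meanRank_members - (n+1)/2) / ((n-m)/2): the affine map sending
    the background mean rank to 0 and the all-at-top configuration to 1 (and
    all-at-bottom to -1).
    """
    n = len(ranks_1d)
    m = int(member_mask.sum())
    if not 0 < m < n:
        raise ValueError("score undefined for empty or full member set")
    mean_rank = float(np.mean(ranks_1d[member_mask]))
    return (mean_rank - (n + 1) / 2.0) / ((n - m) / 2.0)


def bh_adjust(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, significant-at-alpha mask)."""
    p = np.asarray(p_values, float)
    if len(p) == 0:
        return np.array([]), np.array([], bool)
    reject, q, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return q, reject


def chromosome_terms(matched: pd.DataFrame) -> dict[str, tuple[str, ...]]:
    """Chromosome pseudo-terms: each chromosome's genes as one annotation."""
    return {f"chr{chrom}": tuple(sub["gene"])
            for chrom, sub in matched.groupby("chromosome", sort=False)}


def _permutation_p(ranks: pd.DataFrame, m: int, observed_stat: float,
                   tie_terms: list[float], n_permutations: int,
                   rng: np.random.Generator) -> float:
    n = len(ranks)
    rank_arrays = [ranks[d].to_numpy() for d in ranks.columns]
    count = 0
    for _ in range(n_permutations):
        idx = rng.choice(n, size=m, replace=False)
        stat = 0.0
        for r, tt in zip(rank_arrays, tie_terms):
            stat += _mw_z(r[idx].sum(), m, n, tt) ** 2
        if stat >= observed_stat:
            count += 1
    return (count + 1) / (n_permutations + 1)


def run_annotation_analysis(matched: pd.DataFrame,
                            term_sources: Mapping[str, Mapping[str, Sequence[str]]],
                            min_category_size: int = 5, fdr: float = 0.05,
                            include_chromosomes: bool = True,
                            dims: tuple[str, str] = ("copy_log2", "protein_log2"),
                            method: str = "analytic", n_permutations: int = 10_000,
                            seed: int = 0) -> pd.DataFrame:
    """Test every annotation term for a 2D shift; BH-adjust over terms.

    ``term_sources`` maps a source label (GOBP, CORUM, ...) to its term
    mapping {term_id: genes}. Terms are intersected with the matched gene
    universe and kept when min_category_size <= m <= n - min_category_size.
    Chromosome pseudo-terms are added unless disabled. Returns one row per
    retained term, ordered by q-value: term_id, source, n_members, z and
    score per dimension, p_value, q_value, significant.
    """
    n = len(matched)
    if n < 2 * min_category_size:
        log.warning("run_annotation_analysis: only %d matched genes; no testable terms", n)
        return _empty_result()
    ranks = rank_dimensions(matched, dims)
    gene_index = {g: i for i, g in enumerate(matched["gene"])}
    sources = dict(term_sources)
    if include_chromosomes:
        sources["chromosome"] = chromosome_terms(matched)

    rng = np.random.default_rng(seed)
    tie_terms = [_tie_term(ranks[d].to_numpy()) for d in ranks.columns]
    rows = []
    for source, terms in sources.items():
        for term_id, members in terms.items():
            idx = [gene_index[g] for g in set(members) if g in gene_index]
            m = len(idx)
            if m < min_category_size or m > n - min_category_size:
                log.debug("term %s skipped (m=%d outside bounds)", term_id, m)
                continue
            mask = np.zeros(n, bool)
            mask[idx] = True
            z1, z2, p = mannwhitney_2d(mask, ranks)
            if method == "permutation":
                p = _permutation_p(ranks, m, z1 ** 2 + z2 ** 2, tie_terms,
                                   n_permutations, rng)
            rows.append((term_id, source, m, z1, z2,
                         score_2d(mask, ranks[dims[0]].to_numpy()),
                         score_2d(mask, ranks[dims[1]].to_numpy()), p))
    if not rows:
        log.warning("run_annotation_analysis: no terms retained")
        return _empty_result()
    out = pd.DataFrame(rows, columns=["term_id", "source", "n_members", "z_genome",
                                      "z_proteome", "score_genome", "score_proteome",
                                      "p_value"])
    q, sig = bh_adjust(out["p_value"].to_numpy(), alpha=fdr)
    out["q_value"] = q
    out["significant"] = sig
    return out.sort_values(["q_value", "p_value"], ignore_index=True)


def _empty_result() -> pd.DataFrame:
    return pd.DataFrame(columns=["term_id", "source", "n_members", "z_genome",
                                 "z_proteome", "score_genome", "score_proteome",
                                 "p_value", "q_value", "significant"])


def plot_scores(results: pd.DataFrame, path: str | Path,
                significant_only: bool = True) -> None:
    """2D scatter of (score_genome, score_proteome) colored by source."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = results[results["significant"]] if significant_only else results
    fig, ax = plt.subplots(figsize=(6, 6))
    for source, sub in df.groupby("source"):
        ax.scatter(sub["score_genome"], sub["score_proteome"], s=18, alpha=0.8, label=source)
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-1.05, 1.05)
    ax.set_xlabel("annotation score, genome dimension")
    ax.set_ylabel("annotation score, proteome dimension")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
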