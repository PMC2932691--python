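"""Genome profiling: regional amplification/deletion calls from protein log-ratios.

Proteins are ordered along each chromosome and scanned with windows of 3
up to the whole chromosome in multiplicative steps of sqrt(2), stride one
gene. Each window's mean is tested against zero with a one-sample t-test.
Because a small p-value means something very different for a 3-protein
window than for a chromosome-sized one, p-values are converted to posterior
error probabilities (PEP) per window-size stratum by Bayes' rule on
histograms of observed versus permutation-null log10 p-values (the null is
built from randomized genomes: the gene ordering is kept, the log-ratio
values are shuffled genome-wide). A permutation-estimated FDR threshold
(default 2%) selects significant windows. The final profile assigns each
gene position the median of the intersecting significant window whose
median deviates most from zero, and zero where no significant window
intersects; exponentiating and multiplying by two turns profile values into
copy-number estimates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "window_sizes",
    "scan_chromosome",
    "randomize_genome",
    "pep_transform",
    "significance_threshold",
    "build_profile",
    "profile_to_copy_number",
    "profiled_correlation",
    "genome_profile",
    "profile_segments",
    "write_bed",
    "segment_recovery",
    "ProfileResult",
]

#: p assigned to zero-variance windows with nonzero mean
_MIN_P = np.finfo(float).tiny
_SQRT2 = np.sqrt(2.0)


def window_sizes(chromosome_length: int) -> list[int]:
    """Window sizes 3..chromosome length in steps of factors of sqrt(2).

    Sizes are round(3 * sqrt(2)**k), deduplicated, capped at the chromosome
    length, which is always included as the final size.
    """
    if chromosome_length < 3:
        raise ValueError("chromosome must hold at least 3 proteins")
    sizes: list[int] = []
    k = 0
    while True:
        s = int(np.floor(3.0 * _SQRT2 ** k + 0.5))
        if s >= chromosome_length:
            break
        if not sizes or s != sizes[-1]:
            sizes.append(s)
        k += 1
    sizes.append(chromosome_length)
    return sizes


def scan_chromosome(values: np.ndarray, sizes: list[int] | None = None) -> pd.DataFrame:
    """All window tests for one chromosome's ordered log2 ratios.

    Returns one row per (size, start) with half-open gene-index bounds, the
    window mean and median, and the two-sided one-sample t-test p-value of
    the mean against zero. Zero-variance windows get p=1 when the mean is
    zero and the minimal representable p otherwise.
    """
    values = np.asarray(values, float)
    n = len(values)
    if sizes is None:
        sizes = window_sizes(n)
    frames = []
    for s in sizes:
        if s > n:
            continue
        win = sliding_window_view(values, s)
        mean = win.mean(axis=1)
        sd = win.std(axis=1, ddof=1)
        med = np.median(win, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / (sd / np.sqrt(s))
        p = np.empty_like(mean)
        ok = sd > 0
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df=s - 1)
        p[~ok] = np.where(mean[~ok] == 0.0, 1.0, _MIN_P)
        starts = np.arange(n - s + 1)
        frames.append(pd.DataFrame({
            "start": starts, "end": starts + s, "size": s,
            "mean": mean, "median": med, "p_value": np.maximum(p, _MIN_P),
        }))
    return pd.concat(frames, ignore_index=True)


def randomize_genome(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomized genome: values permuted genome-wide, ordering preserved."""
    return rng.permutation(np.asarray(values, float))


def _stratum_bin_pep(obs_logp: np.ndarray, null_logp: np.ndarray,
                     n_permutations: int, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges and monotone PEP per bin for one window-size stratum.

    pep(bin) = min(1, pi0 * f_null / f_obs) with pi0 = 1, f_null the
    per-permutation mean count and f_obs the observed count in the bin.
    Both counts carry a half-count pseudo-observation so that a sparse bin
    with zero permuted windows cannot claim a PEP of exactly zero (with 10
    permutations a zero null count only bounds the null rate, it does not
    establish it). Bins with no observed windows are interpolated from
    neighboring filled bins (flat extension at the ends); finally PEP is
    made non-increasing in -log10 p (running minimum from the large-p end),
    so a smaller p never has a larger PEP.
    """
    lo = min(obs_logp.min(), null_logp.min()) if len(null_logp) else obs_logp.min()
    hi = max(obs_logp.max(), null_logp.max()) if len(null_logp) else obs_logp.max()
    if hi - lo < 1e-9:  # degenerate: all p identical
        ratio = ((len(null_logp) + 0.5) / n_permutations) / (max(len(obs_logp), 1) + 0.5)
        return np.array([lo - 0.5, hi + 0.5]), np.array([min(1.0, ratio)])
    edges = np.linspace(lo, hi, n_bins + 1)
    obs_cnt = np.histogram(obs_logp, bins=edges)[0]
    null_cnt = np.histogram(null_logp, bins=edges)[0]
    pep = np.where(obs_cnt > 0,
                   np.minimum(1.0, ((null_cnt + 0.5) / n_permutations) / (obs_cnt + 0.5)),
                   np.nan)
    if np.isnan(pep).all():
        pep = np.ones_like(pep)
    elif np.isnan(pep).any():
        centers = (edges[:-1] + edges[1:]) / 2.0
        filled = ~np.isnan(pep)
        pep = np.interp(centers, centers[filled], pep[filled])
    # monotone: iterate from the largest p (last bin) downward
    pep = np.minimum.accumulate(pep[::-1])[::-1]
    return edges, pep


def pep_transform(observed: pd.DataFrame, null: pd.DataFrame, n_permutations: int,
                  n_bins: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Posterior error probabilities for observed and null windows.

    Windows are binned on (log10 p, window size): one stratum per distinct
    size (sizes are already discrete), 20 log10-p bins per stratum. Returns
    PEP arrays aligned with ``observed`` and ``null`` rows.
    """
    obs_pep = np.ones(len(observed))
    null_pep = np.ones(len(null))
    obs_logp_all = np.log10(observed["p_value"].to_numpy())
    null_logp_all = np.log10(null["p_value"].to_numpy())
    obs_sizes = observed["size"].to_numpy()
    null_sizes = null["size"].to_numpy()
    for s in np.unique(obs_sizes):
        o_idx = obs_sizes == s
        n_idx = null_sizes == s
        edges, pep = _stratum_bin_pep(obs_logp_all[o_idx], null_logp_all[n_idx],
                                      n_permutations, n_bins)
        nb = len(pep)
        o_bin = np.clip(np.digitize(obs_logp_all[o_idx], edges) - 1, 0, nb - 1)
        obs_pep[o_idx] = pep[o_bin]
        if n_idx.any():
            n_bin = np.clip(np.digitize(null_logp_all[n_idx], edges) - 1, 0, nb - 1)
            null_pep[n_idx] = pep[n_bin]
    return obs_pep, null_pep


def significance_threshold(obs_pep: np.ndarray, null_pep: np.ndarray,
                           n_permutations: int, fdr: float = 0.02,
                           ) -> tuple[float, np.ndarray]:
    """Largest PEP cutoff controlling the permutation-estimated window FDR.

    FDR(t) = (mean permuted windows with pep <= t) / (observed windows with
    pep <= t), with the usual finite-permutation correction: the numerator
    counts one extra pseudo-permutation hit, (k + 1) / (B + 1), since zero
    hits among B permutations bounds the null rate rather than establishing
    it. Returns the cutoff and the boolean significant mask; if no cutoff
    achieves the target (or fdr <= 0), the set is empty.
    """
    if fdr <= 0 or len(obs_pep) == 0:
        return float("nan"), np.zeros(len(obs_pep), bool)
    cand = np.unique(obs_pep)
    obs_counts = np.searchsorted(np.sort(obs_pep), cand, side="right")
    null_counts = (np.searchsorted(np.sort(null_pep), cand, side="right") + 1.0) \
        / (n_permutations + 1.0)
    est = null_counts / np.maximum(obs_counts, 1)
    ok = est <= fdr
    if not ok.any():
        return float("nan"), np.zeros(len(obs_pep), bool)
    cutoff = float(cand[np.nonzero(ok)[0].max()])
    return cutoff, obs_pep <= cutoff


def build_profile(significant: pd.DataFrame, chromosome_lengths: dict[str, int],
                  ) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Aberration profile per chromosome from the significant window set.

    For every gene position the value is the median of the intersecting
    significant window whose median deviates most from zero (ties go to the
    smaller window); positions intersected by no significant window are
    exactly zero. Returns {chromosome: (values, window_row_labels)} where the
    label is the ``significant`` row index of the contributing window, -1
    for none.
    """
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, length in chromosome_lengths.items():
        values = np.zeros(length)
        best_abs = np.zeros(length)
        best_size = np.full(length, np.iinfo(np.int64).max)
        win_id = np.full(length, -1)
        if len(significant):
            sub = significant[significant["chromosome"] == chrom]
            for row in sub.itertuples():
                sl = slice(row.start, row.end)
                absmed = abs(row.median)
                better = (absmed > best_abs[sl]) | (
                    (absmed == best_abs[sl]) & (row.size < best_size[sl]) & (win_id[sl] != -1))
                if absmed > 0:
                    idx = np.nonzero(better)[0] + row.start
                    values[idx] = row.median
                    best_abs[idx] = absmed
                    best_size[idx] = row.size
                    win_id[idx] = row.Index
                else:
                    # a significant window with median exactly 0 still marks
                    # coverage; value stays 0 but the window is recorded
                    idx = np.nonzero(win_id[sl] == -1)[0] + row.start
                    win_id[idx] = row.Index
                    best_size[idx] = np.minimum(best_size[idx], row.size)
        out[chrom] = (values, win_id)
    return out


def profile_to_copy_number(profile_value):
    """Copy-number estimate from a profile log2 value: 2 * 2**value."""
    return 2.0 * 2.0 ** np.asarray(profile_value, float)


def profiled_correlation(profile_values, copy_log2) -> float:
    """Pearson correlation of the aberration profile with copy log2 ratios."""
    x = np.asarray(profile_values, float)
    y = np.asarray(copy_log2, float)
    if len(x) < 3 or np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("profiled correlation undefined: zero variance", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def _chromosome_sort_key(chrom: str):
    s = str(chrom)
    return (0, int(s)) if s.isdigit() else (1, s)


@dataclass
class ProfileResult:
    """Output of :func:`genome_profile`.

    ``profile`` has one row per matched gene in chromosomal order with the
    profile log2 value (0 where nothing significant intersects), the implied
    copy-number estimate, and the row label of the contributing window in
    ``windows`` (-1 for none). ``windows`` holds every tested observed
    window with its p-value, PEP and significance flag.
    """

    profile: pd.DataFrame
    windows: pd.DataFrame
    pep_cutoff: float
    n_permutations: int
    fdr: float

    @property
    def significant_windows(self) -> pd.DataFrame:
        return self.windows[self.windows["significant"]]


def genome_profile(matched: pd.DataFrame, value_col: str = "protein_log2",
                   fdr: float = 0.02, n_permutations: int = 10, seed: int = 0,
                   center: bool = True, n_bins: int = 20) -> ProfileResult:
    """Run the full profiling algorithm on a matched (or protein-only) table.

    ``matched`` needs gene, chromosome, position and ``value_col`` columns.
    Chromosomes with fewer than 3 genes are skipped with a warning. The
    log-ratio track is median-centered genome-wide before scanning unless
    ``center=False``.
    """
    df = matched.sort_values(["chromosome", "position"],
                             key=lambda s: s.map(_chromosome_sort_key) if s.name == "chromosome" else s,
                             kind="stable").reset_index(drop=True)
    values = df[value_col].to_numpy(float)
    if center and len(values):
        values = values - np.median(values)

    chroms: list[str] = []
    tracks: list[np.ndarray] = []
    keep_rows = []
    for chrom, sub in df.groupby("chromosome", sort=False):
        if len(sub) < 3:
            log.warning("genome_profile: chromosome %s has %d proteins (<3), skipped",
                        chrom, len(sub))
            continue
        chroms.append(str(chrom))
        tracks.append(values[sub.index.to_numpy()])
        keep_rows.append(sub.index.to_numpy())
    if not chroms:
        raise ValueError("no chromosome with at least 3 proteins")
    lengths = {c: len(t) for c, t in zip(chroms, tracks)}
    sizes = {c: window_sizes(n) for c, n in lengths.items()}

    def scan_all(track_by_chrom: list[np.ndarray]) -> pd.DataFrame:
        parts = []
        for chrom, track in zip(chroms, track_by_chrom):
            w = scan_chromosome(track, sizes[chrom])
            w.insert(0, "chromosome", chrom)
            parts.append(w)
        return pd.concat(parts, ignore_index=True)

    observed = scan_all(tracks)

    rng = np.random.default_rng(seed)
    concat = np.concatenate(tracks)
    bounds = np.cumsum([0] + [len(t) for t in tracks])
    null_parts = []
    for _ in range(n_permutations):
        perm = randomize_genome(concat, rng)
        null_parts.append(scan_all([perm[bounds[i]:bounds[i + 1]] for i in range(len(tracks))]))
    null = pd.concat(null_parts, ignore_index=True)

    obs_pep, null_pep = pep_transform(observed, null, n_permutations, n_bins=n_bins)
    observed["pep"] = obs_pep
    cutoff, sig = significance_threshold(obs_pep, null_pep, n_permutations, fdr)
    observed["significant"] = sig
    log.info("genome_profile: %d/%d windows significant at FDR %.3g (pep cutoff %.3g)",
             int(sig.sum()), len(observed), fdr, cutoff)

    per_chrom = build_profile(observed[sig], lengths)
    prof_values = np.zeros(len(df))
    prof_win = np.full(len(df), -1)
    for chrom, rows in zip(chroms, keep_rows):
        vals, wid = per_chrom[chrom]
        prof_values[rows] = vals
        prof_win[rows] = wid
    profile = df[["gene", "chromosome", "position"]].copy()
    profile["profile_log2"] = prof_values
    profile["copy_number_estimate"] = profile_to_copy_number(prof_values)
    profile["window_id"] = prof_win
    if value_col in df.columns:
        profile[value_col] = df[value_col]
    return ProfileResult(profile=profile, windows=observed, pep_cutoff=cutoff,
                         n_permutations=n_permutations, fdr=fdr)


def profile_segments(profile: pd.DataFrame) -> pd.DataFrame:
    """Merged aberrant segments: maximal same-sign nonzero runs of the profile.

    Returns chromosome, gene-index bounds (half-open), base-pair bounds
    (0-based half-open), direction (amp/del) and the maximal |profile| value.
    """
    rows = []
    for chrom, sub in profile.groupby("chromosome", sort=False):
        sub = sub.sort_values("position")
        vals = sub["profile_log2"].to_numpy()
        pos = sub["position"].to_numpy()
        sign = np.sign(vals)
        i = 0
        while i < len(vals):
            if sign[i] == 0:
                i += 1
                continue
            j = i
            while j + 1 < len(vals) and sign[j + 1] == sign[i]:
                j += 1
            rows.append((str(chrom), i, j + 1, int(pos[i]) - 1, int(pos[j]),
                         "amp" if sign[i] > 0 else "del",
                         float(np.abs(vals[i:j + 1]).max())))
            i = j + 1
    return pd.DataFrame(rows, columns=["chromosome", "start_index", "end_index",
                                       "start", "end", "direction", "max_abs_log2"])


def write_bed(segments: pd.DataFrame, path: str | Path) -> None:
    """Write merged segments as BED (0-based half-open; score = |log2|*1000,
    capped at 1000)."""
    with open(path, "w") as fh:
        for row in segments.itertuples():
            score = int(min(1000, round(row.max_abs_log2 * 1000)))
            fh.write(f"{row.chromosome}\t{row.start}\t{row.end}\t{row.direction}\t{score}\n")


def segment_recovery(profile: pd.DataFrame, truth_segments: pd.DataFrame,
                     boundary_tol: int = 3) -> pd.DataFrame:
    """Score planted-segment recovery against a profile.

    For each planted segment (chromosome, start, end gene indices, mean), the
    recovered region is the maximal contiguous run of genes whose profile
    value has the planted sign and |value| >= |mean|/2 (half-amplitude rule,
    suppressing low-level background from chromosome-scale windows) that
    overlaps the planted segment. A segment counts as recovered when such a
    run exists and both boundaries are within ``boundary_tol`` genes of
    truth.
    """
    results = []
    prof_by_chrom = {str(c): sub.sort_values("position")["profile_log2"].to_numpy()
                     for c, sub in profile.groupby("chromosome", sort=False)}
    for seg in truth_segments.itertuples():
        vals = prof_by_chrom.get(str(seg.chromosome))
        mu = seg.mean
        found = False
        start_err = end_err = np.nan
        if vals is not None:
            mask = (np.sign(vals) == np.sign(mu)) & (np.abs(vals) >= abs(mu) / 2.0)
            hit = np.nonzero(mask[seg.start:seg.end])[0]
            if hit.size:
                i = j = int(hit[0]) + seg.start
                while i > 0 and mask[i - 1]:
                    i -= 1
                while j + 1 < len(mask) and mask[j + 1]:
                    j += 1
                start_err = i - seg.start
                end_err = (j + 1) - seg.end
                found = abs(start_err) <= boundary_tol and abs(end_err) <= boundary_tol
        results.append((seg.chromosome, seg.start, seg.end, mu, found, start_err, end_err))
    return pd.DataFrame(results, columns=["chromosome", "start", "end", "mean",
                                          "recovered", "start_error", "end_error"])
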