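"""Join proteome and copy-number data into a matched per-gene dataset.

Protein changes are quantified as the SILAC "ratio-of-ratios": each sample is
measured against a common heavy-labeled internal standard, and the log2 ratio
of the two sample/standard ratios cancels the standard, giving the tumor vs.
control protein change. Copy numbers come from probe-level smooth signals
summarized per gene by the median and normalized to the diploid control.
The two sides are joined on gene name.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "read_proteins",
    "read_probes",
    "ratio_of_ratios",
    "filter_quantified",
    "aggregate_replicates",
    "gene_copy_from_probes",
    "normalize_to_control",
    "match_by_gene",
    "correlation_and_r2",
    "control_diploidy_check",
    "build_matched",
    "read_matched",
    "write_matched",
]

PROTEIN_COLUMNS = ("gene", "chromosome", "position", "ratio_tumor_vs_std",
                   "ratio_control_vs_std", "n_events")
PROBE_COLUMNS = ("chromosome", "position", "gene", "smooth_signal")


def _read_tsv(path: str | Path, required: tuple[str, ...],
              colmap: Mapping[str, str] | None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if colmap:
        df = df.rename(columns=dict(colmap))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_proteins(path: str | Path, colmap: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a protein quantification TSV.

    ``colmap`` maps source column names to the canonical schema, which
    supports MaxQuant proteinGroups-style exports with renamed columns.
    A ``replicate`` column is added (single replicate) when absent.
    """
    df = _read_tsv(path, PROTEIN_COLUMNS, colmap)
    if "replicate" not in df.columns:
        df["replicate"] = "rep1"
    return df


def read_probes(path: str | Path, colmap: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a probe-level smooth-signal TSV (Genotyping-Console-like)."""
    return _read_tsv(path, PROBE_COLUMNS, colmap)


def ratio_of_ratios(tumor_vs_std, control_vs_std):
    """log2 relative protein level from two ratios against a common standard.

    Both inputs must be positive; scalars raise on violation, array inputs are
    validated by the caller (``build_matched`` drops and logs bad records).
    """
    t = np.asarray(tumor_vs_std, float)
    c = np.asarray(control_vs_std, float)
    if t.ndim == 0:
        if t <= 0 or c <= 0:
            raise ValueError("ratios must be positive")
        return float(np.log2(t / c))
    return np.log2(t / c)


def filter_quantified(proteins: pd.DataFrame, min_events: int = 2) -> pd.DataFrame:
    """Keep records with at least ``min_events`` quantification events
    (applied per replicate record)."""
    keep = proteins["n_events"] >= min_events
    removed = int((~keep).sum())
    if removed:
        log.info("filter_quantified: removed %d/%d records with < %d events",
                 removed, len(proteins), min_events)
    return proteins.loc[keep].reset_index(drop=True)


def aggregate_replicates(proteins: pd.DataFrame,
                         value_col: str = "protein_log2") -> pd.DataFrame:
    """One log2 value per gene: median over replicate values.

    Even counts use the mean-of-middle-two convention (numpy median).
    Chromosome/position are taken from the first record of each gene.
    """
    grouped = proteins.groupby("gene", sort=False)
    out = grouped.agg(
        chromosome=("chromosome", "first"),
        position=("position", "first"),
        protein_log2=(value_col, "median"),
        n_events=("n_events", "max"),
        n_replicates=(value_col, "size"),
    ).reset_index()
    return out


def gene_copy_from_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Per-gene copy number: median smooth signal of the gene's probes.

    Genes are located at their smallest probe position. Probe order and
    duplication of the whole probe set do not change the median.
    """
    grouped = probes.groupby("gene", sort=False)
    out = grouped.agg(
        chromosome=("chromosome", "first"),
        position=("position", "min"),
        copy_number=("smooth_signal", "median"),
    ).reset_index()
    return out


def normalize_to_control(tumor: pd.DataFrame, control: pd.DataFrame,
                         control_floor: float = 0.25) -> pd.DataFrame:
    """Copy log2 ratio of tumor vs. diploid-control gene copy numbers.

    Control copies below ``control_floor`` are floored (and the record
    flagged) so that near-zero control signal cannot produce infinities.
    """
    merged = tumor.merge(control[["gene", "copy_number"]], on="gene",
                         suffixes=("", "_control"))
    ctrl = merged["copy_number_control"].to_numpy(float)
    floored = ctrl < control_floor
    if floored.any():
        log.warning("normalize_to_control: %d genes with control copy < %.3g floored",
                    int(floored.sum()), control_floor)
    ctrl = np.maximum(ctrl, control_floor)
    tum = np.maximum(merged["copy_number"].to_numpy(float), control_floor / 8.0)
    merged["copy_log2"] = np.log2(tum / ctrl)
    merged["control_floored"] = floored
    return merged.drop(columns=["copy_number_control"])


def match_by_gene(proteins: pd.DataFrame, gene_copies: pd.DataFrame) -> pd.DataFrame:
    """Inner join of per-gene protein and copy records on gene name.

    Duplicate gene names on the protein side (protein groups mapping to the
    same gene) are resolved by keeping the record with the most
    quantification events, ties broken by smallest position; duplicates on
    the copy side keep the first by position. Unmatched counts are logged.
    """
    prot = proteins
    if prot["gene"].duplicated().any():
        n_dup = int(prot["gene"].duplicated().sum())
        log.warning("match_by_gene: %d duplicate protein gene names resolved", n_dup)
        order_cols = ["n_events"] if "n_events" in prot.columns else []
        prot = (prot.sort_values(order_cols + ["position"],
                                 ascending=[False] * len(order_cols) + [True])
                .drop_duplicates("gene").sort_index())
    copies = gene_copies
    if copies["gene"].duplicated().any():
        copies = copies.sort_values("position").drop_duplicates("gene").sort_index()

    merged = prot.merge(copies[["gene", "copy_number", "copy_log2"]], on="gene", how="inner")
    log.info("match_by_gene: matched %d genes (%d protein-only, %d copy-only)",
             len(merged), len(prot) - len(merged), len(copies) - len(merged))
    cols = ["gene", "chromosome", "position", "protein_log2", "copy_log2", "copy_number"]
    extra = [c for c in merged.columns if c not in cols]
    return merged[cols + extra]


def correlation_and_r2(matched: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation of copy vs. protein log2 changes, and r^2 in %.

    Degenerate inputs (fewer than 3 genes or zero variance on either axis)
    yield (nan, nan) with a warning.
    """
    x = matched["copy_log2"].to_numpy(float)
    y = matched["protein_log2"].to_numpy(float)
    if len(x) < 3 or np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("correlation undefined: <3 genes or zero variance", stacklevel=2)
        return float("nan"), float("nan")
    r = float(stats.pearsonr(x, y).statistic)
    return r, 100.0 * r * r


def control_diploidy_check(control_probes: pd.DataFrame,
                           drop_chromosome: str | None = None,
                           bin_width: float = 0.05) -> float:
    """Mode of the control smooth-signal histogram; should sit near 2.

    ``drop_chromosome`` removes a chromosome before the check (e.g. the
    Y chromosome, whose absent-in-female probes pile up at zero).
    """
    probes = control_probes
    if drop_chromosome is not None:
        probes = probes[probes["chromosome"].astype(str) != str(drop_chromosome)]
    sig = probes["smooth_signal"].to_numpy(float)
    if len(sig) < 100:
        log.warning("control_diploidy_check: only %d probes; mode is unstable", len(sig))
    lo, hi = sig.min(), sig.max() + bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(sig, bins=edges)
    mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0)
    if not 1.8 <= mode <= 2.2:
        warnings.warn(f"control smooth-signal mode {mode:.2f} outside [1.8, 2.2]; "
                      "control may not be diploid", stacklevel=2)
    return mode


def build_matched(proteins: pd.DataFrame, tumor_probes: pd.DataFrame,
                  control_probes: pd.DataFrame, min_events: int = 2,
                  center: bool = True, control_floor: float = 0.25) -> pd.DataFrame:
    """Full integration pipeline: raw tables -> matched per-gene dataset.

    Steps: drop non-positive ratios, compute the log2 ratio-of-ratios, filter
    on quantification events, aggregate replicates by median, summarize
    probes to gene copy numbers, normalize to the diploid control, join on
    gene name and (optionally) median-center the protein log2 ratios.
    """
    bad = (proteins["ratio_tumor_vs_std"] <= 0) | (proteins["ratio_control_vs_std"] <= 0)
    if bad.any():
        log.warning("build_matched: dropped %d records with non-positive ratios",
                    int(bad.sum()))
        proteins = proteins.loc[~bad]
    proteins = proteins.copy()
    proteins["protein_log2"] = ratio_of_ratios(
        proteins["ratio_tumor_vs_std"], proteins["ratio_control_vs_std"])
    proteins = filter_quantified(proteins, min_events)
    per_gene = aggregate_replicates(proteins)

    tumor_copy = gene_copy_from_probes(tumor_probes)
    control_copy = gene_copy_from_probes(control_probes)
    copies = normalize_to_control(tumor_copy, control_copy, control_floor)

    matched = match_by_gene(per_gene, copies)
    if center and len(matched):
        matched["protein_log2"] = matched["protein_log2"] - matched["protein_log2"].median()
    return matched


def write_matched(matched: pd.DataFrame, path: str | Path) -> None:
    matched.to_csv(path, sep="\t", index=False)


def read_matched(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in ("gene", "chromosome", "position", "protein_log2") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df
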