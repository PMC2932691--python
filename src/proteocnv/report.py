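"""Interpretation tables: amplicon zoom-ins, cancer-gene-census intersection,
and candidate lists of sign-concordant amplified/deleted genes.

Thresholds default to |log2| >= 0.32 (~1.25-fold) on both axes; they are
explicit configuration, not derived values.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "parse_region",
    "amplicon_zoom",
    "census_intersect",
    "candidate_lists",
    "read_census",
]

DEFAULT_THRESHOLD = 0.32  # log2, ~1.25-fold

_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse 'chrom:start-end' (1-based, inclusive) into its parts."""
    m = _REGION_RE.match(region)
    if not m or int(m["start"]) > int(m["end"]):
        raise ValueError(f"bad region syntax: {region!r} (expected chrom:start-end)")
    return m["chrom"], int(m["start"]), int(m["end"])


def amplicon_zoom(gene_copies: pd.DataFrame, matched: pd.DataFrame | None,
                  chromosome: str, start: int, end: int,
                  threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Per-gene linear fold changes inside a genomic region.

    ``gene_copies`` must carry gene/chromosome/position/copy_log2; matched
    protein values are joined when available, so amplified genes without a
    quantified protein still appear (protein fold NaN). Concordant means
    both changes exceed the threshold with the same sign.
    """
    sel = gene_copies[(gene_copies["chromosome"].astype(str) == str(chromosome))
                      & (gene_copies["position"] >= start)
                      & (gene_copies["position"] <= end)].copy()
    if sel.empty:
        log.warning("amplicon_zoom: no genes in %s:%d-%d", chromosome, start, end)
        return pd.DataFrame(columns=["gene", "chromosome", "position", "copy_log2",
                                     "protein_log2", "copy_fold", "protein_fold",
                                     "concordant"])
    if "protein_log2" not in sel.columns:
        if matched is not None and "protein_log2" in matched.columns:
            sel = sel.merge(matched[["gene", "protein_log2"]], on="gene", how="left")
        else:
            sel["protein_log2"] = np.nan
    sel["copy_fold"] = 2.0 ** sel["copy_log2"]
    sel["protein_fold"] = 2.0 ** sel["protein_log2"]
    sel["concordant"] = ((np.sign(sel["copy_log2"]) == np.sign(sel["protein_log2"]))
                         & (sel["copy_log2"].abs() >= threshold)
                         & (sel["protein_log2"].abs() >= threshold))
    cols = ["gene", "chromosome", "position", "copy_log2", "protein_log2",
            "copy_fold", "protein_fold", "concordant"]
    return sel.sort_values("position")[cols].reset_index(drop=True)


def read_census(path: str | Path) -> pd.DataFrame:
    """Read a cancer-gene-census table (TSV with gene and optional role)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene" not in df.columns:
        raise ValueError(f"{path}: census file needs a 'gene' column")
    if "role" not in df.columns:
        df["role"] = ""
    return df[["gene", "role"]]


def census_intersect(matched: pd.DataFrame, census: pd.DataFrame,
                     copy_threshold: float = DEFAULT_THRESHOLD,
                     protein_threshold: float = DEFAULT_THRESHOLD) -> pd.DataFrame:
    """Census genes whose copy number changed, with a concordance flag.

    A hit is a census gene with |copy_log2| >= copy_threshold; it is
    concordant when the protein change has the same sign and
    |protein_log2| >= protein_threshold.
    """
    if census.empty:
        raise ValueError("census list is empty")
    hits = matched.merge(census, on="gene", how="inner")
    hits = hits[hits["copy_log2"].abs() >= copy_threshold].copy()
    hits["concordant"] = ((np.sign(hits["copy_log2"]) == np.sign(hits["protein_log2"]))
                          & (hits["protein_log2"].abs() >= protein_threshold))
    cols = ["gene", "role", "copy_log2", "protein_log2", "concordant"]
    return hits.sort_values("copy_log2", ascending=False)[cols].reset_index(drop=True)


def candidate_lists(matched: pd.DataFrame, profile: pd.DataFrame | None = None,
                    copy_threshold: float = DEFAULT_THRESHOLD,
                    protein_threshold: float = DEFAULT_THRESHOLD,
                    ) -> dict[str, pd.DataFrame]:
    """Four disjoint candidate tables crossed by copy and protein direction.

    Genes first pass the copy criterion: |copy_log2| >= copy_threshold, or,
    when an aberration ``profile`` is supplied, membership in a significant
    profile segment (profile_log2 != 0, whose sign then defines the copy
    direction). The protein criterion |protein_log2| >= protein_threshold
    then assigns amplified-up / amplified-down / deleted-down / deleted-up;
    genes with unchanged protein are in no list. Tables are sorted by
    |protein_log2| descending.
    """
    df = matched.copy()
    if profile is not None:
        df = df.merge(profile[["gene", "profile_log2"]], on="gene", how="left")
        df["copy_direction"] = np.sign(df["profile_log2"].fillna(0.0))
    else:
        df["copy_direction"] = np.where(df["copy_log2"].abs() >= copy_threshold,
                                        np.sign(df["copy_log2"]), 0.0)
    df = df[df["copy_direction"] != 0]
    df = df[df["protein_log2"].abs() >= protein_threshold]
    prot_dir = np.sign(df["protein_log2"])
    out = {}
    for name, cdir, pdir in (("amplified_up", 1, 1), ("amplified_down", 1, -1),
                             ("deleted_down", -1, -1), ("deleted_up", -1, 1)):
        sub = df[(df["copy_direction"] == cdir) & (prot_dir == pdir)]
        sub = sub.reindex(sub["protein_log2"].abs().sort_values(ascending=False).index)
        cols = ["gene", "chromosome", "position", "copy_log2", "protein_log2"]
        out[name] = sub[cols].reset_index(drop=True)
    return out
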