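"""Synthetic proteogenomic data with the statistical structure of an
aneuploid-cancer-line versus diploid-control comparison.

The generator produces the three inputs of the analysis pipeline:

* probe-level SNP-array "smooth signal" tables for a tumor sample (signal
  centered on the segmental integer copy state, 0-4+) and a diploid control
  (signal centered on 2);
* a SILAC-style protein quantification table with tumor-vs-standard and
  control-vs-standard ratios, whose log2 ratio-of-ratios responds only
  partially to gene dosage (protein log2 = alpha_g * log2(c_g / 2) + shifts
  + noise, with alpha_g the per-gene dosage-response coefficient);
* GMT-like annotation term files, optionally containing planted terms whose
  members carry a coordinated (copy, protein) log2 shift.

All randomness is driven by :class:`SimConfig.seed`; the same configuration
always yields bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .gmt import write_gmt

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "simulate_genome",
    "simulate_proteome",
    "simulate_annotations",
    "simulate_dataset",
    "simulate_planted_track",
    "place_random_segments",
    "expected_r_squared",
    "write_dataset",
]

#: synthetic coordinates: genes every 10 kb, probes every 1 kb within a gene.
#: Only the ordering matters downstream; physical spacing is cosmetic.
GENE_SPACING = 10_000
PROBE_SPACING = 1_000

# rng stream ids, so each stage is reproducible independently of the others
_STREAM_GENOME = 0
_STREAM_PROTEOME = 1
_STREAM_ANNOTATIONS = 2
_STREAM_TRACK = 3


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    Defaults describe a five-chromosome genome with arm-level and focal
    aberrations (integer copy states 1-4, diploid state dominant), a partially
    dosage-responsive proteome tuned to a raw copy-protein Pearson r of ~0.28
    (a few percent of protein variance explained by dosage), and one planted
    annotation term shifted at the protein level only.
    """

    n_chromosomes: int = 10
    genes_per_chromosome: int = 300
    probes_per_gene: int = 5
    #: mean segment length in genes; lengths are geometric (stationary
    #: segmental model producing both focal and arm-level events).
    segment_mean_length: int = 50
    #: (copy state, weight) pairs; state 2 = diploid must dominate.
    copy_states: tuple[tuple[int, float], ...] = (
        (1, 0.15),
        (2, 0.60),
        (3, 0.15),
        (4, 0.10),
    )
    probe_noise_sd: float = 0.2
    dosage_sensitive_fraction: float = 1.0
    attenuation_alpha: float = 0.25
    protein_noise_sd: float = 0.45
    #: per-replicate measurement noise on each ratio-vs-standard (log2)
    technical_noise_sd: float = 0.1
    n_replicates: int = 3
    #: fraction of protein records downgraded to a single quantification
    #: event, to exercise the min-events filter
    low_evidence_fraction: float = 0.05
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    n_planted_terms: int = 1
    #: (log2 copy shift, log2 protein shift) applied to planted-term members
    planted_term_shift: tuple[float, float] = (0.0, 1.0)
    #: log2(0/2) is floored here instead of -inf (residual protein; keeps
    #: downstream t-tests finite)
    zero_copy_floor: float = -5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "genes_per_chromosome", "probes_per_gene",
                     "segment_mean_length", "n_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        for name in ("probe_noise_sd", "protein_noise_sd", "technical_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("dosage_sensitive_fraction", "low_evidence_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_terms < 0 or self.n_planted_terms < 0:
            raise ValueError("term counts must be non-negative")
        states = [s for s, _ in self.copy_states]
        weights = np.array([w for _, w in self.copy_states], float)
        if any(s < 0 for s in states):
            raise ValueError("copy states must be non-negative integers")
        if weights.min() < 0 or weights.sum() <= 0:
            raise ValueError("copy-state weights must be non-negative and sum > 0")
        lo, hi = self.term_size_range
        if not 0 < lo <= hi:
            raise ValueError("term_size_range must satisfy 0 < lo <= hi")

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic per-stage generator derived from the config seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset.

    ``genes`` holds one row per gene (position-ordered within chromosome):
    gene, chromosome, position, copy_state, copy_log2 (log2(c/2), floored at
    the configured value for c=0), alpha (dosage-response coefficient) and
    protein_log2_mean (noise-free expected protein log2 ratio, planted term
    shifts included). ``segments`` records the segmental partition.
    """

    genes: pd.DataFrame
    segments: pd.DataFrame
    planted_terms: dict[str, tuple[str, ...]] = field(default_factory=dict)
    seed: int = 0


class SimData(NamedTuple):
    truth: SimTruth
    proteins: pd.DataFrame
    tumor_probes: pd.DataFrame
    control_probes: pd.DataFrame
    terms: dict[str, tuple[str, ...]]


def _copy_log2(states: np.ndarray, floor: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        out = np.log2(np.asarray(states, float) / 2.0)
    return np.where(np.isneginf(out), floor, out)


def _draw_segments(rng: np.random.Generator, n_genes: int, mean_len: int,
                   states: np.ndarray, weights: np.ndarray) -> list[tuple[int, int, int]]:
    """Partition [0, n_genes) into segments with i.i.d. copy states.

    Returns (start, end, state) with half-open gene-index bounds.
    """
    out = []
    pos = 0
    while pos < n_genes:
        length = int(rng.geometric(1.0 / mean_len))
        end = min(pos + length, n_genes)
        state = int(rng.choice(states, p=weights))
        out.append((pos, end, state))
        pos = end
    return out


def simulate_genome(cfg: SimConfig) -> tuple[SimTruth, pd.DataFrame, pd.DataFrame]:
    """Draw the segmental genome and the tumor/control probe tables.

    Control probes are drawn around 2 (diploid); tumor probes around the
    segment copy state (times 2^copy-shift for planted-term members).
    Planted-term memberships are drawn here and recorded in the truth, so the
    proteome and annotation stages can apply/report the same memberships.
    """
    rng = cfg.rng(_STREAM_GENOME)
    states = np.array([s for s, _ in cfg.copy_states], int)
    weights = np.array([w for _, w in cfg.copy_states], float)
    weights = weights / weights.sum()

    gene_rows = []
    seg_rows = []
    for c in range(cfg.n_chromosomes):
        chrom = str(c + 1)
        segs = _draw_segments(rng, cfg.genes_per_chromosome,
                              cfg.segment_mean_length, states, weights)
        for start, end, state in segs:
            seg_rows.append((chrom, start, end, state))
            for i in range(start, end):
                gene_rows.append((f"G{chrom}_{i:04d}", chrom,
                                  (i + 1) * GENE_SPACING, state))
    genes = pd.DataFrame(gene_rows, columns=["gene", "chromosome", "position", "copy_state"])
    segments = pd.DataFrame(seg_rows, columns=["chromosome", "start", "end", "copy_state"])

    # dosage response coefficients
    sensitive = rng.random(len(genes)) < cfg.dosage_sensitive_fraction
    genes["alpha"] = np.where(sensitive, cfg.attenuation_alpha, 0.0)
    genes["copy_log2"] = _copy_log2(genes["copy_state"].to_numpy(), cfg.zero_copy_floor)

    # planted annotation terms: membership fixed at genome time
    planted: dict[str, tuple[str, ...]] = {}
    lo, hi = cfg.term_size_range
    universe = genes["gene"].to_numpy()
    copy_shift, protein_shift = cfg.planted_term_shift
    member_copy_shift = np.zeros(len(genes))
    member_protein_shift = np.zeros(len(genes))
    for t in range(cfg.n_planted_terms):
        size = int(rng.integers(lo, hi + 1))
        if size > len(universe):
            raise ValueError(f"planted term size {size} exceeds gene universe {len(universe)}")
        idx = rng.choice(len(universe), size=size, replace=False)
        planted[f"planted_{t + 1}"] = tuple(sorted(universe[idx]))
        member_copy_shift[idx] += copy_shift
        member_protein_shift[idx] += protein_shift

    genes["protein_log2_mean"] = genes["alpha"] * genes["copy_log2"] + member_protein_shift

    # probe tables
    n_probes = cfg.probes_per_gene
    probe_gene = np.repeat(np.arange(len(genes)), n_probes)
    probe_pos = (genes["position"].to_numpy()[probe_gene]
                 + np.tile(np.arange(n_probes), len(genes)) * PROBE_SPACING)
    tumor_mean = (genes["copy_state"].to_numpy(float) * 2.0 ** member_copy_shift)[probe_gene]
    tumor_sig = tumor_mean + rng.normal(0.0, cfg.probe_noise_sd, size=len(probe_gene)) \
        if cfg.probe_noise_sd > 0 else tumor_mean.copy()
    control_sig = 2.0 + rng.normal(0.0, cfg.probe_noise_sd, size=len(probe_gene)) \
        if cfg.probe_noise_sd > 0 else np.full(len(probe_gene), 2.0)
    base = {
        "chromosome": genes["chromosome"].to_numpy()[probe_gene],
        "position": probe_pos,
        "gene": genes["gene"].to_numpy()[probe_gene],
    }
    tumor_probes = pd.DataFrame({**base, "smooth_signal": np.maximum(tumor_sig, 0.0)})
    control_probes = pd.DataFrame({**base, "smooth_signal": np.maximum(control_sig, 0.0)})

    truth = SimTruth(genes=genes, segments=segments, planted_terms=planted, seed=cfg.seed)
    return truth, tumor_probes, control_probes


def simulate_proteome(truth: SimTruth, cfg: SimConfig) -> pd.DataFrame:
    """SILAC-style protein table: ratios versus a common internal standard.

    Per gene g a standard-abundance offset u_g (log2) cancels in the
    ratio-of-ratios. Biological noise (protein_noise_sd) is drawn once per
    gene; each replicate adds technical noise to both ratios. Quantification
    event counts are >= 2 except for a configured low-evidence fraction.
    """
    rng = cfg.rng(_STREAM_PROTEOME)
    genes = truth.genes
    n = len(genes)
    u = rng.normal(0.0, 0.5, size=n)  # abundance vs standard, cancels in RoR
    bio = rng.normal(0.0, cfg.protein_noise_sd, size=n) if cfg.protein_noise_sd > 0 else np.zeros(n)
    mu = genes["protein_log2_mean"].to_numpy() + bio

    frames = []
    for r in range(cfg.n_replicates):
        tech_t = rng.normal(0.0, cfg.technical_noise_sd, size=n) \
            if cfg.technical_noise_sd > 0 else np.zeros(n)
        tech_c = rng.normal(0.0, cfg.technical_noise_sd, size=n) \
            if cfg.technical_noise_sd > 0 else np.zeros(n)
        n_events = 2 + rng.poisson(5.0, size=n)
        low = rng.random(n) < cfg.low_evidence_fraction
        n_events = np.where(low, 1, n_events)
        frames.append(pd.DataFrame({
            "gene": genes["gene"],
            "chromosome": genes["chromosome"],
            "position": genes["position"],
            "ratio_tumor_vs_std": 2.0 ** (u + mu + tech_t),
            "ratio_control_vs_std": 2.0 ** (u + tech_c),
            "n_events": n_events,
            "replicate": f"rep{r + 1}",
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_annotations(truth: SimTruth, cfg: SimConfig) -> dict[str, tuple[str, ...]]:
    """Annotation terms: the planted terms from the truth plus random terms
    of sizes drawn from ``term_size_range``."""
    rng = cfg.rng(_STREAM_ANNOTATIONS)
    universe = truth.genes["gene"].to_numpy()
    lo, hi = cfg.term_size_range
    if cfg.n_terms > 0 and hi > len(universe):
        raise ValueError(f"term_size_range upper bound {hi} exceeds gene universe {len(universe)}")
    terms: dict[str, tuple[str, ...]] = dict(truth.planted_terms)
    for t in range(cfg.n_terms):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(len(universe), size=size, replace=False)
        terms[f"term_{t + 1:04d}"] = tuple(sorted(universe[idx]))
    return terms


def simulate_dataset(cfg: SimConfig) -> SimData:
    """Run all three stages and return the full synthetic dataset."""
    truth, tumor, control = simulate_genome(cfg)
    proteins = simulate_proteome(truth, cfg)
    terms = simulate_annotations(truth, cfg)
    return SimData(truth, proteins, tumor, control, terms)


def place_random_segments(rng: np.random.Generator, n_chromosomes: int,
                          genes_per_chromosome: int, n_segments: int,
                          length_range: tuple[int, int] = (15, 60),
                          mean_range: tuple[float, float] = (0.6, 1.5),
                          ) -> pd.DataFrame:
    """Place non-overlapping shifted segments with sign-balanced means.

    Returns a frame (chromosome, start, end, mean) with half-open gene-index
    bounds; used to lay out ground truth for profiling experiments.
    """
    signs = np.ones(n_segments)
    signs[: n_segments // 2] = -1.0
    rng.shuffle(signs)
    placed: list[tuple[str, int, int, float]] = []
    occupied: dict[str, list[tuple[int, int]]] = {str(c + 1): [] for c in range(n_chromosomes)}
    for k in range(n_segments):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        mean = float(rng.uniform(*mean_range)) * signs[k]
        for _ in range(1000):
            chrom = str(int(rng.integers(1, n_chromosomes + 1)))
            start = int(rng.integers(0, genes_per_chromosome - length + 1))
            end = start + length
            # keep a small gap so planted segments never merge
            if all(end + 3 <= s or start >= e + 3 for s, e in occupied[chrom]):
                occupied[chrom].append((start, end))
                placed.append((chrom, start, end, mean))
                break
        else:  # pragma: no cover - only with absurdly dense requests
            raise RuntimeError("could not place non-overlapping segments")
    return pd.DataFrame(placed, columns=["chromosome", "start", "end", "mean"]) \
        .sort_values(["chromosome", "start"], ignore_index=True)


def simulate_planted_track(n_chromosomes: int, genes_per_chromosome: int,
                           segments: pd.DataFrame | None, noise_sd: float,
                           seed: int) -> pd.DataFrame:
    """Ordered per-gene protein log2-ratio track with planted regional shifts.

    A direct generator for profiling experiments: Gaussian noise around zero
    everywhere except the given segments, whose genes get the segment mean
    added. Returns a matched-style frame (gene, chromosome, position,
    protein_log2) ordered by chromosome and position.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAM_TRACK,)))
    rows = []
    for c in range(n_chromosomes):
        chrom = str(c + 1)
        values = rng.normal(0.0, noise_sd, size=genes_per_chromosome)
        if segments is not None:
            for seg in segments[segments["chromosome"] == chrom].itertuples():
                values[seg.start:seg.end] += seg.mean
        for i in range(genes_per_chromosome):
            rows.append((f"G{chrom}_{i:04d}", chrom, (i + 1) * GENE_SPACING, values[i]))
    return pd.DataFrame(rows, columns=["gene", "chromosome", "position", "protein_log2"])


def expected_r_squared(cfg: SimConfig, copy_log2: Sequence[float]) -> float:
    """Closed-form fraction of protein log2 variance explained by dosage.

    Under the linear-Gaussian response model with dosage-sensitive fraction f,
    response coefficient alpha and noise sd sigma,
    R^2 = f^2 alpha^2 V / (f alpha^2 V + sigma^2) with V the variance of the
    copy log2 ratios (reduces to alpha^2 V / (alpha^2 V + sigma^2) for f=1).
    Replicate aggregation and technical noise are ignored; the formula is
    exact for single-replicate, technical-noise-free data.
    """
    v = float(np.var(np.asarray(copy_log2, float)))
    f = cfg.dosage_sensitive_fraction
    a = cfg.attenuation_alpha
    s2 = cfg.protein_noise_sd ** 2
    denom = f * a * a * v + s2
    if denom == 0:
        return 1.0 if f * a != 0 else 0.0
    return (f * a) ** 2 * v / denom


def write_dataset(data: SimData, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as TSV/GMT files (schema used by the readers)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out / "proteins.tsv",
        "tumor_probes": out / "tumor_probes.tsv",
        "control_probes": out / "control_probes.tsv",
        "truth_genes": out / "truth_genes.tsv",
        "truth_segments": out / "truth_segments.tsv",
        "terms": out / "terms.gmt",
    }
    header = f"# proteocnv synthetic dataset, seed={data.truth.seed}\n"
    for key, df in (("proteins", data.proteins), ("tumor_probes", data.tumor_probes),
                    ("control_probes", data.control_probes), ("truth_genes", data.truth.genes),
                    ("truth_segments", data.truth.segments)):
        with open(paths[key], "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False)
    write_gmt(data.terms, paths["terms"],
              descriptions={t: ("planted" if t in data.truth.planted_terms else "random")
                            for t in data.terms})
    return paths
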