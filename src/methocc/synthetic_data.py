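"""Synthetic genomes, methylomes, ChIP/Input fragments and expression counts.

The generator emulates the statistical structure of a neuronal
methylome/MeCP2-occupancy study:

* a CG-depleted genome carrying unmethylated, CG-rich CpG islands (CGIs);
* high mCG (~0.8) outside CGIs, near-zero inside;
* domain-structured non-CpG methylation: CAC sites methylated at a high
  level inside "high" domains and a low level elsewhere, with all other
  CA/CC/CT contexts near zero;
* Input coverage with a GC-composition bias and ChIP coverage coupled
  multiplicatively to the combined mCG+mCAC site density;
* negative-binomial expression counts whose knockout (KO) fold-changes
  couple linearly (in log2) to gene occupancy, on top of a global
  library-scale factor (default 0.85, the 15% per-cell RNA reduction);
  overexpression (OE) fold-changes get the opposite sign.

Every stage draws from its own ``numpy`` Generator seeded as
``seed + stage_offset``, so changing one stage's parameters never perturbs
the draws of another.  All outputs are pure functions of the configuration.

Ground truth (planted domains, expected window intensities, per-gene
fold-changes, the applied global scale) is collected in :class:`SimTruth`
for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_formats import GenomeSequence, GenomicInterval
from . import meth_context

# stage offsets for the per-stage random streams
_STAGE_GENOME = 0
_STAGE_METHYLOME = 1_000
_STAGE_CHIP = 2_000
_STAGE_EXPRESSION = 3_000
_STAGE_SPIKE = 4_000


class ConfigError(ValueError):
    """An inconsistent simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """All tunable parameters of the generative model.

    Defaults are the desk-scale study conditions: 2 chromosomes x 5 Mb,
    mCG ~0.8 outside CGIs and ~0.05 inside, mCAC 0.12/0.02 in high/low
    domains, mean 50 fragments per 1 kb window, and a KO global scale of
    0.85 (a 15% reduction of RNA per cell).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # genome composition
    cgi_count: int = 40
    cgi_length: int = 2_000
    cg_suppression: float = 0.75  # prob. of breaking a CG dinucleotide outside CGIs
    # mCAC domain structure
    domain_length_range: tuple[int, int] = (50_000, 400_000)
    frac_high_domains: float = 0.5
    # methylation levels
    mcg_level_out: float = 0.8
    mcg_level_cgi: float = 0.05
    mcac_level_high: float = 0.12
    mcac_level_low: float = 0.02
    other_context_level: float = 0.01
    hmc_level: float = 0.03
    nonconversion_rate: float = 0.005
    meth_depth: float = 30.0  # mean reads per cytosine
    # ChIP / Input
    window: int = 1_000
    coverage_depth: float = 50.0  # mean fragments per window per library
    gc_bias_strength: float = 15.0
    beta_occupancy: float = 0.03  # log-units per (mCG+mCAC sites/kb)
    fragment_length: int = 134
    # optional planted mCAC clusters (summit emulation)
    cluster_anchor_count: int = 0
    cluster_halfwidth: int = 100
    cluster_level: float = 0.9
    # expression
    n_genes: int = 2_000
    gene_length: int = 2_000
    n_replicates: int = 3
    baseline_log_mean: float = 4.6  # natural-log mean of the log-normal baseline
    baseline_log_sd: float = 1.0
    nb_dispersion: float = 0.02
    coupling_alpha: float = 3.0  # log2FC per log2-occupancy unit
    frac_coupled_genes: float = 0.3
    global_scale_ko: float = 0.85

    def __post_init__(self) -> None:
        fracs = {
            "frac_high_domains": self.frac_high_domains,
            "mcg_level_out": self.mcg_level_out,
            "mcg_level_cgi": self.mcg_level_cgi,
            "mcac_level_high": self.mcac_level_high,
            "mcac_level_low": self.mcac_level_low,
            "other_context_level": self.other_context_level,
            "frac_coupled_genes": self.frac_coupled_genes,
            "cg_suppression": self.cg_suppression,
        }
        for name, value in fracs.items():
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.chrom_length <= 0 or self.window <= 0:
            raise ConfigError("lengths must be positive")
        if self.domain_length_range[0] > self.domain_length_range[1]:
            raise ConfigError("domain_length_range must be (lo, hi) with lo <= hi")
        if self.chrom_length < self.domain_length_range[1]:
            raise ConfigError("chrom_length smaller than the maximum domain length")
        if self.coverage_depth <= 0:
            raise ConfigError("coverage_depth must be positive")
        if self.global_scale_ko <= 0:
            raise ConfigError("global_scale_ko must be positive")

    def rng(self, stage_offset: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + stage_offset)


@dataclass
class SimTruth:
    """Planted ground truth for parameter-recovery tests."""

    domains: list[GenomicInterval] = field(default_factory=list)
    cgis: list[GenomicInterval] = field(default_factory=list)
    window: int = 0
    fragment_length: int = 0
    expected_input: dict[str, np.ndarray] = field(default_factory=dict)
    expected_chip: dict[str, np.ndarray] = field(default_factory=dict)
    summit_anchors: list[tuple[str, int]] = field(default_factory=list)
    genes: Optional[pd.DataFrame] = None
    global_scale_ko: float = 1.0

    def domains_on(self, chrom: str, label: str | None = None) -> list[GenomicInterval]:
        out = [d for d in self.domains if d.chrom == chrom]
        if label is not None:
            out = [d for d in out if d.name == label]
        return out


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# CGIs are strongly GC- and CG-enriched
_P_CGI = np.array([0.15, 0.35, 0.35, 0.15])
# smoothly varying background GC landscape (isochore-like)
_GC_MEAN = 0.42
_GC_SD = 0.04
_GC_BLOCK = 10_000  # bp; correlation scale of the landscape
_GC_SMOOTH = 10  # blocks


def _gc_landscape(length: int, rng: np.random.Generator) -> np.ndarray:
    """Per-base GC probability, smooth at the ~100 kb scale."""
    n_blocks = -(-length // _GC_BLOCK)
    raw = rng.normal(size=n_blocks + _GC_SMOOTH)
    kernel = np.ones(_GC_SMOOTH) / _GC_SMOOTH
    smooth = np.convolve(raw, kernel, mode="valid")[:n_blocks]
    smooth *= 1.0 / max(smooth.std(), 1e-9)
    gc = np.clip(_GC_MEAN + _GC_SD * smooth, 0.30, 0.55)
    return np.repeat(gc, _GC_BLOCK)[:length]


def _tile_domains(
    chrom: str, length: int, config: SimConfig, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Tile one chromosome with high/low domains, exactly covering it."""
    lo, hi = config.domain_length_range
    bounds = [0]
    while bounds[-1] < length:
        bounds.append(min(length, bounds[-1] + int(rng.integers(lo, hi + 1))))
    out = []
    for s, e in zip(bounds[:-1], bounds[1:]):
        label = "high" if rng.random() < config.frac_high_domains else "low"
        out.append(GenomicInterval(chrom, s, e, name=label))
    return out


def _place_cgis(
    chrom: str, length: int, count: int, cgi_length: int, rng: np.random.Generator
) -> list[GenomicInterval]:
    """Place non-overlapping CGIs uniformly along one chromosome."""
    if count == 0:
        return []
    placed: list[int] = []
    attempts = 0
    while len(placed) < count and attempts < 100 * count:
        start = int(rng.integers(0, length - cgi_length))
        if all(abs(start - p) >= 2 * cgi_length for p in placed):
            placed.append(start)
        attempts += 1
    return [GenomicInterval(chrom, s, s + cgi_length, name="CGI") for s in sorted(placed)]


def simulate_genome(
    config: SimConfig,
) -> tuple[GenomeSequence, list[GenomicInterval], SimTruth]:
    """Draw a CG-depleted genome with CG-rich CGIs and a domain tiling.

    Bases are drawn i.i.d. (GC-rich inside CGIs); CG dinucleotides outside
    CGIs are then broken with probability ``cg_suppression`` by replacing
    the G, which depletes CG genome-wide while leaving CGIs enriched.
    """
    rng = config.rng(_STAGE_GENOME)
    truth = SimTruth()
    names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    per_chrom_cgis = np.array_split(np.arange(config.cgi_count), config.n_chroms)
    sequences: dict[str, str] = {}
    all_cgis: list[GenomicInterval] = []
    for chrom, cgi_idx in zip(names, per_chrom_cgis):
        L = config.chrom_length
        truth.domains.extend(_tile_domains(chrom, L, config, rng))
        cgis = _place_cgis(chrom, L, len(cgi_idx), config.cgi_length, rng)
        all_cgis.extend(cgis)

        gc = _gc_landscape(L, rng)
        u = rng.random(L)
        # cumulative thresholds A | C | G | T with per-base GC probability
        codes = (
            (u > (1 - gc) / 2).astype(np.int8)
            + (u > 0.5).astype(np.int8)
            + (u > (1 + gc) / 2).astype(np.int8)
        )
        in_cgi = np.zeros(L, dtype=bool)
        for cgi in cgis:
            n = cgi.end - cgi.start
            codes[cgi.start : cgi.end] = rng.choice(4, size=n, p=_P_CGI)
            in_cgi[cgi.start : cgi.end] = True
        # suppress CG outside CGIs: break the dinucleotide at the G
        is_c = codes[:-1] == 1
        is_g = codes[1:] == 2
        cg_pos = np.flatnonzero(is_c & is_g & ~in_cgi[:-1])
        hit = cg_pos[rng.random(cg_pos.size) < config.cg_suppression]
        codes[hit + 1] = rng.choice(
            np.array([0, 1, 3], dtype=np.int8), size=hit.size
        )
        sequences[chrom] = _BASES[codes].tobytes().decode("ascii")
    truth.cgis = all_cgis
    genome = GenomeSequence(names, sequences)
    return genome, all_cgis, truth


# ---------------------------------------------------------------------------
# methylome
# ---------------------------------------------------------------------------


def _membership(pos: np.ndarray, intervals: list[GenomicInterval]) -> np.ndarray:
    """Boolean membership of positions in a sorted non-overlapping set."""
    if not intervals:
        return np.zeros(pos.size, dtype=bool)
    starts = np.array([iv.start for iv in intervals])
    ends = np.array([iv.end for iv in intervals])
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    idx = np.searchsorted(starts, pos, side="right") - 1
    ok = idx >= 0
    out = np.zeros(pos.size, dtype=bool)
    out[ok] = pos[ok] < ends[idx[ok]]
    return out


def methylation_probabilities(
    sites: pd.DataFrame, truth: SimTruth, config: SimConfig
) -> np.ndarray:
    """Per-site true methylation probability under the planted model."""
    p = np.full(len(sites), config.other_context_level)
    di = sites["di"].to_numpy()
    tri = sites["tri"].to_numpy()
    pos = sites["pos"].to_numpy()
    chroms = sites["chrom"].to_numpy()
    is_cg = di == "CG"
    is_cac = tri == "CAC"
    p[di == "NA"] = 0.0
    for chrom in pd.unique(chroms):
        on = chroms == chrom
        in_cgi = _membership(pos[on], [c for c in truth.cgis if c.chrom == chrom])
        in_high = _membership(pos[on], truth.domains_on(chrom, "high"))
        pc = p[on]
        pc[is_cg[on]] = np.where(
            in_cgi[is_cg[on]], config.mcg_level_cgi, config.mcg_level_out
        )
        pc[is_cac[on]] = np.where(
            in_high[is_cac[on]], config.mcac_level_high, config.mcac_level_low
        )
        p[on] = pc
    # planted mCAC clusters override domain levels near their anchors,
    # tapering linearly from the anchor so the aggregate profile peaks there
    for chrom, anchor in truth.summit_anchors:
        d = np.abs(pos - anchor)
        near = (chroms == chrom) & is_cac & (d <= config.cluster_halfwidth)
        taper = 1.0 - d[near] / (config.cluster_halfwidth + 1)
        p[near] = np.maximum(p[near], config.cluster_level * taper)
    return p


def simulate_methylome(
    genome: GenomeSequence,
    truth: SimTruth,
    config: SimConfig,
    with_tab: bool = False,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Binomial basecalls for every cytosine; optional TAB (hmC) channel.

    Returns site tables (see :mod:`methocc.meth_context`) with counts and
    levels filled and a ``p_true`` column recording the planted
    probability.  BS levels include the global non-conversion rate; the TAB
    channel draws independent low hmC levels.
    """
    rng = config.rng(_STAGE_METHYLOME)
    sites = meth_context.classify_contexts(genome)
    if config.cluster_anchor_count and not truth.summit_anchors:
        margin = 10 * config.cluster_halfwidth
        for chrom in genome.chrom_names:
            n_anchor = config.cluster_anchor_count // len(genome.chrom_names)
            anchors = rng.integers(
                margin, genome.lengths[chrom] - margin, size=n_anchor
            )
            truth.summit_anchors.extend((chrom, int(a)) for a in np.sort(anchors))
    p = methylation_probabilities(sites, truth, config)
    p_obs = p + (1.0 - p) * config.nonconversion_rate
    depth = rng.poisson(config.meth_depth, size=len(sites)).astype(np.int32)
    mod = rng.binomial(depth, p_obs).astype(np.int32)
    sites["count_modified"] = mod
    sites["count_total"] = depth
    with np.errstate(invalid="ignore"):
        sites["level"] = np.where(depth > 0, mod / np.maximum(depth, 1), np.nan)
    sites["p_true"] = p

    tab_sites = None
    if with_tab:
        hmc = np.where(sites["di"].to_numpy() == "CG", config.hmc_level, 0.0)
        hmc_obs = hmc + (1.0 - hmc) * config.nonconversion_rate
        depth_t = rng.poisson(config.meth_depth, size=len(sites)).astype(np.int32)
        mod_t = rng.binomial(depth_t, hmc_obs).astype(np.int32)
        tab_sites = sites.drop(columns=["p_true"]).copy()
        tab_sites["count_modified"] = mod_t
        tab_sites["count_total"] = depth_t
        with np.errstate(invalid="ignore"):
            tab_sites["level"] = np.where(
                depth_t > 0, mod_t / np.maximum(depth_t, 1), np.nan
            )
        tab_sites["p_true"] = hmc
    return sites, tab_sites


def simulate_spike_report(config: SimConfig, n_sites: int = 500) -> pd.DataFrame:
    """Unmethylated lambda spike-in sites read at the non-conversion rate."""
    rng = config.rng(_STAGE_SPIKE)
    depth = rng.poisson(config.meth_depth, size=n_sites).astype(np.int32)
    mod = rng.binomial(depth, config.nonconversion_rate).astype(np.int32)
    return pd.DataFrame(
        {
            "chrom": "lambda",
            "pos": np.arange(n_sites, dtype=np.int64),
            "strand": "+",
            "di": "CG",
            "tri": "CGA",
            "count_modified": mod,
            "count_total": depth,
            "level": np.where(depth > 0, mod / np.maximum(depth, 1), np.nan),
        }
    )


def sites_to_report(sites: pd.DataFrame) -> pd.DataFrame:
    """Site table -> cytosine-report records (1-based positions)."""
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].astype(str),
            "pos": sites["pos"] + 1,
            "strand": sites["strand"].astype(str),
            "count_modified": sites["count_modified"],
            "count_unmodified": sites["count_total"] - sites["count_modified"],
            "di_context": sites["di"].astype(str),
            "tri_context": sites["tri"].astype(str),
        }
    )


# ---------------------------------------------------------------------------
# ChIP / Input fragments
# ---------------------------------------------------------------------------


def combined_density_per_kb(
    sites: pd.DataFrame, chrom: str, chrom_length: int, window: int
) -> np.ndarray:
    """mCG + mCAC methylation density per kb in fixed windows (truth scale).

    Uses the planted probabilities when available (``p_true``), falling
    back to observed levels, so the ChIP model couples to the noise-free
    methylation landscape.
    """
    n_win = chrom_length // window
    on = sites["chrom"].to_numpy() == chrom
    di = sites["di"].to_numpy()
    tri = sites["tri"].to_numpy()
    keep = on & ((di == "CG") | (tri == "CAC"))
    pos = sites["pos"].to_numpy()[keep]
    if "p_true" in sites.columns:
        lev = sites["p_true"].to_numpy()[keep]
    else:
        lev = np.nan_to_num(sites["level"].to_numpy()[keep])
    inside = pos < n_win * window
    dens = np.bincount(
        pos[inside] // window, weights=lev[inside], minlength=n_win
    )
    return dens / window * 1000.0


def gc_fraction_track(genome: GenomeSequence, chrom: str, window: int) -> np.ndarray:
    seq = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
    n_win = seq.size // window
    gc = (seq == ord("G")) | (seq == ord("C"))
    return (
        np.add.reduceat(gc[: n_win * window].astype(np.int64), np.arange(0, n_win * window, window))
        / window
    )


def _fragments_from_counts(
    chrom: str,
    counts: np.ndarray,
    window: int,
    fragment_length: int,
    chrom_length: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    total = int(counts.sum())
    win_start = np.repeat(np.arange(counts.size) * window, counts)
    offset = rng.integers(0, window, size=total)
    start = win_start + offset
    end = np.minimum(start + fragment_length, chrom_length)
    strand = np.where(rng.random(total) < 0.5, "+", "-")
    return pd.DataFrame(
        {"chrom": chrom, "start": start, "end": end, "strand": strand}
    )


def simulate_chip_experiment(
    genome: GenomeSequence,
    sites: Optional[pd.DataFrame],
    truth: SimTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Poisson ChIP and Input fragment sets over fixed windows.

    Input intensity carries a logistic GC-composition bias; ChIP intensity
    multiplies it by ``exp(beta * (combined mCG+mCAC density/kb - mean))``,
    so ``beta_occupancy = 0`` gives a null experiment with identically
    distributed libraries.
    """
    rng = config.rng(_STAGE_CHIP)
    w = config.window
    chip_frames, input_frames = [], []
    # genome-wide centering so mean intensities match across chromosomes
    gc_all, dens_all = [], []
    for chrom in genome.chrom_names:
        gc_all.append(gc_fraction_track(genome, chrom, w))
        if sites is None:
            # density only matters through beta_occupancy; a null experiment
            # may skip the methylome stage entirely
            dens_all.append(np.zeros(genome.lengths[chrom] // w))
        else:
            dens_all.append(
                combined_density_per_kb(sites, chrom, genome.lengths[chrom], w)
            )
    gc_mean = float(np.mean(np.concatenate(gc_all)))
    dens_mean = float(np.mean(np.concatenate(dens_all)))

    truth.window = w
    truth.fragment_length = config.fragment_length
    for chrom, gc, dens in zip(genome.chrom_names, gc_all, dens_all):
        bias = 2.0 * expit(config.gc_bias_strength * (gc - gc_mean))
        input_intensity = config.coverage_depth * bias
        chip_intensity = input_intensity * np.exp(
            config.beta_occupancy * (dens - dens_mean)
        )
        truth.expected_input[chrom] = input_intensity
        truth.expected_chip[chrom] = chip_intensity
        L = genome.lengths[chrom]
        input_counts = rng.poisson(input_intensity)
        chip_counts = rng.poisson(chip_intensity)
        input_frames.append(
            _fragments_from_counts(chrom, input_counts, w, config.fragment_length, L, rng)
        )
        chip_frames.append(
            _fragments_from_counts(chrom, chip_counts, w, config.fragment_length, L, rng)
        )
    chip = pd.concat(chip_frames, ignore_index=True)
    inp = pd.concat(input_frames, ignore_index=True)
    return chip, inp


def simulate_step_domains(
    config: SimConfig,
    domain_length: int = 50_000,
    fold: float = 1.5,
    n_domains: int = 10,
    base_window: int = 100,
):
    """Planted constant-fold domains over a flat Input, as window counts.

    A single chromosome is tiled with ``base_window`` bp windows; Input
    intensity is flat at ``coverage_depth`` fragments per ``config.window``
    bp, and ChIP intensity is ``fold`` times Input inside ``n_domains``
    evenly spaced domains of ``domain_length`` bp (``fold`` < 1 plants
    depletions).  Returns ChIP and Input :class:`CoverageWindows` plus the
    true domain intervals — the recovery oracle for the multiscale
    segmentation.
    """
    from .occupancy import CoverageWindows, make_partition

    rng = config.rng(_STAGE_CHIP)
    L = config.chrom_length
    n_win = L // base_window
    spacing = L // n_domains
    if domain_length >= spacing:
        raise ConfigError("domains would touch; reduce n_domains or length")
    domains = []
    for k in range(n_domains):
        start = k * spacing + (spacing - domain_length) // 2
        domains.append(GenomicInterval("chr1", start, start + domain_length, name="planted"))
    depth = config.coverage_depth * base_window / config.window
    input_intensity = np.full(n_win, depth)
    chip_intensity = input_intensity.copy()
    for d in domains:
        chip_intensity[d.start // base_window : d.end // base_window] *= fold
    input_counts = rng.poisson(input_intensity)
    chip_counts = rng.poisson(chip_intensity)
    partition = make_partition({"chr1": L}, base_window)
    chip_cw = CoverageWindows(
        partition, chip_counts.astype(np.int64), base_window, 0, int(chip_counts.sum()), 0
    )
    input_cw = CoverageWindows(
        partition, input_counts.astype(np.int64), base_window, 0, int(input_counts.sum()), 0
    )
    return chip_cw, input_cw, domains


# ---------------------------------------------------------------------------
# genes and expression
# ---------------------------------------------------------------------------


def flat_truth(genome: GenomeSequence, config: SimConfig) -> SimTruth:
    """A truth record with flat unit intensities (zero occupancy everywhere).

    Lets the expression stage run without the methylome/ChIP stages when
    occupancy coupling is not under study.
    """
    truth = SimTruth()
    truth.window = config.window
    truth.fragment_length = config.fragment_length
    for chrom in genome.chrom_names:
        n_win = genome.lengths[chrom] // config.window
        truth.expected_input[chrom] = np.ones(n_win)
        truth.expected_chip[chrom] = np.ones(n_win)
    return truth


def place_genes(genome: GenomeSequence, config: SimConfig) -> pd.DataFrame:
    """Evenly spaced non-overlapping gene bodies across the chromosomes."""
    per_chrom = config.n_genes // config.n_chroms
    rem = config.n_genes - per_chrom * config.n_chroms
    rows = []
    gi = 0
    for k, chrom in enumerate(genome.chrom_names):
        n = per_chrom + (1 if k < rem else 0)
        L = genome.lengths[chrom]
        slot = L // max(n, 1)
        if slot <= config.gene_length:
            raise ConfigError(
                f"n_genes={config.n_genes} does not fit on {chrom} "
                f"with gene_length={config.gene_length}"
            )
        for j in range(n):
            start = j * slot + (slot - config.gene_length) // 2
            rows.append(
                {
                    "gene_id": f"g{gi:05d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + config.gene_length,
                    "strand": "+" if gi % 2 == 0 else "-",
                }
            )
            gi += 1
    return pd.DataFrame(rows)


def true_gene_occupancy(genes: pd.DataFrame, truth: SimTruth) -> np.ndarray:
    """Noise-free log2(ChIP/Input) averaged over each gene body."""
    occ = np.zeros(len(genes))
    w = truth.window
    for i, row in enumerate(genes.itertuples(index=False)):
        exp_c = truth.expected_chip[row.chrom]
        exp_i = truth.expected_input[row.chrom]
        lo, hi = row.start // w, max(row.start // w + 1, -(-row.end // w))
        hi = min(hi, exp_c.size)
        occ[i] = float(np.mean(np.log2(exp_c[lo:hi] / exp_i[lo:hi])))
    return occ


def simulate_expression(
    genes: pd.DataFrame,
    truth: SimTruth,
    config: SimConfig,
) -> tuple[pd.DataFrame, SimTruth]:
    """NB count matrix for WT/KO/OE replicates with planted fold-changes.

    A ``frac_coupled_genes`` subset couples its KO log2FC to true gene
    occupancy (``coupling_alpha`` log2 units per occupancy unit) and its OE
    log2FC to the opposite sign; every KO expectation is then multiplied by
    ``global_scale_ko``.  Truth records the pre-scaling fold-changes.
    """
    rng = config.rng(_STAGE_EXPRESSION)
    n = len(genes)
    occ = true_gene_occupancy(genes, truth)
    coupled = rng.random(n) < config.frac_coupled_genes
    l2fc_ko = np.where(coupled, config.coupling_alpha * occ, 0.0)
    l2fc_oe = np.where(coupled, -config.coupling_alpha * occ, 0.0)
    base = rng.lognormal(config.baseline_log_mean, config.baseline_log_sd, size=n)

    cols = {}
    conditions = []
    for cond, l2fc, scale in (
        ("WT", np.zeros(n), 1.0),
        ("KO", l2fc_ko, config.global_scale_ko),
        ("OE", l2fc_oe, 1.0),
    ):
        mu = base * np.exp2(l2fc) * scale
        for r in range(config.n_replicates):
            cols[f"{cond}_{r + 1}"] = _nb_draw(mu, config.nb_dispersion, rng)
            conditions.append(cond)
    counts = pd.DataFrame(cols, index=genes["gene_id"].to_numpy())
    counts.index.name = "gene_id"

    gt = genes.copy()
    gt["occupancy"] = occ
    gt["coupled"] = coupled
    gt["true_log2fc_ko"] = l2fc_ko
    gt["true_log2fc_oe"] = l2fc_oe
    gt["baseline_mean"] = base
    truth.genes = gt
    truth.global_scale_ko = config.global_scale_ko
    return counts, truth


def _nb_draw(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    if dispersion < 1e-8:
        return rng.poisson(mu).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mu * dispersion)
    return rng.poisson(lam).astype(np.int64)


def condition_labels(counts: pd.DataFrame) -> pd.Series:
    """Condition of each sample column, read from the ``COND_rep`` names."""
    return pd.Series(
        [c.rsplit("_", 1)[0] for c in counts.columns], index=counts.columns
    )


# ---------------------------------------------------------------------------
# one-call bundle
# ---------------------------------------------------------------------------


@dataclass
class SimData:
    """Everything one simulated study produces."""

    config: SimConfig
    genome: GenomeSequence
    cgis: list[GenomicInterval]
    truth: SimTruth
    sites: pd.DataFrame
    tab_sites: Optional[pd.DataFrame]
    chip_fragments: pd.DataFrame
    input_fragments: pd.DataFrame
    genes: pd.DataFrame
    counts: pd.DataFrame


def simulate_all(config: SimConfig, with_tab: bool = False) -> SimData:
    """Run every stage of the generator under one configuration."""
    genome, cgis, truth = simulate_genome(config)
    sites, tab_sites = simulate_methylome(genome, truth, config, with_tab=with_tab)
    chip, inp = simulate_chip_experiment(genome, sites, truth, config)
    genes = place_genes(genome, config)
    counts, truth = simulate_expression(genes, truth, config)
    return SimData(
        config, genome, cgis, truth, sites, tab_sites, chip, inp, genes, counts
    )
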