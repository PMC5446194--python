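"""Windowed coverage, RPKM, log2(ChIP/Input) occupancy, and the
Input-predictability model.

ChIP occupancy is quantified against the Input library (fragmented
chromatin without immunoprecipitation): fragments are shifted toward their
midpoint, counted in fixed windows covering each chromosome, normalised to
RPKM, and expressed as ``log2((chip + psi) / (input + psi))`` with a small
pseudocount.  A protein that tracks total DNA content makes ChIP coverage
almost entirely predictable from Input coverage; the linear model
``chip ~ input`` quantifies that predictability (R^2), and the windows that
escape it — the residual outliers — are the biologically interesting
enriched/depleted fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, GenomicInterval


@dataclass
class CoverageWindows:
    """Fragment counts and RPKM over a fixed-width genome partition."""

    windows: pd.DataFrame  # columns chrom, start, end (sorted, non-overlapping)
    counts: np.ndarray
    width: int
    shift: int
    library_size: int
    lost: int  # fragments falling outside the partition after shifting

    @property
    def rpkm(self) -> np.ndarray:
        return self.counts / (self.library_size / 1e6) / (self.width / 1e3)

    def same_partition(self, other: "CoverageWindows") -> bool:
        return self.width == other.width and self.windows[["chrom", "start"]].equals(
            other.windows[["chrom", "start"]]
        )


@dataclass
class OccupancyTrack:
    """Per-window log2((chip_rpkm + psi) / (input_rpkm + psi))."""

    windows: pd.DataFrame
    log2_ratio: np.ndarray
    psi: float

    def to_bedgraph_frame(self) -> pd.DataFrame:
        out = self.windows.copy()
        out["value"] = self.log2_ratio
        return out


@dataclass
class InputFit:
    """OLS fit of ChIP on Input counts with an outlier partition."""

    slope: float
    intercept: float
    r_squared: float
    residuals: np.ndarray
    labels: Optional[np.ndarray] = None  # {'enriched','depleted','neutral'}
    neutral_r_squared: Optional[float] = None


def make_partition(genome_lengths: dict[str, int], width: int) -> pd.DataFrame:
    """Fixed-width windows per chromosome; trailing partial windows dropped."""
    if width <= 0:
        raise ValueError("window width must be positive")
    frames = []
    for chrom, L in genome_lengths.items():
        n = L // width
        starts = np.arange(n, dtype=np.int64) * width
        frames.append(
            pd.DataFrame({"chrom": chrom, "start": starts, "end": starts + width})
        )
    return pd.concat(frames, ignore_index=True)


def bin_coverage(
    fragments: pd.DataFrame,
    genome_lengths: dict[str, int],
    window: int,
    shift: int = 67,
) -> CoverageWindows:
    """Count shifted fragments in fixed windows and fill RPKM.

    Each fragment is represented by one position — ``start + shift`` on the
    plus strand, ``end - 1 - shift`` on the minus strand — emulating the
    fragment-length shift applied to single-end ChIP reads.  Positions
    falling outside the partition (off the chromosome or in the dropped
    trailing window) are tallied in ``lost``.
    """
    if window <= 0:
        raise ValueError("window width must be positive")
    partition = make_partition(genome_lengths, window)
    n_per_chrom = {
        chrom: genome_lengths[chrom] // window for chrom in genome_lengths
    }
    offsets = {}
    off = 0
    for chrom in genome_lengths:
        offsets[chrom] = off
        off += n_per_chrom[chrom]
    counts = np.zeros(off, dtype=np.int64)
    lost = 0
    library_size = len(fragments)
    for chrom, sub in fragments.groupby("chrom", sort=False, observed=True):
        if chrom not in n_per_chrom:
            raise ValueError(f"fragment on unknown chromosome {chrom!r}")
        strand = sub["strand"].to_numpy() if "strand" in sub else np.repeat("+", len(sub))
        pos = np.where(
            strand == "-",
            sub["end"].to_numpy() - 1 - shift,
            sub["start"].to_numpy() + shift,
        )
        idx = pos // window
        ok = (pos >= 0) & (idx < n_per_chrom[chrom])
        lost += int((~ok).sum())
        counts[offsets[chrom] : offsets[chrom] + n_per_chrom[chrom]] += np.bincount(
            idx[ok], minlength=n_per_chrom[chrom]
        )
    return CoverageWindows(partition, counts, window, shift, library_size, lost)


def log2_ratio(
    chip: CoverageWindows, input_: CoverageWindows, psi: float = 0.5
) -> OccupancyTrack:
    """Per-window log2 ratio of ChIP over Input RPKM with pseudocount psi."""
    if not chip.same_partition(input_):
        raise ValueError("chip and input partitions differ")
    with np.errstate(divide="ignore"):
        ratio = np.log2((chip.rpkm + psi) / (input_.rpkm + psi))
    return OccupancyTrack(chip.windows, ratio, psi)


def fit_input_model(
    chip_counts: np.ndarray, input_counts: np.ndarray
) -> InputFit:
    """Ordinary least squares of ChIP on Input window counts.

    Returns slope, intercept, the coefficient of determination
    ``R^2 = 1 - SS_res/SS_tot``, and per-window residuals.
    """
    chip_counts = np.asarray(chip_counts, dtype=float)
    input_counts = np.asarray(input_counts, dtype=float)
    if chip_counts.size != input_counts.size:
        raise ValueError("chip and input must have equal length")
    if chip_counts.size < 3:
        raise ValueError("need at least 3 windows")
    if np.var(input_counts) == 0:
        raise ValueError("degenerate fit: input counts have zero variance")
    res = stats.linregress(input_counts, chip_counts)
    fitted = res.intercept + res.slope * input_counts
    residuals = chip_counts - fitted
    ss_res = float(np.sum(residuals**2))
    ss_tot = float(np.sum((chip_counts - chip_counts.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return InputFit(float(res.slope), float(res.intercept), r2, residuals)


def partition_outliers(
    fit: InputFit,
    chip_counts: np.ndarray,
    input_counts: np.ndarray,
    mode: str = "quantile",
    q_low: float = 0.041,
    q_high: float = 0.017,
    z_cut: float = 2.0,
) -> InputFit:
    """Label windows enriched/depleted/neutral by their fit residuals.

    ``quantile`` mode labels the lowest ``q_low`` residual fraction
    depleted and the highest ``q_high`` fraction enriched (defaults are the
    printed 4.1% / 1.7% window fractions); ``zscore`` mode uses
    standardised-residual cutoffs at ``±z_cut``.  ``neutral_r_squared`` is
    the R^2 of a fresh fit restricted to neutral windows.
    """
    if mode not in {"quantile", "zscore"}:
        raise ValueError(f"unknown mode {mode!r}")
    if q_low + q_high >= 1:
        raise ValueError("q_low + q_high must be < 1")
    resid = fit.residuals
    n = resid.size
    labels = np.full(n, "neutral", dtype=object)
    if mode == "quantile":
        order = np.argsort(resid, kind="stable")
        n_dep = int(round(q_low * n))
        n_enr = int(round(q_high * n))
        if n_dep:
            labels[order[:n_dep]] = "depleted"
        if n_enr:
            labels[order[n - n_enr :]] = "enriched"
    else:
        sd = resid.std(ddof=1)
        if sd > 0:
            z = resid / sd
            labels[z < -z_cut] = "depleted"
            labels[z > z_cut] = "enriched"
    neutral = labels == "neutral"
    neutral_r2 = None
    if neutral.sum() >= 3 and np.var(np.asarray(input_counts, float)[neutral]) > 0:
        neutral_r2 = fit_input_model(
            np.asarray(chip_counts, float)[neutral],
            np.asarray(input_counts, float)[neutral],
        ).r_squared
    return InputFit(
        fit.slope, fit.intercept, fit.r_squared, resid, labels, neutral_r2
    )


# ---------------------------------------------------------------------------
# AT-flank comparison
# ---------------------------------------------------------------------------


def _has_at_run(
    seq: np.ndarray, pos: int, flank: int = 13, min_run: int = 4
) -> bool:
    """True if a maximal run of >= min_run consecutive A/T starts within
    ±flank of pos."""
    lo = max(0, pos - flank - min_run)
    hi = min(seq.size, pos + flank + min_run + 1)
    window = (seq[lo:hi] == ord("A")) | (seq[lo:hi] == ord("T"))
    run = 0
    run_start = 0
    for i, at in enumerate(window):
        if at:
            if run == 0:
                run_start = i
            run += 1
        else:
            if run >= min_run and abs(run_start + lo - pos) <= flank:
                return True
            run = 0
    return run >= min_run and abs(run_start + lo - pos) <= flank


def at_flank_analysis(
    site_positions: pd.DataFrame,
    genome: GenomeSequence,
    site_signal: np.ndarray,
    flank: int = 13,
    min_run: int = 4,
    isolation_radius: int = 50,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> dict:
    """Compare occupancy at isolated methylated sites with vs without an
    AT-rich flank.

    A site is flagged when any maximal run of >= ``min_run`` consecutive
    A/T bases starts within ±``flank`` bp of it.  Only isolated sites (no
    other listed site within ±``isolation_radius``) enter the comparison.
    Returns group sizes, mean signal per group, their difference, and a
    bootstrap 95% CI of the difference.
    """
    rng = np.random.default_rng(seed)
    flags = []
    isolated = []
    seqs = {
        chrom: np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        for chrom in genome.chrom_names
    }
    pos_by_chrom = {
        chrom: np.sort(sub["pos"].to_numpy())
        for chrom, sub in site_positions.groupby("chrom", sort=False, observed=True)
    }
    for row in site_positions.itertuples(index=False):
        allpos = pos_by_chrom[row.chrom]
        i = np.searchsorted(allpos, row.pos)
        near = allpos[max(0, i - 2) : i + 3]
        near = near[(near != row.pos) & (np.abs(near - row.pos) <= isolation_radius)]
        iso = near.size == 0
        isolated.append(iso)
        flags.append(
            _has_at_run(seqs[row.chrom], int(row.pos), flank, min_run) if iso else False
        )
    isolated = np.array(isolated)
    flags = np.array(flags)
    if not isolated.any():
        raise ValueError("no isolated sites under the configured radius")
    signal = np.asarray(site_signal, dtype=float)
    with_at = signal[isolated & flags]
    without_at = signal[isolated & ~flags]
    diff = float(with_at.mean() - without_at.mean()) if with_at.size and without_at.size else float("nan")
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        a = rng.choice(with_at, size=with_at.size, replace=True) if with_at.size else np.array([np.nan])
        c = rng.choice(without_at, size=without_at.size, replace=True) if without_at.size else np.array([np.nan])
        boots[b] = a.mean() - c.mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return {
        "n_with_at_run": int(with_at.size),
        "n_without_at_run": int(without_at.size),
        "mean_with_at_run": float(with_at.mean()) if with_at.size else float("nan"),
        "mean_without_at_run": float(without_at.mean()) if without_at.size else float("nan"),
        "difference": diff,
        "ci_low": float(lo),
        "ci_high": float(hi),
    }


def valid_windows_mask(
    genome: GenomeSequence, window: int, max_n_fraction: float = 0.5
) -> np.ndarray:
    """Windows whose assembly-gap (N) fraction is acceptable for fitting.

    Aligned with :func:`make_partition` order; windows with more than
    ``max_n_fraction`` N bases are excluded from Input-model fits.
    """
    masks = []
    for chrom in genome.chrom_names:
        seq = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        n_win = seq.size // window
        is_n = (seq[: n_win * window] == ord("N")).astype(np.int64)
        frac = np.add.reduceat(is_n, np.arange(0, n_win * window, window)) / window
        masks.append(frac <= max_n_fraction)
    return np.concatenate(masks) if masks else np.zeros(0, dtype=bool)


def flag_at_run(seq: str, pos: int, flank: int = 13, min_run: int = 4) -> bool:
    """Single-site AT-run rule, exposed for direct checks."""
    return _has_at_run(
        np.frombuffer(seq.encode("ascii"), dtype=np.uint8), pos, flank, min_run
    )
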