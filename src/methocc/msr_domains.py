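"""Simplified multiscale segmentation of occupancy into enriched/depleted
domains.

A geometric smoothing ladder replaces a full multiscale-representation
tool: at scale index ``s`` both coverage tracks are mean-smoothed over
``w0 * 2^s`` bp, the enrichment score is
``log2((chip_s + psi) / (input_s * r + psi))`` with ``r`` the library-size
ratio, candidate segments are maximal runs of windows with
``|score| >= score_threshold`` (one sign per run), and a candidate is kept
when a two-sided binomial test of its summed raw ChIP count against the
scaled Input expectation clears ``p_thresh`` (default 1e-6).  Segments
carry their scale index, the segment-mean signed score, and annotation
densities (mCG, mCAC, combined, GC fraction).  Mappability is assumed
uniform.  Nested segments across scales are all reported; an optional
pruning pass keeps only the most significant scale per locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, GenomicInterval
from .occupancy import CoverageWindows
from .meth_context import region_methylation
from .summits_profiles import _running_mean


@dataclass
class Segment:
    """One enriched (score > 0) or depleted (score < 0) domain."""

    interval: GenomicInterval
    scale_index: int
    enrichment_score: float
    p_value: float
    annotations: dict[str, float] = field(default_factory=dict)

    @property
    def label(self) -> str:
        return "enriched" if self.enrichment_score > 0 else "depleted"

    def __len__(self) -> int:
        return len(self.interval)


@dataclass
class ScaleScoreSummary:
    """Segment statistics on a scale x score grid (empty cells absent)."""

    table: pd.DataFrame  # indexed by (scale_bin, score_bin)


def smoothing_window_bp(w0: int, scale_index: int) -> int:
    return w0 * (2**scale_index)


def multiscale_segments(
    chip: CoverageWindows,
    input_: CoverageWindows,
    scales: Sequence[int] = tuple(range(13)),
    score_threshold: float = 0.2,
    p_thresh: float = 1e-6,
    psi: float = 0.5,
) -> list[Segment]:
    """Segment the genome at every scale of the smoothing ladder.

    ``scales`` are exponents of the doubling ladder on the base window
    (default 100 bp windows, 12 doublings: 100 bp to ~400 kb).
    """
    if len(scales) == 0:
        raise ValueError("empty scale list")
    if not chip.same_partition(input_):
        raise ValueError("chip and input partitions differ")
    w0 = chip.width
    r = chip.library_size / max(input_.library_size, 1)
    p_chip = r / (1.0 + r)
    segments: list[Segment] = []
    for chrom, sub in chip.windows.groupby("chrom", sort=False, observed=True):
        idx = sub.index.to_numpy()
        c = chip.counts[idx].astype(float)
        i = input_.counts[idx].astype(float)
        c_cum = np.concatenate(([0.0], np.cumsum(c)))
        i_cum = np.concatenate(([0.0], np.cumsum(i)))
        starts_bp = sub["start"].to_numpy()
        for s in scales:
            k = 2**s
            if k > c.size:
                continue
            c_s = _running_mean(c, k)
            i_s = _running_mean(i, k)
            score = np.log2((c_s + psi) / (i_s * r + psi))
            score_cum = np.concatenate(([0.0], np.cumsum(score)))
            for sign in (1, -1):
                a, b = _run_bounds(sign * score >= score_threshold)
                if a.size == 0:
                    continue
                chip_sum = np.rint(c_cum[b] - c_cum[a]).astype(np.int64)
                n_tot = np.rint(
                    chip_sum + (i_cum[b] - i_cum[a])
                ).astype(np.int64)
                pvals = _binom_two_sided(chip_sum, n_tot, p_chip)
                seg_scores = (score_cum[b] - score_cum[a]) / (b - a)
                keep = (pvals < p_thresh) & (sign * seg_scores > 0) & (n_tot > 0)
                for aa, bb, sc, pv in zip(
                    a[keep], b[keep], seg_scores[keep], pvals[keep]
                ):
                    segments.append(
                        Segment(
                            GenomicInterval(
                                str(chrom),
                                int(starts_bp[aa]),
                                int(starts_bp[bb - 1] + w0),
                            ),
                            int(s),
                            float(sc),
                            float(pv),
                        )
                    )
    return segments


def _binom_two_sided(k: np.ndarray, n: np.ndarray, p: float) -> np.ndarray:
    """Vectorised two-sided binomial tail (doubled smaller tail, capped)."""
    n = np.maximum(n, 1)
    lower = stats.binom.cdf(k, n, p)
    upper = stats.binom.sf(k - 1, n, p)
    return np.minimum(1.0, 2.0 * np.minimum(lower, upper))


def _run_bounds(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if not mask.any():
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    return starts.astype(np.int64), ends.astype(np.int64)


def candidate_run_count(
    chip: CoverageWindows,
    input_: CoverageWindows,
    scales: Sequence[int],
    score_threshold: float,
    psi: float = 0.5,
) -> int:
    """Number of candidate runs (both signs, all scales) before testing.

    The null-calibration bound on significant segments is
    ``p_thresh * candidates`` (two-sided tests are counted once per signed
    run).
    """
    if not chip.same_partition(input_):
        raise ValueError("chip and input partitions differ")
    r = chip.library_size / max(input_.library_size, 1)
    n = 0
    for chrom, sub in chip.windows.groupby("chrom", sort=False, observed=True):
        idx = sub.index.to_numpy()
        c = chip.counts[idx].astype(float)
        i = input_.counts[idx].astype(float)
        for s in scales:
            k = 2**s
            if k > c.size:
                continue
            score = np.log2(
                (_running_mean(c, k) + psi) / (_running_mean(i, k) * r + psi)
            )
            for sign in (1, -1):
                n += _run_bounds(sign * score >= score_threshold)[0].size
    return n


def annotate_segments(
    segments: list[Segment],
    sites: pd.DataFrame,
    genome: GenomeSequence,
    min_coverage: int = 1,
) -> list[Segment]:
    """Attach mCG/mCAC/combined densities (per kb) and GC fraction."""
    seqs = {
        c: np.frombuffer(genome.sequences[c].encode("ascii"), dtype=np.uint8)
        for c in genome.chrom_names
    }
    # pre-sort covered positions per (chrom, context) for fast range sums
    from .meth_context import _context_mask

    tracks = {}
    for ctx in ("CG", "CAC"):
        covered = sites[_context_mask(sites, ctx) & (sites["count_total"] >= min_coverage)]
        for chrom, sub in covered.groupby("chrom", sort=False, observed=True):
            pos = sub["pos"].to_numpy()
            order = np.argsort(pos)
            lev = sub["level"].to_numpy()[order]
            tracks[(str(chrom), ctx)] = (pos[order], np.concatenate(([0.0], np.cumsum(lev))))
    for seg in segments:
        iv = seg.interval
        L = len(iv)
        dens = {}
        for ctx in ("CG", "CAC"):
            pos, cum = tracks.get((iv.chrom, ctx), (np.zeros(0, dtype=np.int64), np.zeros(1)))
            a, b = np.searchsorted(pos, [iv.start, iv.end])
            dens[ctx] = (cum[b] - cum[a]) / L * 1000.0
        seq = seqs[iv.chrom][iv.start : iv.end]
        gc = float(((seq == ord("G")) | (seq == ord("C"))).mean()) if L else 0.0
        seg.annotations = {
            "mCG_density": float(dens["CG"]),
            "mCAC_density": float(dens["CAC"]),
            "combined_density": float(dens["CG"] + dens["CAC"]),
            "gc_fraction": gc,
        }
    return segments


def scale_score_summary(
    segments: list[Segment],
    scale_bins: Sequence[int] | None = None,
    score_bins: Sequence[float] | None = None,
) -> ScaleScoreSummary:
    """Count, median length and mean annotations on a scale x score grid.

    Cells with no segments are absent from the table rather than zero.
    """
    if not segments:
        raise ValueError("no segments to summarise")
    if score_bins is None:
        score_bins = np.arange(-3.0, 3.01, 0.5)
    rows = []
    for seg in segments:
        j = int(np.clip(np.digitize(seg.enrichment_score, score_bins) - 1, 0, len(score_bins) - 2))
        row = {
            "scale_bin": seg.scale_index if scale_bins is None else int(
                np.clip(np.digitize(seg.scale_index, scale_bins) - 1, 0, len(scale_bins) - 2)
            ),
            "score_bin": float(score_bins[j]),
            "length": len(seg),
        }
        row.update(seg.annotations)
        rows.append(row)
    df = pd.DataFrame(rows)
    agg = {"length": ["count", "median"]}
    for col in ("mCG_density", "mCAC_density", "combined_density", "gc_fraction"):
        if col in df.columns:
            agg[col] = ["mean"]
    table = df.groupby(["scale_bin", "score_bin"]).agg(agg)
    table.columns = [
        "count" if (a, b) == ("length", "count")
        else "median_length" if (a, b) == ("length", "median")
        else f"mean_{a}"
        for a, b in table.columns
    ]
    return ScaleScoreSummary(table)


def prune_segments(segments: list[Segment]) -> list[Segment]:
    """Keep the most significant segment per overlapping same-sign locus."""
    kept: list[Segment] = []
    for seg in sorted(segments, key=lambda s: s.p_value):
        if not any(
            seg.interval.overlaps(k.interval)
            and np.sign(k.enrichment_score) == np.sign(seg.enrichment_score)
            for k in kept
        ):
            kept.append(seg)
    return kept


def overlap_with_cgis(
    segments: list[Segment],
    cgis: Sequence[GenomicInterval],
    genome_lengths: dict[str, int],
    scale_cutoff: int = 4,
    n_shuffles: int = 200,
    seed: int = 0,
) -> dict:
    """Fraction of short depleted segments overlapping a CGI, with an
    empirical p-value from position-shuffled segment sets.

    Shuffling preserves each segment's length and chromosome.  With no
    CGIs the observed fraction is 0 and the p-value 1.
    """
    import warnings

    if n_shuffles < 100:
        warnings.warn("fewer than 100 shuffles gives a coarse empirical p-value", stacklevel=2)
    short_depleted = [
        s for s in segments
        if s.scale_index < scale_cutoff and s.enrichment_score < 0
    ]
    if not short_depleted:
        raise ValueError("no short depleted segments below the scale cutoff")
    cgi_by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in genome_lengths:
        mine = sorted(
            [c for c in cgis if c.chrom == chrom], key=lambda c: c.start
        )
        cgi_by_chrom[chrom] = (
            np.array([c.start for c in mine], dtype=np.int64),
            np.array([c.end for c in mine], dtype=np.int64),
        )

    def frac_overlapping(intervals: list[tuple[str, int, int]]) -> float:
        hit = 0
        for chrom, s, e in intervals:
            starts, ends = cgi_by_chrom[chrom]
            j = np.searchsorted(ends, s, side="right")
            if j < starts.size and starts[j] < e:
                hit += 1
        return hit / len(intervals)

    observed = frac_overlapping(
        [(s.interval.chrom, s.interval.start, s.interval.end) for s in short_depleted]
    )
    rng = np.random.default_rng(seed)
    null = np.empty(n_shuffles)
    for b in range(n_shuffles):
        shuffled = []
        for s in short_depleted:
            L = len(s.interval)
            chrom = s.interval.chrom
            start = int(rng.integers(0, genome_lengths[chrom] - L))
            shuffled.append((chrom, start, start + L))
        null[b] = frac_overlapping(shuffled)
    p_emp = (1 + int((null >= observed).sum())) / (n_shuffles + 1)
    return {
        "observed_fraction": observed,
        "null_fractions": null,
        "empirical_p": p_emp,
        "n_segments": len(short_depleted),
    }


def bp_jaccard(
    a: Sequence[GenomicInterval],
    b: Sequence[GenomicInterval],
    genome_lengths: dict[str, int],
) -> float:
    """Base-pair Jaccard index (|intersection| / |union|) of interval sets."""
    inter = 0
    union = 0
    for chrom, L in genome_lengths.items():
        mask_a = np.zeros(L, dtype=bool)
        mask_b = np.zeros(L, dtype=bool)
        for iv in a:
            if iv.chrom == chrom:
                mask_a[iv.start : iv.end] = True
        for iv in b:
            if iv.chrom == chrom:
                mask_b[iv.start : iv.end] = True
        inter += int((mask_a & mask_b).sum())
        union += int((mask_a | mask_b).sum())
    return inter / union if union else float("nan")


def segments_to_frame(segments: list[Segment]) -> pd.DataFrame:
    rows = []
    for s in segments:
        row = {
            "chrom": s.interval.chrom,
            "start": s.interval.start,
            "end": s.interval.end,
            "scale_index": s.scale_index,
            "enrichment_score": s.enrichment_score,
            "p_value": s.p_value,
            "label": s.label,
        }
        row.update(s.annotations)
        rows.append(row)
    return pd.DataFrame(rows)
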