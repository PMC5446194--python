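"""Summit calling on ChIP-over-Input enrichment and anchored meta-profiles.

The summit caller is a deliberately simplified stand-in for a full peak
caller: per fine window it computes ``log2((chip + psi)/(input*r + psi))``
with ``r`` the ChIP/Input library-size ratio, smooths with a running mean,
takes maximal runs above an enrichment threshold, and keeps a run only if
its summed ChIP count clears a Poisson upper-tail test against the scaled
Input expectation.  The summit is the argmax of the smoothed enrichment
within the run (leftmost on ties).  Its contract is summit *position*
agreement, not score agreement with any published caller.

Meta-profiles aggregate a signal in fixed bins around anchor positions
(summits ±4 kb at 20 bp, TSS ±100 kb at 1 kb, CGI centres at 100 bp, ...).
Stranded anchors have their rows reversed so downstream is always to the
right.  With an even number of bins the anchor sits on the boundary
between the two central bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, GenomicInterval
from .occupancy import CoverageWindows


@dataclass(frozen=True)
class Summit:
    chrom: str
    pos: int  # single-base summit position
    score: float  # smoothed enrichment at the summit
    peak_start: int
    peak_end: int


@dataclass
class ProfileMatrix:
    """Per-anchor binned signal and its column-mean aggregate."""

    values: np.ndarray  # n_anchors x n_bins
    bin_size: int
    flank: int
    n_dropped: int  # anchors whose flank left the chromosome

    @property
    def aggregate(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]


def _running_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Centered running mean with edge shrinkage (window clipped at ends)."""
    if k <= 1:
        return x.astype(float)
    c = np.cumsum(np.concatenate(([0.0], x)))
    half = k // 2
    n = x.size
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + (k - half), n)
    return (c[hi] - c[lo]) / (hi - lo)


def call_summits(
    chip: CoverageWindows,
    input_: CoverageWindows,
    bandwidth: int = 200,
    threshold: float = 1.0,
    psi: float = 0.5,
    p_thresh: float = 1e-5,
) -> list[Summit]:
    """Summits of ChIP enrichment over library-scaled Input.

    ``bandwidth`` is the running-mean width in bp and must be at least the
    window size.  Candidate peaks are maximal runs of smoothed enrichment
    above ``threshold``; each is kept if the Poisson upper tail of its
    summed ChIP count against ``r x Input count`` is below ``p_thresh``.
    """
    if not chip.same_partition(input_):
        raise ValueError("chip and input partitions differ")
    w = chip.width
    if bandwidth < w:
        raise ValueError("bandwidth must be at least the window size")
    k = max(1, bandwidth // w)
    r = chip.library_size / max(input_.library_size, 1)
    summits: list[Summit] = []
    windows = chip.windows
    k_local = max(k, 5000 // w)  # background stabilisation scale
    for chrom, sub in windows.groupby("chrom", sort=False, observed=True):
        idx = sub.index.to_numpy()
        c = chip.counts[idx].astype(float)
        i = input_.counts[idx].astype(float)
        e = np.log2((c + psi) / (i * r + psi))
        e_s = _running_mean(e, k)
        i_s = _running_mean(i, k)
        i_local = _running_mean(i, k_local)
        i_global = float(i.mean())
        above = e_s > threshold
        if not above.any():
            continue
        # maximal runs of above-threshold windows
        edges = np.diff(above.astype(np.int8))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if above[0]:
            starts = np.concatenate(([0], starts))
        if above[-1]:
            ends = np.concatenate((ends, [above.size]))
        starts_bp = sub["start"].to_numpy()
        for s, t in zip(starts, ends):
            chip_sum = float(c[s:t].sum())
            # local-mean background: the largest of the run-scale, 5 kb and
            # genome-wide Input means, per window, scaled by library ratio
            lam = max(float(i_s[s:t].mean()), float(i_local[s:t].mean()), i_global)
            expect = max(r * lam * (t - s), 1e-12)
            p = stats.poisson.sf(chip_sum - 1, expect)
            if p >= p_thresh:
                continue
            rel = int(np.argmax(e_s[s:t]))  # argmax is leftmost on ties
            pos = int(starts_bp[s + rel] + w // 2)
            summits.append(
                Summit(
                    str(chrom),
                    pos,
                    float(e_s[s + rel]),
                    int(starts_bp[s]),
                    int(starts_bp[t - 1] + w),
                )
            )
    return summits


def sample_random_regions(
    genome: GenomeSequence,
    n: int,
    seed: int,
    exclusion: Sequence[GenomicInterval] = (),
) -> pd.DataFrame:
    """Uniformly sampled single-base positions outside exclusions and gaps.

    The negative control for anchored profiles: positions are uniform over
    all non-N, non-excluded bases, so per-chromosome counts are
    multinomial in the usable lengths.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    allowed: list[tuple[str, np.ndarray]] = []
    total = 0
    for chrom in genome.chrom_names:
        seq = np.frombuffer(genome.sequences[chrom].encode("ascii"), dtype=np.uint8)
        ok = seq != ord("N")
        for iv in exclusion:
            if iv.chrom == chrom:
                ok[iv.start : iv.end] = False
        pos = np.flatnonzero(ok)
        allowed.append((chrom, pos))
        total += pos.size
    if total == 0:
        raise ValueError("exclusion covers the whole genome")
    weights = np.array([p.size for _, p in allowed], dtype=float) / total
    counts = rng.multinomial(n, weights)
    rows = []
    for (chrom, pos), k in zip(allowed, counts):
        if k == 0:
            continue
        pick = rng.choice(pos, size=k, replace=True)
        rows.append(pd.DataFrame({"chrom": chrom, "pos": np.sort(pick)}))
    return pd.concat(rows, ignore_index=True)


def profile_matrix(
    anchors: pd.DataFrame,
    signal: "SignalSource",
    flank: int,
    bin_size: int,
) -> ProfileMatrix:
    """Binned signal around each anchor, plus the column-mean aggregate.

    ``anchors`` needs columns ``chrom, pos`` and optionally ``strand``;
    minus-strand anchors are column-reversed so downstream is rightward.
    Anchors whose ±flank leaves the chromosome are dropped and tallied.
    """
    if flank % bin_size != 0:
        raise ValueError("flank must be divisible by bin size")
    n_bins = 2 * flank // bin_size
    rows = []
    dropped = 0
    has_strand = "strand" in anchors.columns
    for row in anchors.itertuples(index=False):
        lo = int(row.pos) - flank
        hi = int(row.pos) + flank
        vals = signal.binned(row.chrom, lo, hi, bin_size)
        if vals is None:
            dropped += 1
            continue
        if has_strand and row.strand == "-":
            vals = vals[::-1]
        rows.append(vals)
    if not rows:
        raise ValueError("no anchors retained (all flanks leave the genome)")
    return ProfileMatrix(np.vstack(rows), bin_size, flank, dropped)


class SignalSource:
    """Anything that can average itself over fixed bins of a locus."""

    def binned(self, chrom: str, lo: int, hi: int, bin_size: int) -> Optional[np.ndarray]:
        raise NotImplementedError


class SiteDensitySignal(SignalSource):
    """Methylation density (per kb) of one context from a site table.

    Bin value = sum of covered-site levels in the bin / bin length — the
    same region statistic used everywhere else, evaluated per bin.
    """

    def __init__(
        self,
        sites: pd.DataFrame,
        context: str,
        chrom_lengths: dict[str, int],
        min_coverage: int = 1,
        per_kb: bool = True,
    ) -> None:
        from .meth_context import _context_mask  # shared context rule

        covered = sites[
            _context_mask(sites, context) & (sites["count_total"] >= min_coverage)
        ]
        self._pos: dict[str, np.ndarray] = {}
        self._lev: dict[str, np.ndarray] = {}
        for chrom, sub in covered.groupby("chrom", sort=False, observed=True):
            order = np.argsort(sub["pos"].to_numpy())
            self._pos[str(chrom)] = sub["pos"].to_numpy()[order]
            self._lev[str(chrom)] = sub["level"].to_numpy()[order]
        self._lengths = chrom_lengths
        self._scale = 1000.0 if per_kb else 1.0

    def binned(self, chrom, lo, hi, bin_size):
        if chrom not in self._lengths or lo < 0 or hi > self._lengths[chrom]:
            return None
        pos = self._pos.get(chrom, np.zeros(0, dtype=np.int64))
        lev = self._lev.get(chrom, np.zeros(0))
        a, b = np.searchsorted(pos, [lo, hi])
        n_bins = (hi - lo) // bin_size
        idx = (pos[a:b] - lo) // bin_size
        dens = np.bincount(idx, weights=lev[a:b], minlength=n_bins) / bin_size
        return dens * self._scale


class WindowTrackSignal(SignalSource):
    """A per-window track (e.g. the occupancy log2 ratio) as a signal.

    Bin value = length-weighted mean of the track windows overlapping the
    bin; bins outside the track's coverage use 0 weight and return NaN-safe
    means (fully uncovered bins give 0).
    """

    def __init__(self, windows: pd.DataFrame, values: np.ndarray, chrom_lengths: dict[str, int]):
        self._tracks: dict[str, tuple[int, np.ndarray]] = {}
        vals = np.asarray(values, dtype=float)
        for chrom, sub in windows.groupby("chrom", sort=False, observed=True):
            width = int(sub["end"].iloc[0] - sub["start"].iloc[0])
            self._tracks[str(chrom)] = (width, vals[sub.index.to_numpy()])
        self._lengths = chrom_lengths

    def binned(self, chrom, lo, hi, bin_size):
        if chrom not in self._lengths or lo < 0 or hi > self._lengths[chrom]:
            return None
        width, vals = self._tracks[chrom]
        n_bins = (hi - lo) // bin_size
        out = np.empty(n_bins)
        edges = lo + np.arange(n_bins + 1) * bin_size
        for k in range(n_bins):
            w_lo = edges[k] // width
            w_hi = -(-edges[k + 1] // width)
            w_hi = min(w_hi, vals.size)
            if w_lo >= vals.size:
                out[k] = 0.0
                continue
            weights = []
            vv = []
            for w_idx in range(w_lo, w_hi):
                seg_lo = max(edges[k], w_idx * width)
                seg_hi = min(edges[k + 1], (w_idx + 1) * width)
                if seg_hi > seg_lo:
                    weights.append(seg_hi - seg_lo)
                    vv.append(vals[w_idx])
            out[k] = np.average(vv, weights=weights) if weights else 0.0
        return out
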