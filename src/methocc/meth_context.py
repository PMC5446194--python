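"""Strand-aware cytosine context classification and methylation statistics.

A cytosine site lives on one strand.  On the plus strand it is a literal
``C`` in the sequence; on the minus strand it is a ``G`` in the plus-strand
sequence, and its context is read 5'->3' along the minus strand (i.e.
leftward along plus coordinates, complemented).  The per-site methylation
level is ``m_i = modified / total`` basecalls.  For a region of length L
containing N_CX covered sites of context CX with mean level m'_CX, the
context methylation density is ``N_CX * m'_CX / L`` — equivalently the sum
of site levels divided by L.  Densities are stored per bp and reported per
kb.

Site tables are plain :class:`pandas.DataFrame` objects with columns
``chrom, pos, strand, di, tri, count_modified, count_total, level``
(``pos`` 0-based; ``di``/``tri`` are ``NA`` when the context runs off the
chromosome or contains an N).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenomeSequence, GenomicInterval

logger = logging.getLogger("methocc")

SITE_COLUMNS = ["chrom", "pos", "strand", "di", "tri", "count_modified", "count_total", "level"]

_COMPLEMENT = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# context classification
# ---------------------------------------------------------------------------


# categorical dictionaries shared by all site tables (compact int codes)
DI_CATEGORIES = ["CA", "CC", "CG", "CT", "NA"]
TRI_CATEGORIES = [d + b for d in ("CA", "CC", "CG", "CT") for b in "ACGT"] + ["NA"]
STRAND_CATEGORIES = ["+", "-"]

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_DI_OF_BASE = np.array([0, 1, 2, 3], dtype=np.int8)  # A,C,G,T -> CA,CC,CG,CT


def _classify_chrom(seq: str, chrom: str) -> pd.DataFrame:
    """Vectorised context read-off for one chromosome, both strands."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    comp = np.frombuffer(seq.encode("ascii").translate(_COMPLEMENT), dtype=np.uint8)
    n = arr.size

    frames = []
    # plus strand: C at p, context from seq[p+1], seq[p+2]
    pos = np.flatnonzero(arr == ord("C"))
    if pos.size:
        nxt1 = np.full(pos.size, ord("N"), dtype=np.uint8)
        nxt2 = np.full(pos.size, ord("N"), dtype=np.uint8)
        in1 = pos + 1 < n
        in2 = pos + 2 < n
        nxt1[in1] = arr[pos[in1] + 1]
        nxt2[in2] = arr[pos[in2] + 2]
        frames.append(_context_frame(chrom, pos, "+", nxt1, nxt2))
    # minus strand: a G on plus is a C on minus; 5'->3' on minus runs
    # leftward along plus coordinates, complemented
    pos = np.flatnonzero(arr == ord("G"))
    if pos.size:
        nxt1 = np.full(pos.size, ord("N"), dtype=np.uint8)
        nxt2 = np.full(pos.size, ord("N"), dtype=np.uint8)
        in1 = pos - 1 >= 0
        in2 = pos - 2 >= 0
        nxt1[in1] = comp[pos[in1] - 1]
        nxt2[in2] = comp[pos[in2] - 2]
        frames.append(_context_frame(chrom, pos, "-", nxt1, nxt2))
    if not frames:
        return _empty_sites()
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["pos", "strand"], kind="stable", ignore_index=True)


def _context_frame(chrom, pos, strand, nxt1, nxt2) -> pd.DataFrame:
    b1 = _BASE_CODE[nxt1]  # -1 for N/out-of-range
    b2 = _BASE_CODE[nxt2]
    di_code = np.where(b1 >= 0, b1, 4).astype(np.int8)  # NA rank 4
    tri_code = np.where((b1 >= 0) & (b2 >= 0), b1 * 4 + b2, 16).astype(np.int8)
    n = pos.size
    return pd.DataFrame(
        {
            "chrom": pd.Categorical([chrom] * n),
            "pos": pos.astype(np.int64),
            "strand": pd.Categorical([strand] * n, categories=STRAND_CATEGORIES),
            "di": pd.Categorical.from_codes(di_code, categories=DI_CATEGORIES),
            "tri": pd.Categorical.from_codes(tri_code, categories=TRI_CATEGORIES),
            "count_modified": np.zeros(n, dtype=np.int32),
            "count_total": np.zeros(n, dtype=np.int32),
            "level": np.full(n, np.nan),
        }
    )


def _empty_sites() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "di": pd.Series(dtype=str),
            "tri": pd.Series(dtype=str),
            "count_modified": pd.Series(dtype=np.int64),
            "count_total": pd.Series(dtype=np.int64),
            "level": pd.Series(dtype=float),
        }
    )


def classify_contexts(genome: GenomeSequence) -> pd.DataFrame:
    """Every cytosine on both strands with its di-/tri-nucleotide context.

    Contexts truncated by the chromosome end or containing an N are labelled
    ``NA`` at the affected rank (a site may carry a valid di-context and an
    NA tri-context).  Counts are zero and levels NaN until calls are
    attached.
    """
    frames = [
        _classify_chrom(genome.sequences[c], c) for c in genome.chrom_names
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_sites()
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# joining basecalls onto skeletons
# ---------------------------------------------------------------------------


def attach_calls(skeletons: pd.DataFrame, report: pd.DataFrame) -> pd.DataFrame:
    """Join cytosine-report counts onto classified sites.

    Report positions are 1-based and shifted by exactly one on ingest.
    Sites absent from the report stay at zero coverage (flagged by
    ``count_total == 0`` and NaN level) and are excluded from mean-level
    statistics downstream.  A report record at a position/strand that is not
    a classified cytosine raises ``ValueError`` naming the first offender.
    """
    sites = skeletons.copy()
    if len(report) == 0:
        return sites
    rep = report.copy()
    rep["pos0"] = rep["pos"] - 1  # 1-based file -> 0-based internal
    key_sites = pd.MultiIndex.from_frame(sites[["chrom", "pos", "strand"]])
    key_rep = pd.MultiIndex.from_frame(
        rep[["chrom", "pos0", "strand"]].rename(columns={"pos0": "pos"})
    )
    missing = ~key_rep.isin(key_sites)
    if missing.any():
        first = rep[missing].iloc[0]
        raise ValueError(
            "report record at non-cytosine position: "
            f"{first['chrom']}:{first['pos']}({first['strand']})"
        )
    locs = key_sites.get_indexer(key_rep)
    mod = sites["count_modified"].to_numpy().copy()
    tot = sites["count_total"].to_numpy().copy()
    mod[locs] = rep["count_modified"].to_numpy()
    tot[locs] = (rep["count_modified"] + rep["count_unmodified"]).to_numpy()
    sites["count_modified"] = mod
    sites["count_total"] = tot
    with np.errstate(invalid="ignore", divide="ignore"):
        level = np.where(tot > 0, mod / np.maximum(tot, 1), np.nan)
    sites["level"] = level
    return sites


# ---------------------------------------------------------------------------
# region statistics
# ---------------------------------------------------------------------------


@dataclass
class RegionMethylation:
    """Context-specific methylation summary of one region.

    ``density`` is stored per bp; ``density_per_kb`` is the reporting unit.
    """

    region: GenomicInterval
    context: str
    n_sites: int
    mean_level: float  # NaN when no covered sites
    density: float  # per bp

    @property
    def density_per_kb(self) -> float:
        return self.density * 1000.0


def _context_mask(sites: pd.DataFrame, context: str) -> pd.Series:
    if len(context) == 2:
        return sites["di"] == context
    if len(context) == 3:
        return sites["tri"] == context
    raise ValueError(f"context must be a di- or tri-nucleotide, got {context!r}")


def region_methylation(
    sites: pd.DataFrame,
    region: GenomicInterval,
    context: str,
    min_coverage: int = 1,
) -> RegionMethylation:
    """N_CX, mean level m'_CX and density N_CX*m'_CX/L for one region.

    Only sites with ``count_total >= min_coverage`` enter the mean; a region
    with no covered sites of the context has NaN mean and density zero.
    """
    if region.end <= region.start:
        raise ValueError("empty region")
    L = region.end - region.start
    sel = sites[
        (sites["chrom"] == region.chrom)
        & (sites["pos"] >= region.start)
        & (sites["pos"] < region.end)
        & _context_mask(sites, context)
        & (sites["count_total"] >= min_coverage)
    ]
    n = len(sel)
    if n == 0:
        return RegionMethylation(region, context, 0, float("nan"), 0.0)
    mean_level = float(sel["level"].mean())
    density = n * mean_level / L
    return RegionMethylation(region, context, n, mean_level, density)


def density_track(
    sites: pd.DataFrame,
    chrom: str,
    chrom_length: int,
    context: str,
    window: int,
    min_coverage: int = 1,
) -> np.ndarray:
    """Per-window methylation density (per bp) along one chromosome.

    Vectorised equivalent of calling :func:`region_methylation` per window:
    the density of a window is the sum of covered-site levels divided by the
    window length.  The trailing partial window is dropped.
    """
    n_win = chrom_length // window
    sel = sites[
        (sites["chrom"] == chrom)
        & _context_mask(sites, context)
        & (sites["count_total"] >= min_coverage)
    ]
    pos = sel["pos"].to_numpy()
    lev = sel["level"].to_numpy()
    keep = pos < n_win * window
    idx = pos[keep] // window
    out = np.bincount(idx, weights=lev[keep], minlength=n_win)
    return out / window


# ---------------------------------------------------------------------------
# genome-wide frequency tables
# ---------------------------------------------------------------------------


def genome_context_frequencies(
    sites: pd.DataFrame,
    mode: str = "weighted",
    level_threshold: float = 0.5,
    min_coverage: int = 1,
) -> dict[str, pd.Series]:
    """Genome-wide context composition and methylation tables.

    Returns three tables:

    ``cx_fraction``
        Fraction of all classified cytosines in each di-context.
    ``modified_cx_fraction``
        Fraction of modified cytosines per di-context.  ``weighted`` mode
        (default) weights each covered site by its level, i.e. partitions
        the expected modified-basecall mass; ``binary`` mode counts sites
        with level >= ``level_threshold``.
    ``mean_level_tri``
        Mean methylation level per tri-nucleotide context (covered sites).

    Fractions in the first two tables sum to 1 (when any mass exists).
    """
    if mode not in {"weighted", "binary"}:
        raise ValueError(f"mode must be 'weighted' or 'binary', got {mode!r}")
    di_ok = sites[sites["di"] != "NA"]
    cx = di_ok["di"].value_counts(normalize=True).sort_index()
    cx = cx[cx.index != "NA"]

    covered = di_ok[di_ok["count_total"] >= min_coverage]
    if mode == "weighted":
        weights = covered.groupby("di", observed=True)["level"].sum()
    else:
        weights = (
            covered[covered["level"] >= level_threshold]
            .groupby("di", observed=True)["level"]
            .count()
            .astype(float)
        )
    weights = weights[weights.index != "NA"]
    total = weights.sum()
    mod_cx = (weights / total).sort_index() if total > 0 else (weights * 0.0)

    tri_ok = sites[(sites["tri"] != "NA") & (sites["count_total"] >= min_coverage)]
    mean_tri = tri_ok.groupby("tri", observed=True)["level"].mean().sort_index()
    mean_tri = mean_tri[mean_tri.index != "NA"]
    return {
        "cx_fraction": cx,
        "modified_cx_fraction": mod_cx,
        "mean_level_tri": mean_tri,
    }


# ---------------------------------------------------------------------------
# BS vs TAB modification resolution
# ---------------------------------------------------------------------------


@dataclass
class ModificationLevels:
    """5mC / 5hmC split at one site from paired BS and TAB measurements."""

    chrom: str
    pos: int
    strand: str
    mc_level: float
    hmc_level: float  # NaN when no TAB channel
    clamped: bool = False


def resolve_modification_levels(
    bs_site: pd.Series, tab_site: pd.Series | None
) -> ModificationLevels:
    """Split a BS level (mC+hmC) and a TAB level (hmC) into mC and hmC.

    ``mc = max(0, bs - tab)``; negative differences (sampling noise) are
    clamped to zero and flagged.  Without a TAB measurement mC equals the BS
    level and hmC is NaN.
    """
    if tab_site is None:
        return ModificationLevels(
            bs_site["chrom"], int(bs_site["pos"]), bs_site["strand"],
            float(bs_site["level"]), float("nan"),
        )
    same = (
        bs_site["chrom"] == tab_site["chrom"]
        and int(bs_site["pos"]) == int(tab_site["pos"])
        and bs_site["strand"] == tab_site["strand"]
    )
    if not same:
        raise ValueError(
            f"site identity mismatch: {bs_site['chrom']}:{bs_site['pos']} vs "
            f"{tab_site['chrom']}:{tab_site['pos']}"
        )
    hmc = float(tab_site["level"])
    diff = float(bs_site["level"]) - hmc
    clamped = diff < 0
    return ModificationLevels(
        bs_site["chrom"], int(bs_site["pos"]), bs_site["strand"],
        max(0.0, diff), hmc, clamped,
    )


def resolve_modification_table(bs: pd.DataFrame, tab: pd.DataFrame) -> pd.DataFrame:
    """Vectorised BS-TAB resolution over matched site tables."""
    key = ["chrom", "pos", "strand"]
    merged = bs.merge(tab[key + ["level"]], on=key, how="left", suffixes=("_bs", "_tab"))
    hmc = merged["level_tab"].to_numpy()
    mc = merged["level_bs"].to_numpy() - np.nan_to_num(hmc)
    clamped = mc < 0
    n_clamped = int(np.nansum(clamped))
    if n_clamped:
        logger.info("clamped %d negative mC levels to zero", n_clamped)
    out = merged[key].copy()
    out["mc_level"] = np.maximum(mc, 0.0)
    out["hmc_level"] = hmc
    out["clamped"] = clamped
    return out


# ---------------------------------------------------------------------------
# spike-in conversion rate
# ---------------------------------------------------------------------------


@dataclass
class ConversionRate:
    rate: float
    ci_low: float
    ci_high: float
    n_calls: int


def estimate_conversion_rate(spike_sites: pd.DataFrame) -> ConversionRate:
    """Bisulfite non-conversion rate from an unmethylated spike-in.

    Pools modified and total basecalls over all covered spike sites (the
    unmethylated lambda-phage control); any modified call is a conversion
    failure.  Returns the pooled fraction with an exact (Clopper-Pearson)
    binomial 95% CI.
    """
    mod = int(spike_sites["count_modified"].sum())
    tot = int(spike_sites["count_total"].sum())
    if tot == 0:
        raise ValueError("no covered spike-in sites")
    res = stats.binomtest(mod, tot)
    ci = res.proportion_ci(confidence_level=0.95, method="exact")
    return ConversionRate(mod / tot, float(ci.low), float(ci.high), tot)
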