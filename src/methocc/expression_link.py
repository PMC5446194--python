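"""Differential expression with a global-scale correction, and the links
between occupancy, methylation density and transcriptional change.

Normalisation is the median-of-ratios procedure: per-gene geometric means
across samples form a pseudo-reference, and each sample's size factor is
the median ratio of its counts to that reference.  The global-scale
correction multiplies the size factors of one condition by a constant —
the device used to encode a measured change in RNA per cell (a 15%
reduction in knockout tissue, i.e. factor x1.15) that per-library
normalisation cannot see.

Differential testing is a self-contained moderated negative-binomial Wald
test: per-gene moment dispersions are shrunk halfway toward a fitted
``a + b/mean`` trend, and the Wald statistic of the log2 fold-change is
referred to a t distribution with the within-group residual degrees of
freedom.  The acceptance surface is calibration and power on simulated
counts, not numerical agreement with any particular DE package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import GenomicInterval
from .occupancy import OccupancyTrack


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (one per sample column).

    Genes with a zero count in any sample are excluded from the medians;
    at least one all-positive gene is required.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    x = counts.to_numpy(dtype=float)
    allpos = (x > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene with positive counts in every sample")
    logx = np.log(x[allpos])
    log_geomean = logx.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logx - log_geomean, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def apply_global_scale(
    factors: pd.Series,
    conditions: pd.Series,
    condition: str = "KO",
    multiplier: float = 1.15,
) -> pd.Series:
    """Multiply the size factors of one condition by a constant.

    ``multiplier`` > 1 shrinks that condition's normalised counts
    (normalised = count / factor), encoding a global reduction of RNA per
    cell that library normalisation absorbs.
    """
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    out = factors.copy()
    mask = conditions.reindex(factors.index) == condition
    out[mask] = out[mask] * multiplier
    return out


def tpm_matrix(counts: pd.DataFrame, gene_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million from counts and exonic lengths (bp)."""
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any():
        raise ValueError("gene lengths missing for some genes")
    rate = counts.div(lengths / 1e3, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


# ---------------------------------------------------------------------------
# differential testing
# ---------------------------------------------------------------------------


@dataclass
class DEOptions:
    dispersion_floor: float = 1e-8
    dispersion_cap: float = 10.0
    shrinkage_weight: float = 0.3  # weight of the per-gene moment estimate
    log_pseudocount: float = 1e-8


def nb_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    conditions: pd.Series,
    contrast: tuple[str, str] = ("WT", "KO"),
    options: DEOptions = DEOptions(),
) -> pd.DataFrame:
    """Moderated NB Wald test of ``contrast[1]`` versus ``contrast[0]``.

    Returns a frame indexed by gene with ``base_mean, log2fc, se, stat,
    p_value, padj``.  Genes with zero normalised counts in both groups get
    NaN statistics and are excluded from the BH adjustment.
    """
    ref, alt = contrast
    cond = conditions.reindex(counts.columns)
    cols_ref = counts.columns[cond == ref]
    cols_alt = counts.columns[cond == alt]
    if len(cols_ref) < 2 or len(cols_alt) < 2:
        raise ValueError(f"need >=2 replicates per condition for {contrast}")
    sf_ref = factors[cols_ref].to_numpy()
    sf_alt = factors[cols_alt].to_numpy()
    x_ref = counts[cols_ref].to_numpy(dtype=float) / sf_ref
    x_alt = counts[cols_alt].to_numpy(dtype=float) / sf_alt
    n_ref, n_alt = x_ref.shape[1], x_alt.shape[1]

    q_ref = x_ref.mean(axis=1)
    q_alt = x_alt.mean(axis=1)
    base_mean = (q_ref * n_ref + q_alt * n_alt) / (n_ref + n_alt)

    # pooled moment dispersion: Var(K_j/s_j) = q/s_j + alpha q^2
    var_ref = x_ref.var(axis=1, ddof=1)
    var_alt = x_alt.var(axis=1, ddof=1)
    inv_sf_ref = float(np.mean(1.0 / sf_ref))
    inv_sf_alt = float(np.mean(1.0 / sf_alt))
    with np.errstate(divide="ignore", invalid="ignore"):
        a_ref = (var_ref - q_ref * inv_sf_ref) / q_ref**2
        a_alt = (var_alt - q_alt * inv_sf_alt) / q_alt**2
    w_ref, w_alt = n_ref - 1, n_alt - 1
    raw = np.where(
        np.isfinite(a_ref) & np.isfinite(a_alt),
        (w_ref * a_ref + w_alt * a_alt) / (w_ref + w_alt),
        np.where(np.isfinite(a_ref), a_ref, a_alt),
    )
    raw = np.clip(raw, options.dispersion_floor, options.dispersion_cap)

    trend = _dispersion_trend(base_mean, raw, options)
    w = options.shrinkage_weight
    disp = np.clip(
        w * raw + (1 - w) * trend, options.dispersion_floor, options.dispersion_cap
    )

    eps = options.log_pseudocount
    log2fc = np.log2((q_alt + eps) / (q_ref + eps))
    var_q_ref = q_ref * inv_sf_ref / n_ref + disp * q_ref**2 / n_ref
    var_q_alt = q_alt * inv_sf_alt / n_alt + disp * q_alt**2 / n_alt
    ln2sq = np.log(2.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = var_q_ref / np.maximum(q_ref, eps) ** 2 + var_q_alt / np.maximum(
            q_alt, eps
        ) ** 2
        se = np.sqrt(se2 / ln2sq)
        stat = log2fc / se
    p = 2.0 * stats.norm.sf(np.abs(stat))

    testable = (q_ref + q_alt) > 0
    p = np.where(testable, p, np.nan)
    identical = testable & (log2fc == 0.0)
    p = np.where(identical, 1.0, p)
    padj = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        padj[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": np.where(testable, log2fc, np.nan),
            "se": se,
            "stat": stat,
            "p_value": p,
            "padj": padj,
            "dispersion": disp,
        },
        index=counts.index,
    )


def _dispersion_trend(
    mean: np.ndarray, disp: np.ndarray, options: DEOptions
) -> np.ndarray:
    """Least-squares fit of per-gene dispersions to ``a + b/mean``."""
    ok = (mean > 0) & np.isfinite(disp) & (disp > options.dispersion_floor)
    if ok.sum() < 10:
        fallback = float(np.median(disp[np.isfinite(disp)])) if np.isfinite(disp).any() else 0.1
        return np.full_like(disp, max(fallback, options.dispersion_floor))
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mean[ok]])
    coef, *_ = np.linalg.lstsq(X, disp[ok], rcond=None)
    a, b = coef
    a = max(a, options.dispersion_floor)
    b = max(b, 0.0)
    with np.errstate(divide="ignore"):
        trend = a + b / np.maximum(mean, 1e-12)
    return np.clip(trend, options.dispersion_floor, options.dispersion_cap)


# ---------------------------------------------------------------------------
# gene classification
# ---------------------------------------------------------------------------

CLASSES = ("up", "down", "unchanged", "other", "filtered")


def classify_genes(
    results: pd.DataFrame,
    tpm: pd.DataFrame,
    padj_de: float = 0.05,
    padj_unchanged: float = 0.5,
    log2fc_unchanged: float = 0.01,
    tpm_min: float = 5.0,
) -> pd.Series:
    """One class per gene under fixed thresholds.

    ``filtered``: TPM below ``tpm_min`` in every sample (constitutively low
    expression); ``up``/``down``: padj < 0.05 with the matching sign;
    ``unchanged``: padj > 0.5 and |log2FC| < 0.01; ``other``: the rest.
    """
    if not results.index.equals(tpm.index):
        tpm = tpm.reindex(results.index)
    low = (tpm < tpm_min).all(axis=1).to_numpy()
    padj = results["padj"].to_numpy()
    l2fc = results["log2fc"].to_numpy()
    cls = np.full(len(results), "other", dtype=object)
    with np.errstate(invalid="ignore"):
        cls[(padj < padj_de) & (l2fc > 0)] = "up"
        cls[(padj < padj_de) & (l2fc < 0)] = "down"
        cls[(padj > padj_unchanged) & (np.abs(l2fc) < log2fc_unchanged)] = "unchanged"
    cls[~np.isfinite(padj)] = "other"
    cls[low] = "filtered"
    return pd.Series(pd.Categorical(cls, categories=CLASSES), index=results.index, name="class")


# ---------------------------------------------------------------------------
# gene-level occupancy
# ---------------------------------------------------------------------------


def gene_occupancy(
    genes: pd.DataFrame,
    track: OccupancyTrack,
    chrom_lengths: dict[str, int],
    flank: int = 100_000,
) -> pd.DataFrame:
    """Window-weighted mean log2(ChIP/Input) over gene bodies ± flank.

    Partial windows are weighted by their overlap.  Flanks truncated at
    chromosome ends are clipped and flagged.
    """
    tracks: dict[str, tuple[int, np.ndarray]] = {}
    for chrom, sub in track.windows.groupby("chrom", sort=False, observed=True):
        width = int(sub["end"].iloc[0] - sub["start"].iloc[0])
        tracks[str(chrom)] = (width, track.log2_ratio[sub.index.to_numpy()])

    def weighted_mean(chrom: str, lo: int, hi: int) -> float:
        width, vals = tracks[chrom]
        covered_end = vals.size * width
        lo, hi = max(lo, 0), min(hi, covered_end)
        if hi <= lo:
            return float("nan")
        w_lo, w_hi = lo // width, -(-hi // width)
        total = 0.0
        weight = 0.0
        for w_idx in range(w_lo, w_hi):
            seg = min(hi, (w_idx + 1) * width) - max(lo, w_idx * width)
            total += seg * vals[w_idx]
            weight += seg
        return total / weight

    rows = []
    for row in genes.itertuples(index=False):
        chrom = row.chrom
        body = weighted_mean(chrom, row.start, row.end)
        lo, hi = row.start - flank, row.end + flank
        clipped = lo < 0 or hi > chrom_lengths[chrom]
        rows.append(
            {
                "gene_id": row.gene_id,
                "body_mean": body,
                "flank_mean": weighted_mean(chrom, lo, hi),
                "clipped": clipped,
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


# ---------------------------------------------------------------------------
# rank-ordered density curves
# ---------------------------------------------------------------------------


def rolling_density(
    occupancies: np.ndarray,
    densities: np.ndarray,
    window: int = 400,
    step: int = 80,
) -> pd.DataFrame:
    """Rolling mean of densities over genes ranked by occupancy.

    Point k averages the genes ranked ``[k*step, k*step + window)``; ties
    in occupancy keep their original order (stable sort).  Also reports
    the mean occupancy of each window of genes.
    """
    occupancies = np.asarray(occupancies, dtype=float)
    densities = np.asarray(densities, dtype=float)
    n = occupancies.size
    if n < window:
        raise ValueError(f"need at least {window} genes, got {n}")
    order = np.argsort(occupancies, kind="stable")
    d = densities[order]
    o = occupancies[order]
    n_points = (n - window) // step + 1
    rows = [
        {
            "rank_start": k * step,
            "mean_occupancy": float(o[k * step : k * step + window].mean()),
            "mean_density": float(d[k * step : k * step + window].mean()),
        }
        for k in range(n_points)
    ]
    return pd.DataFrame(rows)


def window_group_curve(
    occupancies: np.ndarray,
    densities: np.ndarray,
    group: int = 1000,
) -> pd.DataFrame:
    """Mean density in consecutive non-overlapping occupancy-ranked groups.

    The trailing remainder (fewer than ``group`` windows) is dropped.
    """
    occupancies = np.asarray(occupancies, dtype=float)
    densities = np.asarray(densities, dtype=float)
    n = occupancies.size
    if n < group:
        raise ValueError(f"need at least {group} windows, got {n}")
    order = np.argsort(occupancies, kind="stable")
    n_groups = n // group
    rows = []
    for g in range(n_groups):
        sel = order[g * group : (g + 1) * group]
        rows.append(
            {
                "group": g,
                "mean_occupancy": float(occupancies[sel].mean()),
                "mean_density": float(densities[sel].mean()),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# domain overlap and summary statistics
# ---------------------------------------------------------------------------

OVERLAP_CATEGORIES = (
    "inside_enriched",
    "overlapping_enriched",
    "inside_depleted",
    "overlapping_depleted",
    "neither",
)


def domain_overlap(
    genes: pd.DataFrame,
    classes: pd.Series,
    segments: Sequence,
) -> pd.DataFrame:
    """Cross-tabulate gene classes against domain membership.

    A gene is ``inside`` a domain when fully contained, ``overlapping``
    when partially; enriched domains are checked first, so a gene touching
    both kinds counts with the enriched side.  Returns per-class
    proportions over the membership categories.
    """
    enr = [s.interval for s in segments if s.enrichment_score > 0]
    dep = [s.interval for s in segments if s.enrichment_score < 0]

    def status(chrom: str, start: int, end: int) -> str:
        for ivs, tag in ((enr, "enriched"), (dep, "depleted")):
            best = "none"
            for iv in ivs:
                if iv.chrom != chrom or iv.end <= start or end <= iv.start:
                    continue
                if iv.start <= start and end <= iv.end:
                    best = "inside"
                    break
                best = "overlapping"
            if best != "none":
                return f"{best}_{tag}"
        return "neither"

    cats = [
        status(row.chrom, row.start, row.end) for row in genes.itertuples(index=False)
    ]
    df = pd.DataFrame(
        {
            "class": classes.reindex(genes["gene_id"]).to_numpy(),
            "membership": pd.Categorical(cats, categories=OVERLAP_CATEGORIES),
        }
    )
    table = (
        df.groupby(["class", "membership"], observed=False)
        .size()
        .unstack("membership", fill_value=0)
    )
    totals = table.sum(axis=1)
    props = table.div(totals.replace(0, np.nan), axis=0)
    props["n_genes"] = totals
    return props


def occupancy_expression_stats(
    gene_occ: pd.Series,
    de_ko: pd.DataFrame,
    de_oe: Optional[pd.DataFrame] = None,
    classes: Optional[pd.Series] = None,
    gene_lengths: Optional[pd.Series] = None,
    n_bins: int = 10,
) -> dict:
    """Spearman occupancy-vs-log2FC correlations and companion summaries.

    * ``rho_ko`` / ``rho_oe``: Spearman rank correlation (average ranks on
      ties) between gene occupancy and the KO/OE log2 fold-changes;
    * per-occupancy-bin fractions of up/down/unchanged classes (when
      classes are given);
    * a rank-sum (Mann-Whitney) comparison of gene length for up versus
      unchanged genes (when lengths are given).
    """
    common = gene_occ.index.intersection(de_ko.index)
    if len(common) < 10:
        raise ValueError("need at least 10 shared genes")
    occ = gene_occ.loc[common]
    out: dict = {}
    ok = np.isfinite(de_ko.loc[common, "log2fc"])
    rho, p = stats.spearmanr(occ[ok], de_ko.loc[common, "log2fc"][ok])
    out["rho_ko"], out["rho_ko_p"] = float(rho), float(p)
    if de_oe is not None:
        ok = np.isfinite(de_oe.loc[common, "log2fc"])
        rho, p = stats.spearmanr(occ[ok], de_oe.loc[common, "log2fc"][ok])
        out["rho_oe"], out["rho_oe_p"] = float(rho), float(p)
    if classes is not None:
        cls = classes.reindex(common)
        bins = pd.qcut(occ.rank(method="first"), n_bins, labels=False)
        frac = (
            pd.DataFrame({"bin": bins, "class": cls.to_numpy()})
            .groupby("bin", observed=True)["class"]
            .value_counts(normalize=True)
            .unstack(fill_value=0.0)
        )
        out["class_fractions_by_occupancy_bin"] = frac
    if gene_lengths is not None and classes is not None:
        cls = classes.reindex(common)
        lengths = gene_lengths.reindex(common)
        up = lengths[(cls == "up").to_numpy()]
        unchanged = lengths[(cls == "unchanged").to_numpy()]
        if len(up) >= 3 and len(unchanged) >= 3:
            u, p = stats.mannwhitneyu(up, unchanged, alternative="two-sided")
            out["length_up_vs_unchanged"] = {
                "median_up": float(np.median(up)),
                "median_unchanged": float(np.median(unchanged)),
                "u_statistic": float(u),
                "p_value": float(p),
            }
    return out
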