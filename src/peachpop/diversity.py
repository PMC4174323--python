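"""Windowed population-genetic statistics on dosage-coded genotypes.

Implements the estimators the selection scan is built from: segregating
sites S, nucleotide diversity pi (unbiased frequency form, equivalent to
averaging over all haplotype pairs), Watterson's theta_w = S/(a1*L), and
Tajima's D with its full 1989 constant set; plus per-accession heterozygous
call ratios, composite (dosage) r-squared LD with a binned decay curve and
half-decay distance, and the plain 0/1/2-covariance PCA.

Missing genotypes are handled pairwise-complete: each site uses its called
samples only, and variant sites with fewer than two called samples in the
subgroup are skipped with the window's effective length reduced by one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import MISSING, GenotypeMatrix, SampleGroups

DEFAULT_S_MIN = 3  # windows with fewer segregating sites get D = undefined


@dataclass(frozen=True)
class TajimaConstants:
    """The a1..e2 constants of Tajima's neutrality test for n sequences."""

    n_seq: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n_seq: int) -> TajimaConstants:
    if n_seq < 2:
        raise ValueError("need at least 2 sequences")
    i = np.arange(1, n_seq)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n_seq + 1) / (3.0 * (n_seq - 1))
    b2 = 2.0 * (n_seq**2 + n_seq + 3) / (9.0 * n_seq * (n_seq - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n_seq + 2) / (a1 * n_seq) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return TajimaConstants(n_seq, a1, a2, b1, b2, c1, c2, e1, e2)


# ---------------------------------------------------------------------------
# per-window estimators


def _site_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(called diploids, derived-allele count) per site for one subgroup."""
    called = codes != MISSING
    n_called = called.sum(axis=0)
    derived = np.where(called, codes, 0).sum(axis=0)
    return n_called, derived


def segregating_sites(codes: np.ndarray) -> int:
    """Sites with >= 2 distinct alleles among called genotypes."""
    if codes.size == 0:
        return 0
    n_called, derived = _site_counts(codes)
    return int(((derived > 0) & (derived < 2 * n_called)).sum())


def pairwise_diversity_sum(codes: np.ndarray) -> tuple[float, int]:
    """(sum over usable sites of unbiased per-site heterozygosity, n_usable).

    Per site with n_hap called haplotypes and derived frequency p:
    2*p*(1-p) * n_hap/(n_hap - 1). Sites with < 2 called diploids are
    excluded and reported via the second element.
    """
    if codes.size == 0:
        return 0.0, 0
    n_called, derived = _site_counts(codes)
    usable = n_called >= 2
    n_hap = 2.0 * n_called[usable]
    p = derived[usable] / n_hap
    total = float(np.sum(2.0 * p * (1.0 - p) * n_hap / (n_hap - 1.0)))
    return total, int(usable.sum())


def nucleotide_diversity(codes: np.ndarray, window_bp: int) -> float:
    """pi per site over a window; NaN if no usable length remains.

    window_bp is the physical window length; variant sites that lack two
    called samples shrink the effective length.
    """
    n_skipped = codes.shape[1] - pairwise_diversity_sum(codes)[1] if codes.size else 0
    length = window_bp - n_skipped
    if length <= 0:
        return float("nan")
    return pairwise_diversity_sum(codes)[0] / length


def watterson_theta(s: int, n_hap: int, length: float) -> float:
    """Watterson's estimator per site, S / (a1(n_hap) * L)."""
    if length <= 0:
        raise ValueError("length must be positive")
    if s == 0:
        return 0.0
    return s / tajima_constants(n_hap).a1 / length


def tajimas_d(codes: np.ndarray, s_min: int = DEFAULT_S_MIN) -> float:
    """Tajima's D for one subgroup-window; NaN when S < s_min.

    D = (pi_total - S/a1) / sqrt(e1*S + e2*S*(S-1)) with constants for
    n_hap = 2 * (samples in the slice).
    """
    s = segregating_sites(codes)
    if s < max(s_min, 1):
        return float("nan")
    c = tajima_constants(2 * codes.shape[0])
    pi_total, _ = pairwise_diversity_sum(codes)
    var = c.e1 * s + c.e2 * s * (s - 1)
    return (pi_total - s / c.a1) / math.sqrt(var)


def window_stats(
    matrix: GenotypeMatrix,
    groups: SampleGroups,
    windows: list[tuple[str, int, int]],
    subgroups: list[str] | None = None,
    s_min: int = DEFAULT_S_MIN,
) -> pd.DataFrame:
    """Per (window x subgroup) table of S, pi, theta_w and Tajima's D."""
    subgroups = subgroups if subgroups is not None else groups.subgroups
    rows = []
    for name in subgroups:
        idx = matrix.sample_indices(groups.samples_of(name))
        n_hap = 2 * len(idx)
        for contig, start, end in windows:
            codes = matrix.codes[np.ix_(idx, np.where(matrix.window_mask(contig, start, end))[0])]
            s = segregating_sites(codes)
            pi_sum, n_usable = pairwise_diversity_sum(codes)
            length = (end - start) - (codes.shape[1] - n_usable)
            rows.append(
                {
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "subgroup": name,
                    "n_accessions": len(idx),
                    "length": length,
                    "S": s,
                    "pi": pi_sum / length if length > 0 else float("nan"),
                    "theta_w": watterson_theta(s, n_hap, length) if length > 0 else float("nan"),
                    "D": tajimas_d(codes, s_min=s_min),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heterozygosity


def het_ratio(matrix: GenotypeMatrix, sample_id: str) -> float:
    """Fraction of a sample's called SNP genotypes that are heterozygous."""
    k = matrix.sample_indices([sample_id])[0]
    row = matrix.codes[k]
    called = int((row != MISSING).sum())
    if called == 0:
        return float("nan")
    return float((row == 1).sum()) / called


def het_profile(matrix: GenotypeMatrix, groups: SampleGroups) -> pd.DataFrame:
    """Per-accession heterozygous-call ratio with subgroup/role labels."""
    rows = []
    for rec in groups.table.itertuples():
        if rec.sample_id not in matrix.sample_ids:
            continue
        k = matrix.sample_indices([rec.sample_id])[0]
        row = matrix.codes[k]
        called = int((row != MISSING).sum())
        het = int((row == 1).sum())
        rows.append(
            {
                "sample_id": rec.sample_id,
                "subgroup": rec.subgroup,
                "role": rec.role,
                "called_sites": called,
                "het_calls": het,
                "het_ratio": het / called if called else float("nan"),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linkage disequilibrium


def _pair_r2(x: np.ndarray, y: np.ndarray, maf_min: float) -> float:
    both = (x != MISSING) & (y != MISSING)
    if both.sum() < 2:
        return float("nan")
    xv, yv = x[both].astype(float), y[both].astype(float)
    for v in (xv, yv):
        p = v.sum() / (2 * v.size)
        if min(p, 1 - p) < maf_min:
            return float("nan")
    sx, sy = xv.std(), yv.std()
    if sx == 0 or sy == 0:
        return float("nan")
    r = float(np.mean((xv - xv.mean()) * (yv - yv.mean())) / (sx * sy))
    return r * r


def ld_r2(
    matrix: GenotypeMatrix, site_i: int, site_j: int, maf_min: float = 0.1
) -> float:
    """Composite LD: squared Pearson correlation of the dosage vectors.

    Computed over samples called at both sites; NaN when either site fails
    the MAF threshold or is monomorphic after masking.
    """
    return _pair_r2(matrix.codes[:, site_i], matrix.codes[:, site_j], maf_min)


@dataclass
class LDDecayCurve:
    """Mean r-squared per distance bin with the half-decay summary."""

    table: pd.DataFrame  # columns: bin_start, bin_end, mean_r2, n_pairs
    max_r2: float
    half_decay_bp: float  # NaN when the curve never falls below max/2

    @property
    def empty(self) -> bool:
        return self.table.empty


def ld_decay(
    matrix: GenotypeMatrix,
    sample_ids: list[str],
    max_dist: int = 1_000_000,
    bin_width: int = 1_000,
    maf_min: float = 0.1,
    max_sites_per_contig: int | None = None,
) -> LDDecayCurve:
    """Binned r-squared decay over intra-contig site pairs for a group.

    The half-decay distance is the linearly interpolated distance (between
    bin midpoints) where mean r-squared first crosses half its maximum.
    ``max_sites_per_contig`` thins sites deterministically (evenly spaced)
    to bound the quadratic pair count on dense cohorts.
    """
    if not sample_ids:
        raise ValueError("empty sample group")
    idx = matrix.sample_indices(sample_ids)
    dose = matrix.codes[idx].astype(float)
    dose[dose == MISSING] = np.nan
    contigs = matrix.sites["contig"].to_numpy()
    pos = matrix.sites["pos"].to_numpy()

    n_bins = int(np.ceil(max_dist / bin_width))
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for contig in pd.unique(contigs):
        cols = np.where(contigs == contig)[0]
        if max_sites_per_contig and cols.size > max_sites_per_contig:
            pick = np.linspace(0, cols.size - 1, max_sites_per_contig).round().astype(int)
            cols = cols[np.unique(pick)]
        cpos = pos[cols].astype(np.int64)
        for a_k in range(cols.size - 1):
            hi = int(np.searchsorted(cpos, cpos[a_k] + max_dist, side="right"))
            bs = np.arange(a_k + 1, hi)
            if bs.size == 0:
                continue
            d = cpos[bs] - cpos[a_k]
            x = dose[:, cols[a_k]][:, None]
            y = dose[:, cols[bs]]
            valid = ~np.isnan(x) & ~np.isnan(y)
            n = valid.sum(axis=0)
            xv = np.where(valid, x, 0.0)
            yv = np.where(valid, y, 0.0)
            with np.errstate(invalid="ignore", divide="ignore"):
                mx = xv.sum(axis=0) / n
                my = yv.sum(axis=0) / n
                cov = (xv * yv).sum(axis=0) / n - mx * my
                vx = (xv**2).sum(axis=0) / n - mx**2
                vy = (yv**2).sum(axis=0) / n - my**2
                px = mx / 2.0
                py = my / 2.0
                r2 = cov**2 / (vx * vy)
            ok = (
                (n >= 2)
                & (vx > 0)
                & (vy > 0)
                & (np.minimum(px, 1 - px) >= maf_min)
                & (np.minimum(py, 1 - py) >= maf_min)
                & (d > 0)
            )
            k = np.clip((d - 1) // bin_width, 0, n_bins - 1)
            np.add.at(sums, k[ok], r2[ok])
            np.add.at(counts, k[ok], 1)
    have = counts > 0
    table = pd.DataFrame(
        {
            "bin_start": np.arange(n_bins)[have] * bin_width,
            "bin_end": (np.arange(n_bins)[have] + 1) * bin_width,
            "mean_r2": sums[have] / counts[have],
            "n_pairs": counts[have],
        }
    )
    if table.empty:
        return LDDecayCurve(table, float("nan"), float("nan"))
    mids = (table["bin_start"] + table["bin_end"]).to_numpy() / 2.0
    means = table["mean_r2"].to_numpy()
    max_r2 = float(means.max())
    half = max_r2 / 2.0
    half_bp = float("nan")
    start_k = int(means.argmax())
    for k in range(start_k, len(means)):
        if means[k] <= half:
            if k == 0:
                half_bp = float(mids[0])
            else:
                x0, x1 = mids[k - 1], mids[k]
                y0, y1 = means[k - 1], means[k]
                half_bp = float(x0 + (y0 - half) / (y0 - y1) * (x1 - x0))
            break
    return LDDecayCurve(table, max_r2, half_bp)


# ---------------------------------------------------------------------------
# PCA


def pca_genotypes(matrix: GenotypeMatrix, n_components: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the 0/1/2 genotype matrix via the sample covariance.

    Missing calls are imputed to the per-site mean dosage; sites are
    centered but not variance-standardized. Returns (coordinates,
    eigenvalues): coordinates are eigenvectors scaled by sqrt(eigenvalue),
    eigenvalues non-increasing, eigenvector sign fixed so the
    largest-magnitude loading is positive.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = matrix.codes.astype(float)
    miss = x == MISSING
    col_mean = np.where(
        (~miss).sum(axis=0) > 0,
        np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
        0.0,
    )
    x = np.where(miss, col_mean, x)
    x -= x.mean(axis=0)
    if not np.any(x != 0):
        raise ValueError("all sites monomorphic")
    cov = x @ x.T / max(matrix.n_sites - 1, 1)
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    k = min(n_components, len(vals))
    vals, vecs = vals[:k], vecs[:, :k]
    for j in range(k):
        lead = np.argmax(np.abs(vecs[:, j]))
        if vecs[lead, j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.maximum(vals, 0.0))
    return coords, vals
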