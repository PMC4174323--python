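"""Selection scan: per-subgroup candidate windows and their set-logic
combination into edible- vs ornamental-selected regions, corroborated by
reduction of diversity (ROD) and Hudson-style Fst.

A window is a candidate in a subgroup when the "intensity" of its Tajima's
D — the percent distance from the midpoint of the subgroup's neutral range,
normalized so the range boundary sits at 100% — exceeds 100%. Candidates
are then combined across subgroups: a window is edible-selected when it is
a candidate in every required edible subgroup but not in the ornamental
subgroup, and ornamental-selected when it is a candidate in the ornamental
subgroup but in none of the edible ones. Labeled windows are merged into
maximal contiguous regions and annotated with overlapping genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import MISSING, GenomeAnnotation, GenotypeMatrix
from .neutrality import NeutralRange

Window = tuple[str, int, int]


# ---------------------------------------------------------------------------
# intensity and per-subgroup scan


def intensity(d: float, neutral_range: NeutralRange) -> tuple[float, str]:
    """Percent deviation of D from the neutral-range midpoint.

    Normalized asymmetrically so that D equal to either limit scores
    exactly 100%; direction is 'high' (intermediate-frequency excess) or
    'low' (low-frequency excess).
    """
    if d is None or math.isnan(d):
        raise ValueError("intensity undefined for undefined D")
    m = neutral_range.midpoint
    if d >= m:
        return 100.0 * (d - m) / (neutral_range.upper - m), "high"
    return 100.0 * (m - d) / (m - neutral_range.lower), "low"


def scan_subgroup(stats: pd.DataFrame, neutral_range: NeutralRange) -> pd.DataFrame:
    """Candidate windows of one subgroup: intensity strictly above 100%.

    ``stats`` is the window_stats table restricted to one subgroup (columns
    contig, start, end, D). Windows with undefined D are never candidates.
    """
    rows = []
    for rec in stats.itertuples():
        if rec.D is None or math.isnan(rec.D):
            continue
        pct, direction = intensity(rec.D, neutral_range)
        if pct > 100.0:
            rows.append(
                {
                    "contig": rec.contig,
                    "start": rec.start,
                    "end": rec.end,
                    "subgroup": rec.subgroup,
                    "D": rec.D,
                    "intensity": pct,
                    "direction": direction,
                }
            )
    return pd.DataFrame(
        rows, columns=["contig", "start", "end", "subgroup", "D", "intensity", "direction"]
    )


# ---------------------------------------------------------------------------
# combining subgroups


@dataclass
class SelectionRegions:
    """Merged labeled intervals with their constituent windows."""

    label: str
    regions: list[tuple[str, int, int]]
    windows: set[Window]
    genes: dict[tuple[str, int, int], list[str]] = field(default_factory=dict)


@dataclass(frozen=True)
class CombineRules:
    """Which subgroups drive each label; ignored subgroups play no part."""

    edible_subgroups: tuple[str, ...] = ("C", "D", "E", "F")
    ornamental_subgroup: str = "A"
    ignore_subgroups: tuple[str, ...] = ("B",)


def _merge_windows(windows: set[Window]) -> list[tuple[str, int, int]]:
    merged: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(windows):
        if merged and merged[-1][0] == contig and merged[-1][2] >= start:
            merged[-1] = (contig, merged[-1][1], max(merged[-1][2], end))
        else:
            merged.append((contig, start, end))
    return merged


def combine_subgroups(
    candidates: dict[str, set[Window]], rules: CombineRules = CombineRules()
) -> tuple[SelectionRegions, SelectionRegions]:
    """Apply the two-label set logic on a shared window grid.

    edible_selected = (intersection of all edible subgroups) minus the
    ornamental subgroup; ornamental_selected = ornamental minus the union
    of the edible subgroups. Ignored subgroups are dropped entirely.
    """
    for name in (*rules.edible_subgroups, rules.ornamental_subgroup):
        if name in rules.ignore_subgroups:
            raise ValueError(f"subgroup {name} both required and ignored")
        if name not in candidates:
            raise KeyError(f"missing candidate set for subgroup {name}")
    edible_sets = [candidates[g] for g in rules.edible_subgroups]
    orn = candidates[rules.ornamental_subgroup]
    edible_core = set.intersection(*edible_sets) if edible_sets else set()
    edible_windows = edible_core - orn
    orn_windows = orn - set.union(*edible_sets) if edible_sets else set(orn)
    assert not (edible_windows & orn_windows)
    return (
        SelectionRegions("edible_selected", _merge_windows(edible_windows), edible_windows),
        SelectionRegions(
            "ornamental_selected", _merge_windows(orn_windows), orn_windows
        ),
    )


# ---------------------------------------------------------------------------
# corroborating statistics


def rod(pi_cul: float, pi_wild: float) -> float:
    """Reduction of diversity, 1 - pi_cultivated/pi_wild; NaN if pi_wild=0."""
    if math.isnan(pi_cul) or math.isnan(pi_wild) or pi_wild == 0:
        return float("nan")
    return 1.0 - pi_cul / pi_wild


def _freqs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    called = codes != MISSING
    n_called = called.sum(axis=0)
    derived = np.where(called, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, derived / (2.0 * n_called), np.nan)
    return p, n_called


def fst_hudson(
    matrix: GenotypeMatrix,
    group1: list[str],
    group2: list[str],
    site_mask: np.ndarray,
) -> float:
    """Hudson-style Fst = (pi_between - pi_within)/pi_between for a window.

    pi_between is the mean pairwise difference between haplotypes from
    different groups, summed over sites; pi_within averages the two
    unbiased within-group sums. NaN when either group has < 2 called
    samples throughout or pi_between is 0.
    """
    cols = np.where(np.asarray(site_mask))[0]
    if cols.size == 0:
        return float("nan")
    c1 = matrix.codes[np.ix_(matrix.sample_indices(group1), cols)]
    c2 = matrix.codes[np.ix_(matrix.sample_indices(group2), cols)]
    p1, n1 = _freqs(c1)
    p2, n2 = _freqs(c2)
    ok = (n1 >= 2) & (n2 >= 2)
    if not ok.any():
        return float("nan")
    p1, p2 = p1[ok], p2[ok]
    h1, h2 = 2.0 * n1[ok], 2.0 * n2[ok]
    between = float(np.sum(p1 * (1 - p2) + p2 * (1 - p1)))
    w1 = float(np.sum(2.0 * p1 * (1 - p1) * h1 / (h1 - 1)))
    w2 = float(np.sum(2.0 * p2 * (1 - p2) * h2 / (h2 - 1)))
    within = 0.5 * (w1 + w2)
    if between == 0:
        return float("nan")
    return (between - within) / between


def divergence_table(
    matrix: GenotypeMatrix,
    windows: list[Window],
    cultivated: list[str],
    wild: list[str],
) -> pd.DataFrame:
    """Per-window pi_cul, pi_wild, ROD and Fst (cultivated vs wild)."""
    from .diversity import pairwise_diversity_sum

    rows = []
    wild_idx = matrix.sample_indices(wild)
    cul_idx = matrix.sample_indices(cultivated)
    for contig, start, end in windows:
        mask = matrix.window_mask(contig, start, end)
        cols = np.where(mask)[0]
        cw = matrix.codes[np.ix_(cul_idx, cols)]
        ww = matrix.codes[np.ix_(wild_idx, cols)]
        span = end - start
        pc_sum, pc_n = pairwise_diversity_sum(cw)
        pw_sum, pw_n = pairwise_diversity_sum(ww)
        lc = span - (cols.size - pc_n)
        lw = span - (cols.size - pw_n)
        pi_cul = pc_sum / lc if lc > 0 else float("nan")
        pi_wild = pw_sum / lw if lw > 0 else float("nan")
        rows.append(
            {
                "contig": contig,
                "start": start,
                "end": end,
                "pi_cul": pi_cul,
                "pi_wild": pi_wild,
                "ROD": rod(pi_cul, pi_wild),
                "Fst": fst_hudson(matrix, cultivated, wild, mask),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gene mapping


def map_genes(
    regions: list[tuple[str, int, int]], annotation: GenomeAnnotation
) -> dict[tuple[str, int, int], list[str]]:
    """Gene IDs whose span overlaps each region by >= 1 bp, sorted, unique."""
    out = {}
    for contig, start, end in regions:
        genes = annotation.genes_overlapping(contig, start, end)
        out[(contig, start, end)] = sorted({g.gene_id for g in genes})
    return out
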