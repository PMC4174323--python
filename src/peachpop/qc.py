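"""Quality-control arithmetic for resequencing-based SNP calls.

Covers the simple but load-bearing report numbers: the mixture model for
mean genotyping accuracy given the heterozygous-call fraction, pooled
variant-calling sensitivity from validation counts, and percentage shares
of (possibly overlapping) group SNP counts.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class AccuracyModel:
    """Mean accuracy as a mixture of het- and hom-call accuracies.

    rho is the heterozygous fraction of calls; accuracies are percents
    from independent validation (defaults: Sanger-validated 63.6% for het
    and 99.4% for hom calls).
    """

    rho: float
    acc_het: float = 63.6
    acc_hom: float = 99.4

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        for v in (self.acc_het, self.acc_hom):
            if not 0.0 <= v <= 100.0:
                raise ValueError("accuracies are percents in [0, 100]")


def mean_accuracy(model: AccuracyModel) -> float:
    """rho * acc_het + (1 - rho) * acc_hom, in percent."""
    return model.rho * model.acc_het + (1.0 - model.rho) * model.acc_hom


def variant_sensitivity(truth_counts: list[int], called_counts: list[int]) -> float:
    """Pooled sensitivity: sum(called) / sum(truth) over validation sets."""
    if len(truth_counts) != len(called_counts):
        raise ValueError("count lists must have equal length")
    for t, c in zip(truth_counts, called_counts):
        if c > t:
            raise ValueError(f"called count {c} exceeds truth count {t}")
        if t < 0 or c < 0:
            raise ValueError("counts must be non-negative")
    total = sum(truth_counts)
    if total == 0:
        return float("nan")
    return sum(called_counts) / total


def group_shares(group_counts: dict[str, int], total: int) -> dict[str, float]:
    """Percent of total per group, 2 dp; groups may overlap so shares need
    not sum to 100."""
    if total <= 0:
        raise ValueError("total must be positive")
    return {k: round(100.0 * v / total, 2) for k, v in group_counts.items()}
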