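"""Pipeline orchestration: config, stage sequencing, and report emission.

Runs the full analysis on one cohort: variant summary -> windowed
diversity statistics -> neutral ranges -> per-subgroup selection scan ->
set-logic combination with ROD/Fst corroboration and gene mapping -> LD
decay per role -> per-accession heterozygosity profile. Every stage writes
a TSV/BED artifact into the output directory; a MANIFEST records completed
stages and a plain-text log records the counters behind every reported
number. Identical inputs and config produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import cohort_io, diversity, neutrality, selection
from .cohort_io import GenomeAnnotation, read_cohort, summarize_variants, iter_windows

log = logging.getLogger("peachpop")

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    vcf: str
    groups: str
    fasta: str
    gff3: str
    out_dir: str
    truth_bed: str | None = None

    window_size: int = 10_000
    step: int | None = None  # None -> disjoint tiling (step = window)
    min_called_fraction: float = 0.5
    maf_min: float = 0.0
    s_min: int = diversity.DEFAULT_S_MIN

    ci_level: float = 0.95
    ci_sample_size: str = "accessions"  # or "haplotypes"

    edible_subgroups: tuple[str, ...] = ("C", "D", "E", "F")
    ornamental_subgroup: str = "A"
    ignore_subgroups: tuple[str, ...] = ("B",)

    ld_max_dist: int = 1_000_000
    ld_bin_width: int = 1_000
    ld_maf_min: float = 0.1
    ld_max_sites_per_contig: int = 1_500

    seed: int = 0

    def validate(self) -> None:
        for name in ("vcf", "groups", "fasta", "gff3"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"config {name}: no such file {p}")
        if self.truth_bed and not Path(self.truth_bed).exists():
            raise FileNotFoundError(f"config truth_bed: no such file {self.truth_bed}")
        if self.ci_sample_size not in ("accessions", "haplotypes"):
            raise ValueError("ci_sample_size must be 'accessions' or 'haplotypes'")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("edible_subgroups", "ignore_subgroups"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        for key in ("edible_subgroups", "ignore_subgroups"):
            d[key] = list(d[key])
        return yaml.safe_dump(d, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def _read_truth_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        out.append((parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else ""))
    return out


def _interval_overlap(a: tuple[str, int, int], b: tuple[str, int, int]) -> bool:
    return a[0] == b[0] and a[1] < b[2] and b[1] < a[2]


def sweep_recovery(
    regions: list[tuple[str, int, int]], truth: list[tuple[str, int, int]]
) -> dict[str, float]:
    """Recall/precision of labeled regions against truth intervals by
    >= 1 bp overlap."""
    if not truth:
        return {"recall": float("nan"), "precision": float("nan")}
    hit_truth = sum(any(_interval_overlap(t, r) for r in regions) for t in truth)
    recall = hit_truth / len(truth)
    if not regions:
        return {"recall": recall, "precision": float("nan")}
    hit_reg = sum(any(_interval_overlap(r, t) for t in truth) for r in regions)
    return {"recall": recall, "precision": hit_reg / len(regions)}


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages; returns paths of emitted artifacts.

    Any stage failure aborts with the stage name in the exception; the
    MANIFEST lists the stages that completed.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())

    manifest: list[str] = []
    artifacts: dict[str, Path] = {"config": out / "config.yaml"}
    counters: list[str] = []
    stage = "load"
    try:
        matrix, groups = read_cohort(config.vcf, config.groups)
        counters.append(f"load: {matrix.n_samples} samples, {matrix.n_sites} SNP sites")
        annotation = GenomeAnnotation.from_files(config.fasta, config.gff3)
        counters.append(f"load: {len(annotation.genes)} genes")
        matrix = cohort_io.filter_population_snps(
            matrix, config.min_called_fraction, config.maf_min
        )
        counters.append(f"filter: {matrix.n_sites} sites pass call-rate/MAF")
        manifest.append(stage)

        stage = "summarize"
        summary = summarize_variants(matrix, groups, annotation)
        artifacts["summary"] = out / "variant_summary.tsv"
        _write_tsv(summary.table, artifacts["summary"])
        manifest.append(stage)

        stage = "stats"
        windows = iter_windows(
            annotation.contig_lengths(), config.window_size, config.step
        )
        stats = diversity.window_stats(matrix, groups, windows, s_min=config.s_min)
        artifacts["window_stats"] = out / "window_stats.tsv"
        _write_tsv(stats, artifacts["window_stats"])
        counters.append(f"stats: {len(windows)} windows x {len(groups.subgroups)} subgroups")
        manifest.append(stage)

        stage = "neutral-range"
        ranges: dict[str, neutrality.NeutralRange] = {}
        nr_rows = []
        for name in groups.subgroups:
            n_acc = len(groups.samples_of(name))
            n_ci = n_acc if config.ci_sample_size == "accessions" else 2 * n_acc
            nr = neutrality.d_confidence_limits(n_ci, config.ci_level)
            ranges[name] = nr
            nr_rows.append(
                {
                    "subgroup": name,
                    "n": nr.n,
                    "level": nr.level,
                    "d_min": nr.d_min,
                    "d_max": nr.d_max,
                    "lower": nr.lower,
                    "upper": nr.upper,
                }
            )
        artifacts["neutral_ranges"] = out / "neutral_ranges.tsv"
        _write_tsv(pd.DataFrame(nr_rows), artifacts["neutral_ranges"])
        manifest.append(stage)

        stage = "scan"
        candidates: dict[str, set[selection.Window]] = {}
        cand_tables = []
        for name in groups.subgroups:
            sub_stats = stats[stats["subgroup"] == name]
            cand = selection.scan_subgroup(sub_stats, ranges[name])
            cand_tables.append(cand)
            candidates[name] = {
                (r.contig, int(r.start), int(r.end)) for r in cand.itertuples()
            }
            counters.append(f"scan: subgroup {name}: {len(cand)} candidate windows")
        artifacts["candidates"] = out / "candidate_windows.tsv"
        non_empty = [t for t in cand_tables if not t.empty]
        _write_tsv(
            pd.concat(non_empty, ignore_index=True) if non_empty else cand_tables[0],
            artifacts["candidates"],
        )

        rules = selection.CombineRules(
            config.edible_subgroups, config.ornamental_subgroup, config.ignore_subgroups
        )
        edible, ornamental = selection.combine_subgroups(candidates, rules)
        wild_samples = groups.samples_by_role("wild")
        cul_samples = groups.cultivated_samples()
        region_rows = []
        bed_lines = []
        for regset in (edible, ornamental):
            regset.genes = selection.map_genes(regset.regions, annotation)
            div = (
                selection.divergence_table(
                    matrix, regset.regions, cul_samples, wild_samples
                )
                if regset.regions and wild_samples and cul_samples
                else None
            )
            for k, (contig, start, end) in enumerate(regset.regions):
                row = {
                    "label": regset.label,
                    "contig": contig,
                    "start": start,
                    "end": end,
                    "n_windows": sum(
                        1 for w in regset.windows if _interval_overlap(w, (contig, start, end))
                    ),
                    "genes": ",".join(regset.genes[(contig, start, end)]),
                }
                if div is not None:
                    row["ROD"] = div.iloc[k]["ROD"]
                    row["Fst"] = div.iloc[k]["Fst"]
                region_rows.append(row)
                bed_lines.append(f"{contig}\t{start}\t{end}\t{regset.label}")
            counters.append(f"scan: {regset.label}: {len(regset.regions)} regions")
        artifacts["regions"] = out / "selected_regions.tsv"
        _write_tsv(
            pd.DataFrame(
                region_rows,
                columns=["label", "contig", "start", "end", "n_windows", "ROD", "Fst", "genes"],
            ),
            artifacts["regions"],
        )
        artifacts["regions_bed"] = out / "selected_regions.bed"
        artifacts["regions_bed"].write_text(
            "\n".join(bed_lines) + ("\n" if bed_lines else "")
        )
        manifest.append(stage)

        stage = "divergence"
        div_all = selection.divergence_table(matrix, windows, cul_samples, wild_samples) \
            if wild_samples and cul_samples else pd.DataFrame()
        artifacts["divergence"] = out / "divergence.tsv"
        _write_tsv(div_all, artifacts["divergence"])
        manifest.append(stage)

        stage = "ld"
        ld_rows = []
        for role in ("wild", "ornamental", "edible"):
            samples = groups.samples_by_role(role)
            if len(samples) < 2:
                continue
            curve = diversity.ld_decay(
                matrix,
                samples,
                max_dist=config.ld_max_dist,
                bin_width=config.ld_bin_width,
                maf_min=config.ld_maf_min,
                max_sites_per_contig=config.ld_max_sites_per_contig,
            )
            tbl = curve.table.copy()
            tbl.insert(0, "role", role)
            ld_rows.append(tbl)
            counters.append(
                f"ld: role {role}: max_r2={curve.max_r2:.4g} half_decay_bp={curve.half_decay_bp:.6g}"
            )
        artifacts["ld_decay"] = out / "ld_decay.tsv"
        _write_tsv(
            pd.concat(ld_rows, ignore_index=True) if ld_rows else pd.DataFrame(),
            artifacts["ld_decay"],
        )
        manifest.append(stage)

        stage = "het"
        profile = diversity.het_profile(matrix, groups)
        artifacts["het_profile"] = out / "het_profile.tsv"
        _write_tsv(profile, artifacts["het_profile"])
        manifest.append(stage)

        if config.truth_bed:
            stage = "truth"
            truth = [
                (c, s, e) for c, s, e, _ in _read_truth_bed(config.truth_bed)
            ]
            rec = sweep_recovery(edible.regions + ornamental.regions, truth)
            artifacts["recovery"] = out / "sweep_recovery.tsv"
            _write_tsv(
                pd.DataFrame([{"n_truth": len(truth), **rec}]), artifacts["recovery"]
            )
            manifest.append(stage)

        stage = "report"
        artifacts["log"] = out / "pipeline_log.txt"
        artifacts["log"].write_text("\n".join(counters) + "\n")
        manifest.append(stage)
    except Exception as exc:
        (out / "MANIFEST").write_text("\n".join(manifest) + "\n")
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    artifacts["manifest"] = out / "MANIFEST"
    artifacts["manifest"].write_text("\n".join(manifest) + "\n")
    return artifacts
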