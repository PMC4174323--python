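"""Synthetic diploid cohort generator.

Builds a complete toy resequencing cohort — reference FASTA, GFF3 gene
models, biallelic-SNP VCF, sample-group table and a truth BED of injected
selective sweeps — with the statistical structure a domestication selection
scan assumes:

* neutral windows whose site counts and site-frequency spectra follow the
  standard neutral expectation (P(derived count = i) proportional to 1/i),
  so windowed Tajima's D centres near zero;
* sweep windows, confined to chosen subgroups, with segregating sites
  thinned by a configurable diversity-reduction factor and frequencies
  drawn from a skewed spectrum (low-frequency excess for a completed sweep,
  intermediate-frequency excess for balancing-like signals);
* an inbreeding coefficient F per subgroup that depresses each accession's
  heterozygous-call fraction by the classic (1 - F) factor, emulating the
  collapse of heterozygosity under selfing and clonal propagation;
* a toy annotated genome (genes with UTR/exon/intron structure on both
  strands) so site classification and synonymous/nonsynonymous calls are
  exercised end to end.

Sites are simulated independently (no linkage) unless ``ld_block_bp`` is
set, in which case all sites falling in the same block of that length share
one haplotype partition, producing non-trivial r² for LD-decay tests.

Everything is driven by a single :class:`numpy.random.Generator`; identical
spec + seed yields byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

MISSING = -1

_BASES = np.array(list("ACGT"))

ROLES = ("wild", "ornamental", "edible")
SWEEP_MODES = ("low_freq_excess", "intermediate_excess")


@dataclass(frozen=True)
class SubgroupSpec:
    """One subgroup of diploid accessions.

    theta_per_site is the scaled mutation rate per bp (expected pairwise
    diversity per site under neutrality); inbreeding_F in [0, 1] is the
    probability that an accession's two alleles at a site are identical by
    descent.
    """

    name: str
    role: str
    n_accessions: int
    theta_per_site: float = 1.3e-3
    inbreeding_F: float = 0.0

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.n_accessions < 2:
            raise ValueError("n_accessions must be >= 2")
        if not 0.0 <= self.inbreeding_F <= 1.0:
            raise ValueError("inbreeding_F must lie in [0, 1]")
        if self.theta_per_site < 0:
            raise ValueError("theta_per_site must be >= 0")


@dataclass(frozen=True)
class SweepSpec:
    """A sweep injected into one window of one contig for given subgroups."""

    contig: str
    window_index: int
    subgroups: tuple[str, ...]
    mode: str = "low_freq_excess"
    diversity_reduction: float = 0.2

    def __post_init__(self) -> None:
        if self.mode not in SWEEP_MODES:
            raise ValueError(f"unknown sweep mode {self.mode!r}")
        if not 0.0 < self.diversity_reduction <= 1.0:
            raise ValueError("diversity_reduction must lie in (0, 1]")


@dataclass
class CohortSpec:
    contigs: list[tuple[str, int]]
    subgroups: list[SubgroupSpec]
    window_size: int = 10_000
    sweeps: list[SweepSpec] = field(default_factory=list)
    ld_block_bp: int | None = None
    missing_rate: float = 0.0
    genes_per_contig: int = 20
    seed: int = 0

    def validate(self) -> None:
        names = [s.name for s in self.subgroups]
        if len(set(names)) != len(names):
            raise ValueError("subgroup names must be unique")
        if self.window_size <= 0:
            raise ValueError("window_size must be positive")
        lengths = dict(self.contigs)
        for name, length in self.contigs:
            if length < self.window_size:
                raise ValueError(
                    f"contig {name} ({length} bp) shorter than one window"
                )
        seen: set[tuple[str, int]] = set()
        for sw in self.sweeps:
            if sw.contig not in lengths:
                raise ValueError(f"sweep on unknown contig {sw.contig}")
            start = sw.window_index * self.window_size
            if start < 0 or start + self.window_size > lengths[sw.contig]:
                raise ValueError(
                    f"sweep window {sw.window_index} outside contig {sw.contig}"
                )
            key = (sw.contig, sw.window_index)
            if key in seen:
                raise ValueError(
                    f"overlapping sweep windows on {sw.contig} (window {sw.window_index})"
                )
            seen.add(key)
            for g in sw.subgroups:
                if g not in names:
                    raise ValueError(f"sweep names unknown subgroup {g}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")

    def sample_ids(self) -> list[str]:
        ids = []
        for sg in self.subgroups:
            ids.extend(f"{sg.name}_{k+1:02d}" for k in range(sg.n_accessions))
        return ids


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The default study design: one wild group plus the six cultivated
    subgroups (one ornamental, five edible) at their published sample sizes,
    with wild diversity roughly twice cultivated diversity (genome-wide
    theta_w ~ 2.6e-3 in the wild) and strong inbreeding in cultivars."""
    subgroups = [
        SubgroupSpec("W", "wild", 10, theta_per_site=2.6e-3, inbreeding_F=0.50),
        SubgroupSpec("A", "ornamental", 8, theta_per_site=1.3e-3, inbreeding_F=0.65),
        SubgroupSpec("B", "edible", 6, theta_per_site=1.3e-3, inbreeding_F=0.65),
        SubgroupSpec("C", "edible", 8, theta_per_site=1.3e-3, inbreeding_F=0.65),
        SubgroupSpec("D", "edible", 7, theta_per_site=1.3e-3, inbreeding_F=0.65),
        SubgroupSpec("E", "edible", 9, theta_per_site=1.3e-3, inbreeding_F=0.65),
        SubgroupSpec("F", "edible", 9, theta_per_site=1.3e-3, inbreeding_F=0.65),
    ]
    spec = CohortSpec(
        contigs=[("chr1", 200_000), ("chr2", 200_000)],
        subgroups=subgroups,
        window_size=10_000,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    return spec


# ---------------------------------------------------------------------------
# site-frequency machinery


def _sfs_weights(n_hap: int, mode: str) -> np.ndarray:
    i = np.arange(1, n_hap)
    if mode == "neutral":
        w = 1.0 / i
    elif mode == "low_freq_excess":
        # steeper-than-neutral decay: stochastically smaller than 1/i
        w = 1.0 / i**3
    elif mode == "intermediate_excess":
        # mass tightly concentrated near n/2 (balancing-like signature)
        w = np.exp(-0.5 * ((i - n_hap / 2.0) / max(n_hap / 16.0, 0.75)) ** 2)
    else:
        raise ValueError(f"unknown SFS mode {mode!r}")
    return w / w.sum()


def site_frequency_sample(n_hap: int, mode: str, rng: np.random.Generator) -> int:
    """Draw a derived-allele count in [1, n_hap - 1] from the given spectrum."""
    if n_hap < 2:
        raise ValueError("n_hap must be >= 2")
    if n_hap == 2:
        _sfs_weights(3, mode)  # still validate the mode name
        return 1
    return int(rng.choice(np.arange(1, n_hap), p=_sfs_weights(n_hap, mode)))


def expected_segregating_sites(theta: float, n_hap: int, length: int) -> float:
    """E[S] = theta * a1(n_hap) * L for a neutral window."""
    a1 = float(np.sum(1.0 / np.arange(1, n_hap)))
    return theta * a1 * length


def simulate_window_codes(
    n_accessions: int,
    theta: float,
    length: int,
    rng: np.random.Generator,
    mode: str = "neutral",
    inbreeding_F: float = 0.0,
    diversity_reduction: float = 1.0,
    missing_rate: float = 0.0,
) -> np.ndarray:
    """Simulate one subgroup-window as a dosage matrix (accessions x sites).

    Codes: 0 hom-ref, 1 het, 2 hom-alt, -1 missing. The number of sites is
    Poisson with mean theta * a1 * L * diversity_reduction; each site gets a
    derived count from the requested spectrum, assigned to a uniformly
    random haplotype subset, then collapsed to diploid genotypes with an
    inbreeding mixture (probability F of identical-by-descent pairing).
    """
    n_hap = 2 * n_accessions
    mean_s = expected_segregating_sites(theta, n_hap, length) * diversity_reduction
    n_sites = int(rng.poisson(mean_s))
    codes = np.zeros((n_accessions, n_sites), dtype=np.int8)
    for j in range(n_sites):
        codes[:, j] = _simulate_site(n_accessions, mode, inbreeding_F, rng)
    if missing_rate > 0 and n_sites:
        mask = rng.random(codes.shape) < missing_rate
        codes[mask] = MISSING
    return codes


def _haplotype_site(n_hap: int, mode: str, rng: np.random.Generator) -> np.ndarray:
    i = site_frequency_sample(n_hap, mode, rng)
    h = np.zeros(n_hap, dtype=np.int8)
    h[rng.choice(n_hap, size=i, replace=False)] = 1
    return h


def _collapse_diploid(
    h: np.ndarray, inbreeding_F: float, rng: np.random.Generator
) -> np.ndarray:
    n_acc = h.size // 2
    g = h[0::2] + h[1::2]
    if inbreeding_F > 0:
        ibd = rng.random(n_acc) < inbreeding_F
        pick = rng.integers(0, 2, size=n_acc)
        forced = 2 * h[2 * np.arange(n_acc) + pick]
        g = np.where(ibd, forced, g)
    return g.astype(np.int8)


def _simulate_site(
    n_accessions: int, mode: str, inbreeding_F: float, rng: np.random.Generator
) -> np.ndarray:
    h = _haplotype_site(2 * n_accessions, mode, rng)
    return _collapse_diploid(h, inbreeding_F, rng)


# ---------------------------------------------------------------------------
# toy annotated genome


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


@dataclass
class _ToyTranscript:
    tid: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]          # genomic, 0-based half-open, sorted
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]


def _segments_from_tx_interval(
    exons: list[tuple[int, int]], strand: str, lo: int, hi: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate interval [lo, hi) onto genomic segments.

    Transcript coordinate 0 is the 5' end of the mRNA, i.e. the leftmost
    exon base for '+' and the rightmost for '-'.
    """
    order = exons if strand == "+" else exons[::-1]
    out: list[tuple[int, int]] = []
    off = 0
    for s, e in order:
        ln = e - s
        a, b = max(lo, off), min(hi, off + ln)
        if a < b:
            if strand == "+":
                out.append((s + (a - off), s + (b - off)))
            else:
                out.append((e - (b - off), e - (a - off)))
        off += ln
    return sorted(out)


def _build_genes(
    rng: np.random.Generator, contig: str, length: int, n_genes: int, gene_prefix: str
) -> list[_ToyTranscript]:
    """Lay out non-overlapping genes with 2-4 exons, UTRs and in-frame CDS."""
    transcripts: list[_ToyTranscript] = []
    cursor = 500
    made = 0
    while made < n_genes:
        n_ex = int(rng.integers(2, 5))
        ex_lens = rng.integers(150, 600, size=n_ex)
        introns = rng.integers(100, 500, size=n_ex - 1)
        span = int(ex_lens.sum() + introns.sum())
        gap = int(rng.integers(300, 1500))
        start = cursor + gap
        if start + span + 500 > length:
            break
        exons = []
        pos = start
        for k in range(n_ex):
            exons.append((pos, pos + int(ex_lens[k])))
            pos = exons[-1][1] + (int(introns[k]) if k < n_ex - 1 else 0)
        strand = "+" if rng.random() < 0.5 else "-"
        tx_len = int(ex_lens.sum())
        u5 = int(rng.integers(50, 180))
        u3 = int(rng.integers(50, 180))
        cds_len = tx_len - u5 - u3
        cds_len -= cds_len % 3
        if cds_len < 90:
            cursor = start + span
            continue
        u3 = tx_len - u5 - cds_len
        gid = f"{gene_prefix}{made + 1:04d}"
        transcripts.append(
            _ToyTranscript(
                tid=f"{gid}.t1",
                gene_id=gid,
                contig=contig,
                strand=strand,
                exons=exons,
                cds=_segments_from_tx_interval(exons, strand, u5, u5 + cds_len),
                utr5=_segments_from_tx_interval(exons, strand, 0, u5),
                utr3=_segments_from_tx_interval(exons, strand, u5 + cds_len, tx_len),
            )
        )
        made += 1
        cursor = start + span
    return transcripts


def _gff3_lines(transcripts: list[_ToyTranscript]) -> list[str]:
    lines = ["##gff-version 3"]
    for tx in transcripts:
        g_start = min(s for s, _ in tx.exons) + 1
        g_end = max(e for _, e in tx.exons)
        lines.append(
            f"{tx.contig}\tpeachpop\tgene\t{g_start}\t{g_end}\t.\t{tx.strand}\t.\t"
            f"ID={tx.gene_id}"
        )
        lines.append(
            f"{tx.contig}\tpeachpop\tmRNA\t{g_start}\t{g_end}\t.\t{tx.strand}\t.\t"
            f"ID={tx.tid};Parent={tx.gene_id}"
        )
        for k, (s, e) in enumerate(tx.exons, 1):
            lines.append(
                f"{tx.contig}\tpeachpop\texon\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                f"ID={tx.tid}.exon{k};Parent={tx.tid}"
            )
        # phase: bases to skip at the segment's 5' end, accumulated in
        # transcript order
        cds_order = tx.cds if tx.strand == "+" else tx.cds[::-1]
        done = 0
        phased = {}
        for s, e in cds_order:
            phased[(s, e)] = (3 - done % 3) % 3
            done += e - s
        for k, (s, e) in enumerate(tx.cds, 1):
            lines.append(
                f"{tx.contig}\tpeachpop\tCDS\t{s + 1}\t{e}\t.\t{tx.strand}\t"
                f"{phased[(s, e)]}\tID={tx.tid}.cds{k};Parent={tx.tid}"
            )
        for label, segs in (("five_prime_UTR", tx.utr5), ("three_prime_UTR", tx.utr3)):
            for k, (s, e) in enumerate(segs, 1):
                lines.append(
                    f"{tx.contig}\tpeachpop\t{label}\t{s + 1}\t{e}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.tid}.{label}{k};Parent={tx.tid}"
                )
    return lines


# ---------------------------------------------------------------------------
# cohort simulation


def simulate_cohort(spec: CohortSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic cohort; returns paths keyed by kind.

    Keys: fasta, gff3, vcf, groups, truth.
    """
    spec.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    sequences = {name: _random_sequence(rng, length) for name, length in spec.contigs}

    transcripts: list[_ToyTranscript] = []
    for idx, (name, length) in enumerate(spec.contigs):
        transcripts.extend(
            _build_genes(rng, name, length, spec.genes_per_contig, f"pg{idx + 1}g")
        )

    sweep_by_window = {(sw.contig, sw.window_index): sw for sw in spec.sweeps}
    sample_ids = spec.sample_ids()

    records: list[tuple[str, int, str, str, np.ndarray]] = []
    contig_order = {name: k for k, (name, _) in enumerate(spec.contigs)}
    for name, length in spec.contigs:
        used: set[int] = set()
        n_windows = length // spec.window_size
        for w in range(n_windows):
            w_start = w * spec.window_size
            sweep = sweep_by_window.get((name, w))
            col = 0
            for sg in spec.subgroups:
                affected = sweep is not None and sg.name in sweep.subgroups
                mode = sweep.mode if affected else "neutral"
                reduction = sweep.diversity_reduction if affected else 1.0
                if spec.ld_block_bp:
                    mean_s = (
                        expected_segregating_sites(
                            sg.theta_per_site, 2 * sg.n_accessions, spec.window_size
                        )
                        * reduction
                    )
                    codes = _blockify(int(rng.poisson(mean_s)), sg, mode, spec, rng)
                    if spec.missing_rate > 0 and codes.size:
                        codes[rng.random(codes.shape) < spec.missing_rate] = MISSING
                else:
                    codes = simulate_window_codes(
                        sg.n_accessions,
                        sg.theta_per_site,
                        spec.window_size,
                        rng,
                        mode=mode,
                        inbreeding_F=sg.inbreeding_F,
                        diversity_reduction=reduction,
                        missing_rate=spec.missing_rate,
                    )
                n_sites = codes.shape[1]
                free = np.array(
                    sorted(set(range(w_start, w_start + spec.window_size)) - used)
                )
                if n_sites > free.size:
                    n_sites = free.size
                    codes = codes[:, :n_sites]
                pos = rng.choice(free, size=n_sites, replace=False)
                if spec.ld_block_bp:
                    pos = np.sort(pos)  # blocks must be contiguous in position
                used.update(int(p) for p in pos)
                for j in range(n_sites):
                    if not np.any(codes[:, j] > 0):
                        # inbreeding collapse can erase every derived copy;
                        # an all-reference column is not a SNP record
                        continue
                    p = int(pos[j])
                    ref = str(sequences[name][p])
                    alt = str(rng.choice(_BASES[_BASES != ref]))
                    gvec = np.zeros(len(sample_ids), dtype=np.int8)
                    gvec[col : col + sg.n_accessions] = codes[:, j]
                    records.append((name, p, ref, alt, gvec))
                col += sg.n_accessions

    records.sort(key=lambda r: (contig_order[r[0]], r[1]))

    paths = {
        "fasta": out / "reference.fa",
        "gff3": out / "genes.gff3",
        "vcf": out / "cohort.vcf",
        "groups": out / "groups.tsv",
        "truth": out / "truth.bed",
    }
    _write_fasta(paths["fasta"], spec, sequences)
    paths["gff3"].write_text("\n".join(_gff3_lines(transcripts)) + "\n")
    _write_vcf(paths["vcf"], spec, sample_ids, records)
    with open(paths["groups"], "w") as fh:
        fh.write("sample_id\tsubgroup\trole\n")
        for sg in spec.subgroups:
            for k in range(sg.n_accessions):
                fh.write(f"{sg.name}_{k+1:02d}\t{sg.name}\t{sg.role}\n")
    with open(paths["truth"], "w") as fh:
        for sw in sorted(
            spec.sweeps, key=lambda s: (contig_order[s.contig], s.window_index)
        ):
            s0 = sw.window_index * spec.window_size
            fh.write(
                f"{sw.contig}\t{s0}\t{s0 + spec.window_size}\t"
                f"{','.join(sw.subgroups)}|{sw.mode}\n"
            )
    return paths


def _blockify(
    n_sites: int, sg: SubgroupSpec, mode: str, spec: CohortSpec, rng: np.random.Generator
) -> np.ndarray:
    """Re-simulate a window's sites sharing haplotype partitions per LD block.

    Sites are later laid out sorted within the window, so consecutive sites
    fall in consecutive blocks: sites/block = block_bp / window_bp * n_sites.
    """
    n_hap = 2 * sg.n_accessions
    per_block = max(1, round(n_sites * spec.ld_block_bp / spec.window_size))
    codes = np.empty((sg.n_accessions, n_sites), dtype=np.int8)
    j = 0
    while j < n_sites:
        h = _haplotype_site(n_hap, mode, rng)
        for _ in range(per_block):
            if j >= n_sites:
                break
            codes[:, j] = _collapse_diploid(h, sg.inbreeding_F, rng)
            j += 1
    return codes


def _write_fasta(path: Path, spec: CohortSpec, sequences: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for name, _ in spec.contigs:
            fh.write(f">{name}\n")
            seq = "".join(sequences[name])
            for k in range(0, len(seq), 70):
                fh.write(seq[k : k + 70] + "\n")


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(path, spec, sample_ids, records) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=peachpop-simulate\n")
        for name, length in spec.contigs:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for name, pos0, ref, alt, gvec in records:
            gts = "\t".join(_GT[int(g)] for g in gvec)
            fh.write(f"{name}\t{pos0 + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
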