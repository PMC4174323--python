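"""Cohort ingestion, SNP filtering, and functional site classification.

Reads a diploid VCF plus a sample-group table into a dosage-coded genotype
matrix (0 hom-ref / 1 het / 2 hom-alt / -1 missing), loads the reference
genome and GFF3 gene models, classifies each SNP by genomic context
(CDS > 5' UTR > 3' UTR > intronic > intergenic) and, inside coding
sequence, by codon effect (synonymous vs nonsynonymous), and produces the
per-group summary table a resequencing study reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from cyvcf2 import VCF
from intervaltree import IntervalTree

MISSING = -1

SITE_CLASSES = ("intergenic", "UTR5", "UTR3", "intronic", "CDS")
_CLASS_PRIORITY = {"CDS": 4, "UTR5": 3, "UTR3": 2, "intronic": 1, "intergenic": 0}

log = logging.getLogger("peachpop")


@dataclass
class GenotypeMatrix:
    """Accessions x biallelic SNP sites, dosage-coded.

    ``sites`` is a DataFrame with columns contig, pos (1-based, VCF
    convention), ref, alt; ``codes`` has shape (n_samples, n_sites).
    """

    sample_ids: list[str]
    sites: pd.DataFrame
    codes: np.ndarray

    def __post_init__(self) -> None:
        if self.codes.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("codes shape inconsistent with samples/sites")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: k for k, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in sample_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from exc

    def take_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.sample_ids,
            self.sites.loc[np.asarray(mask)].reset_index(drop=True),
            self.codes[:, np.asarray(mask)],
        )

    def window_mask(self, contig: str, start: int, end: int) -> np.ndarray:
        """Sites with 0-based position in [start, end)."""
        pos0 = self.sites["pos"].to_numpy() - 1
        return (self.sites["contig"].to_numpy() == contig) & (pos0 >= start) & (pos0 < end)


@dataclass
class SampleGroups:
    """sample_id -> (subgroup, role) assignments with derived group views."""

    table: pd.DataFrame  # columns: sample_id, subgroup, role

    def __post_init__(self) -> None:
        required = {"sample_id", "subgroup", "role"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"groups table needs columns {sorted(required)}")
        if self.table["sample_id"].duplicated().any():
            dup = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise ValueError(f"duplicate sample assignment: {dup.iloc[0]}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SampleGroups":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @property
    def subgroups(self) -> list[str]:
        return sorted(self.table["subgroup"].unique())

    def samples_of(self, subgroup: str) -> list[str]:
        sel = self.table.loc[self.table["subgroup"] == subgroup, "sample_id"]
        if sel.empty:
            raise KeyError(f"no samples in subgroup {subgroup!r}")
        return list(sel)

    def samples_by_role(self, role: str) -> list[str]:
        return list(self.table.loc[self.table["role"] == role, "sample_id"])

    def cultivated_samples(self) -> list[str]:
        return list(
            self.table.loc[self.table["role"].isin(["ornamental", "edible"]), "sample_id"]
        )

    def role_of(self, subgroup: str) -> str:
        return self.table.loc[self.table["subgroup"] == subgroup, "role"].iloc[0]


# ---------------------------------------------------------------------------
# VCF ingestion


_DIPLOID_CODE = {(0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}


def read_cohort(
    vcf_path: str | Path, groups_path: str | Path
) -> tuple[GenotypeMatrix, SampleGroups]:
    """Load a VCF and its sample-group table.

    Non-SNP and multiallelic records are dropped (counted in the log);
    genotypes map 0/0 -> 0, 0/1 or 1/0 -> 1, 1/1 -> 2, missing -> -1.
    """
    groups = SampleGroups.from_tsv(groups_path)
    vcf = VCF(str(vcf_path))
    known = set(groups.table["sample_id"])
    for s in vcf.samples:
        if s not in known:
            raise ValueError(f"VCF sample {s!r} absent from groups table")

    rows, code_cols = [], []
    dropped = 0
    for var in vcf:
        if len(var.REF) != 1 or len(var.ALT) != 1 or len(var.ALT[0]) != 1:
            dropped += 1
            continue
        if var.ALT[0] not in "ACGT" or var.REF not in "ACGT":
            dropped += 1
            continue
        col = np.empty(len(vcf.samples), dtype=np.int8)
        for k, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            col[k] = MISSING if (a < 0 or b < 0) else _DIPLOID_CODE[(a, b)]
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        code_cols.append(col)
    log.info("read_cohort: kept %d SNP records, dropped %d", len(rows), dropped)
    if not rows:
        raise ValueError("no usable biallelic SNP records in VCF")
    sites = pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])
    codes = np.stack(code_cols, axis=1)
    return GenotypeMatrix(list(vcf.samples), sites, codes), groups


def filter_population_snps(
    matrix: GenotypeMatrix, min_called_fraction: float = 0.5, maf_min: float = 0.0
) -> GenotypeMatrix:
    """Site filters standing in for raw-read depth/mapping QC: a minimum
    called-genotype fraction and a minimum minor-allele frequency among
    called genotypes. Site order is preserved."""
    if not 0 <= min_called_fraction <= 1 or not 0 <= maf_min < 0.5:
        raise ValueError("invalid filter thresholds")
    called = matrix.codes != MISSING
    n_called = called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = np.where(called, matrix.codes, 0).sum(axis=0)
        p = np.where(n_called > 0, alt / (2 * n_called), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = (n_called / matrix.n_samples >= min_called_fraction) & (
        np.nan_to_num(maf, nan=-1.0) >= maf_min
    )
    log.info("filter_population_snps: kept %d of %d sites", int(keep.sum()), keep.size)
    return matrix.take_sites(keep)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class Transcript:
    tid: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]  # 0-based half-open, sorted by start
    cds: list[tuple[int, int]]
    utr5: list[tuple[int, int]]
    utr3: list[tuple[int, int]]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class Gene:
    gene_id: str
    contig: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)

    def representative_transcript(self) -> Transcript:
        """Longest transcript; ties broken by lexicographically smallest id."""
        return min(self.transcripts, key=lambda t: (-t.length, t.tid))


class GenomeAnnotation:
    """Reference sequences plus gene models, with fast interval lookup."""

    def __init__(self, sequences: dict[str, str], genes: list[Gene]):
        self.sequences = sequences
        self.genes = {g.gene_id: g for g in genes}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            self._trees.setdefault(g.contig, IntervalTree())[g.start : g.end] = g.gene_id

    @classmethod
    def from_files(cls, fasta_path: str | Path, gff3_path: str | Path) -> "GenomeAnnotation":
        sequences = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
        }
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
        genes: list[Gene] = []
        for gf in db.features_of_type("gene"):
            gene = Gene(gf.id, gf.seqid, gf.start - 1, gf.end)
            for mf in db.children(gf, featuretype="mRNA"):
                def segs(ftype: str) -> list[tuple[int, int]]:
                    return sorted(
                        (c.start - 1, c.end)
                        for c in db.children(mf, featuretype=ftype)
                    )

                gene.transcripts.append(
                    Transcript(
                        tid=mf.id,
                        gene_id=gf.id,
                        contig=gf.seqid,
                        strand=mf.strand,
                        exons=segs("exon"),
                        cds=segs("CDS"),
                        utr5=segs("five_prime_UTR"),
                        utr3=segs("three_prime_UTR"),
                    )
                )
            if gene.transcripts:
                genes.append(gene)
        return cls(sequences, genes)

    def contig_lengths(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    def genes_overlapping(self, contig: str, start: int, end: int) -> list[Gene]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        return sorted(
            (self.genes[iv.data] for iv in tree.overlap(start, end)),
            key=lambda g: (g.start, g.gene_id),
        )


def _in_any(pos0: int, segments: list[tuple[int, int]]) -> bool:
    return any(s <= pos0 < e for s, e in segments)


def _classify_in_transcript(pos0: int, tx: Transcript) -> str:
    if _in_any(pos0, tx.cds):
        return "CDS"
    if _in_any(pos0, tx.utr5):
        return "UTR5"
    if _in_any(pos0, tx.utr3):
        return "UTR3"
    return "intronic"


def classify_site(contig: str, pos: int, annotation: GenomeAnnotation) -> str:
    """Assign a 1-based SNP position to exactly one genomic context.

    Each overlapping gene is represented by its longest transcript; across
    genes the highest-priority class wins (CDS > UTR5 > UTR3 > intronic).
    """
    if contig not in annotation.sequences:
        raise KeyError(f"contig {contig!r} not in annotation")
    pos0 = pos - 1
    genes = annotation.genes_overlapping(contig, pos0, pos0 + 1)
    if not genes:
        return "intergenic"
    best = "intronic"
    for g in genes:
        cls = _classify_in_transcript(pos0, g.representative_transcript())
        if _CLASS_PRIORITY[cls] > _CLASS_PRIORITY[best]:
            best = cls
    return best


def _cds_local_position(pos0: int, tx: Transcript) -> int:
    """0-based offset of pos0 within the concatenated CDS, 5'->3'."""
    order = tx.cds if tx.strand == "+" else tx.cds[::-1]
    off = 0
    for s, e in order:
        if s <= pos0 < e:
            return off + (pos0 - s if tx.strand == "+" else e - 1 - pos0)
        off += e - s
    raise ValueError("position not in CDS")


def cds_sequence(tx: Transcript, annotation: GenomeAnnotation) -> str:
    """Spliced coding sequence in translation orientation."""
    seq = annotation.sequences[tx.contig]
    parts = [seq[s:e] for s, e in tx.cds]
    cds = "".join(parts)
    if tx.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return cds


def classify_cds_effect(
    contig: str, pos: int, ref: str, alt: str, annotation: GenomeAnnotation
) -> str:
    """Synonymous vs nonsynonymous call for a SNP inside coding sequence.

    The alt allele is substituted into the strand-corrected codon and both
    codons translated with the standard genetic code; minus-strand variants
    are complemented implicitly by working in transcript orientation.
    """
    pos0 = pos - 1
    genes = annotation.genes_overlapping(contig, pos0, pos0 + 1)
    tx = None
    for g in genes:
        cand = g.representative_transcript()
        if _in_any(pos0, cand.cds):
            tx = cand
            break
    if tx is None:
        raise ValueError(f"{contig}:{pos} is not in a representative CDS")
    if annotation.sequences[contig][pos0] != ref.upper():
        raise ValueError(
            f"ref allele {ref} disagrees with reference at {contig}:{pos}"
        )
    cds = cds_sequence(tx, annotation)
    local = _cds_local_position(pos0, tx)
    base_ref, base_alt = ref.upper(), alt.upper()
    if tx.strand == "-":
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        base_ref, base_alt = comp[base_ref], comp[base_alt]
    k = local // 3
    codon = cds[3 * k : 3 * k + 3]
    if len(codon) < 3:
        raise ValueError("truncated terminal codon")
    offset = local % 3
    assert codon[offset] == base_ref
    mutant = codon[:offset] + base_alt + codon[offset + 1 :]
    same = Seq(codon).translate() == Seq(mutant).translate()
    return "synonymous" if same else "nonsynonymous"


# ---------------------------------------------------------------------------
# summaries and windows


@dataclass
class VariantSummary:
    """Table-1-style class counts per group (rows) with Nonsyn/Syn ratio."""

    table: pd.DataFrame

    _COLUMNS = [
        "group",
        "n_samples",
        "total",
        "intergenic",
        "UTR3",
        "UTR5",
        "intronic",
        "CDS",
        "nonsynonymous",
        "synonymous",
        "nonsyn_syn_ratio",
    ]


def nonsyn_syn_ratio(nonsyn: int, syn: int) -> float:
    """Count ratio of amino-acid-changing to silent coding SNPs, 2 dp."""
    if syn == 0:
        return float("nan")
    return round(nonsyn / syn, 2)


def summarize_variants(
    matrix: GenotypeMatrix, groups: SampleGroups, annotation: GenomeAnnotation
) -> VariantSummary:
    """Per-role and whole-cohort SNP accounting by genomic context.

    A site counts for a group when at least one member carries a called
    non-reference allele. CDS sites are split syn/nonsyn by codon effect.
    """
    classes = np.array(
        [
            classify_site(c, p, annotation)
            for c, p in zip(matrix.sites["contig"], matrix.sites["pos"])
        ]
    )
    effects = np.array(
        [
            classify_cds_effect(row.contig, row.pos, row.ref, row.alt, annotation)
            if cls == "CDS"
            else ""
            for cls, row in zip(classes, matrix.sites.itertuples())
        ]
    )
    role_samples = {
        role: groups.samples_by_role(role)
        for role in ("wild", "ornamental", "edible")
        if groups.samples_by_role(role)
    }
    role_samples["all"] = list(matrix.sample_ids)

    rows = []
    for name, samples in role_samples.items():
        idx = matrix.sample_indices(samples)
        sub = matrix.codes[idx]
        present = ((sub == 1) | (sub == 2)).any(axis=0)
        row = {"group": name, "n_samples": len(samples), "total": int(present.sum())}
        for cls in SITE_CLASSES:
            row[cls] = int((present & (classes == cls)).sum())
        row["nonsynonymous"] = int((present & (effects == "nonsynonymous")).sum())
        row["synonymous"] = int((present & (effects == "synonymous")).sum())
        row["nonsyn_syn_ratio"] = nonsyn_syn_ratio(row["nonsynonymous"], row["synonymous"])
        rows.append(row)
    table = pd.DataFrame(rows)[VariantSummary._COLUMNS]
    return VariantSummary(table)


def iter_windows(
    contigs: list[tuple[str, int]], window_size: int, step: int | None = None
) -> list[tuple[str, int, int]]:
    """Tile contigs with (contig, start, end) windows, 0-based half-open.

    The last window is truncated at the contig end (its true length is
    end - start)."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    step = window_size if step is None else step
    if not 0 < step <= window_size:
        raise ValueError("need 0 < step <= window_size")
    out = []
    for name, length in contigs:
        start = 0
        while start < length:
            out.append((name, start, min(start + window_size, length)))
            start += step
    return out
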