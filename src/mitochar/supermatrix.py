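"""Concatenated PCG supermatrix assembly for phylogenetic inference.

Workflow: extract the 13 protein-coding genes from annotated mitogenomes as
coding-sense FASTA (alignment happens in external tools), optionally strip
third codon positions (the saturated positions in deep-level insect
analyses), concatenate the per-gene alignments with gap fill for missing
taxa, and write inference-ready matrices: relaxed PHYLIP, NEXUS with a
charset block, or FASTA, plus RAxML-style partition files.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TextIO

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import PCG_NAMES, AnnotatedMitogenome, gene_sequence


@dataclass
class GeneAlignment:
    """One per-gene multiple alignment (equal-length rows, gaps allowed)."""

    gene: str
    taxa: list
    rows: list
    codon_phase_known: bool = True

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValueError(f"{self.gene}: {len(self.taxa)} taxa vs {len(self.rows)} rows")
        if len(set(self.taxa)) != len(self.taxa):
            dups = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise ValueError(f"{self.gene}: duplicate taxa {dups}")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError(f"{self.gene}: rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class SupermatrixBundle:
    """Concatenated matrix plus its partition map.

    ``partitions`` holds (gene, start, end) in 1-based inclusive alignment
    coordinates; the blocks tile the matrix exactly.
    """

    matrix: dict                      # taxon -> concatenated sequence
    partitions: list                  # of (gene, start, end)
    positions_kept: tuple = (1, 2, 3)
    name_map: dict = field(default_factory=dict)  # sanitized -> original

    @property
    def length(self) -> int:
        return next(iter(self.matrix.values())).__len__() if self.matrix else 0


def extract_pcg_records(genomes: list[AnnotatedMitogenome], gene: str,
                        ) -> tuple[list[SeqRecord], list[str]]:
    """Coding-sense records of one PCG across genomes, plus a missing list."""
    if gene not in PCG_NAMES:
        raise ValueError(f"{gene!r} is not one of the 13 canonical PCGs")
    records, missing = [], []
    for g in genomes:
        feat = g.feature_by_name(gene)
        if feat is None:
            missing.append(g.taxon_name or g.accession)
            continue
        label = sanitize_taxon_name(g.taxon_name or g.accession)
        records.append(SeqRecord(Seq(gene_sequence(g, feat)), id=label,
                                 description=gene))
    return records, missing


def extract_pcg_fasta(genomes: list[AnnotatedMitogenome], gene: str,
                      handle: TextIO) -> list[str]:
    """Write one PCG's unaligned multi-FASTA; returns missing-taxon report."""
    records, missing = extract_pcg_records(genomes, gene)
    SeqIO.write(records, handle, "fasta")
    return missing


def read_gene_alignment(handle: TextIO, gene: str,
                        codon_phase_known: bool = True) -> GeneAlignment:
    aln = AlignIO.read(handle, "fasta")
    return GeneAlignment(gene=gene, taxa=[r.id for r in aln],
                         rows=[str(r.seq).upper() for r in aln],
                         codon_phase_known=codon_phase_known)


def pad_to_codon(aln: GeneAlignment, gap: str = "-") -> GeneAlignment:
    """Pad rows with gaps to a multiple of 3 (incomplete terminal codons)."""
    rem = aln.length % 3
    if rem == 0:
        return aln
    pad = gap * (3 - rem)
    return GeneAlignment(gene=aln.gene, taxa=list(aln.taxa),
                         rows=[r + pad for r in aln.rows],
                         codon_phase_known=aln.codon_phase_known)


def strip_codon_positions(aln: GeneAlignment, keep: set = frozenset({1, 2})) -> GeneAlignment:
    """Keep only the requested positions (1-based within each codon)."""
    keep = frozenset(keep)
    if not keep or not keep <= {1, 2, 3}:
        raise ValueError(f"keep must be a non-empty subset of {{1,2,3}}, got {set(keep)}")
    if not aln.codon_phase_known:
        raise ValueError(f"{aln.gene}: codon phase unknown; cannot strip positions")
    if aln.length % 3 != 0:
        raise ValueError(f"{aln.gene}: alignment length {aln.length} is not a "
                         "multiple of 3")
    idx = [i for i in range(aln.length) if (i % 3) + 1 in keep]
    return GeneAlignment(gene=aln.gene, taxa=list(aln.taxa),
                         rows=["".join(r[i] for i in idx) for r in aln.rows],
                         codon_phase_known=(keep == {1, 2, 3}))


def concatenate(alns: list[GeneAlignment], taxa: list | None = None,
                gap: str = "-",
                positions_kept: tuple = (1, 2, 3)) -> SupermatrixBundle:
    """Concatenate gene blocks in order, gap-filling missing taxa."""
    if taxa is None:
        seen: list[str] = []
        for a in alns:
            for t in a.taxa:
                if t not in seen:
                    seen.append(t)
        taxa = seen
    for a in alns:
        extra = set(a.taxa) - set(taxa)
        if extra:
            raise ValueError(f"{a.gene}: taxa {sorted(extra)} missing from master list")
    matrix = {t: [] for t in taxa}
    partitions = []
    pos = 0
    for a in alns:
        row_by_taxon = dict(zip(a.taxa, a.rows))
        for t in taxa:
            matrix[t].append(row_by_taxon.get(t, gap * a.length))
        partitions.append((a.gene, pos + 1, pos + a.length))
        pos += a.length
    return SupermatrixBundle(matrix={t: "".join(parts) for t, parts in matrix.items()},
                             partitions=partitions,
                             positions_kept=tuple(sorted(positions_kept)))


def sanitize_taxon_name(name: str) -> str:
    """PHYLIP/NEXUS-safe taxon label: whitespace and brackets to underscores."""
    out = re.sub(r"[\s()\[\]{}:;,\"']+", "_", name.strip()).strip("_")
    return out or "taxon"


def write_matrix(bundle: SupermatrixBundle, handle: TextIO,
                 format: str = "phylip") -> None:
    """Write the supermatrix as relaxed PHYLIP, NEXUS (with charsets), or FASTA."""
    taxa = list(bundle.matrix)
    ncols = bundle.length
    sanitized = [sanitize_taxon_name(t) for t in taxa]
    if len(set(sanitized)) != len(sanitized):
        dups = sorted({s for s in sanitized if sanitized.count(s) > 1})
        raise ValueError(f"taxon-name collision after sanitization: {dups}")
    if format == "phylip":
        handle.write(f" {len(taxa)} {ncols}\n")
        width = max(len(s) for s in sanitized) + 2
        for s, t in zip(sanitized, taxa):
            handle.write(f"{s:<{width}}{bundle.matrix[t]}\n")
    elif format == "nexus":
        handle.write("#NEXUS\n\nBEGIN DATA;\n")
        handle.write(f"  DIMENSIONS NTAX={len(taxa)} NCHAR={ncols};\n")
        handle.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for s, t in zip(sanitized, taxa):
            handle.write(f"    {s}  {bundle.matrix[t]}\n")
        handle.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for gene, start, end in bundle.partitions:
            handle.write(f"  CHARSET {gene} = {start}-{end};\n")
        handle.write("END;\n")
    elif format == "fasta":
        for s, t in zip(sanitized, taxa):
            handle.write(f">{s}\n{bundle.matrix[t]}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def write_partitions(bundle: SupermatrixBundle, handle: TextIO,
                     style: str = "raxml") -> None:
    """Partition definitions: RAxML-style lines or a NEXUS sets block."""
    if style == "raxml":
        for gene, start, end in bundle.partitions:
            handle.write(f"DNA, {gene} = {start}-{end}\n")
    elif style == "nexus":
        handle.write("#NEXUS\nBEGIN SETS;\n")
        for gene, start, end in bundle.partitions:
            handle.write(f"  CHARSET {gene} = {start}-{end};\n")
        handle.write("END;\n")
    else:
        raise ValueError(f"unknown partition style {style!r}")


def read_matrix(handle: TextIO, format: str = "phylip") -> dict:
    """Read a matrix back (round-trip checking); taxon -> sequence."""
    fmt = {"phylip": "phylip-relaxed", "nexus": "nexus", "fasta": "fasta"}[format]
    aln = AlignIO.read(handle, fmt)
    return {r.id: str(r.seq).upper() for r in aln}
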