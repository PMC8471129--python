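"""Domain model for annotated mitochondrial genomes.

An insect mitogenome is a circular DNA molecule of roughly 14-20 kb carrying
37 genes -- 13 protein-coding genes (PCGs), 22 tRNAs and two rRNAs -- plus one
large non-coding A+T-rich region (the control region, CR).  Genes sit on one
of the two strands: the majority strand (J) that encodes most genes, or the
minority strand (N).

Coordinates are 0-based half-open internally; GenBank I/O converts to and
from the 1-based inclusive convention.  Features may wrap the arbitrary
sequence origin of the circular molecule, in which case ``start > end`` in
linear terms and ``wraps_origin`` is set.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

# ---------------------------------------------------------------------------
# Canonical gene vocabulary
# ---------------------------------------------------------------------------

PCG_NAMES = (
    "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
    "ND5", "ND4", "ND4L", "ND6", "CYTB", "ND1",
)

TRNA_NAMES = (
    "trnI", "trnQ", "trnM", "trnW", "trnC", "trnY", "trnL2", "trnK", "trnD",
    "trnG", "trnA", "trnR", "trnN", "trnS1", "trnE", "trnF", "trnH", "trnT",
    "trnP", "trnS2", "trnL1", "trnV",
)

RRNA_NAMES = ("rrnL", "rrnS")

CANONICAL_NAMES = frozenset(PCG_NAMES) | frozenset(TRNA_NAMES) | frozenset(RRNA_NAMES) | {"CR"}

REGION_CLASSES = ("whole", "PCG_J", "PCG_N", "PCG_all", "tRNA_all", "rRNA_all", "CR")

#: Aliases seen in deposited records, keyed lower-case without punctuation.
_ALIASES = {
    "coi": "COX1", "co1": "COX1", "cox1": "COX1", "coxi": "COX1",
    "coii": "COX2", "co2": "COX2", "cox2": "COX2", "coxii": "COX2",
    "coiii": "COX3", "co3": "COX3", "cox3": "COX3", "coxiii": "COX3",
    "cytb": "CYTB", "cob": "CYTB",
    "atp6": "ATP6", "atpase6": "ATP6", "atp8": "ATP8", "atpase8": "ATP8",
    "nad1": "ND1", "nd1": "ND1", "nad2": "ND2", "nd2": "ND2",
    "nad3": "ND3", "nd3": "ND3", "nad4": "ND4", "nd4": "ND4",
    "nad4l": "ND4L", "nd4l": "ND4L", "nad5": "ND5", "nd5": "ND5",
    "nad6": "ND6", "nd6": "ND6",
    "rrnl": "rrnL", "16s": "rrnL", "lrrna": "rrnL", "lsu": "rrnL", "16srrna": "rrnL",
    "rrns": "rrnS", "12s": "rrnS", "srrna": "rrnS", "ssu": "rrnS", "12srrna": "rrnS",
    "dloop": "CR", "cr": "CR", "atrichregion": "CR", "controlregion": "CR",
    "atrich": "CR",
}

#: Single-letter amino-acid codes for tRNA product names ("tRNA-Leu" etc.).
_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}

# Anticodon-bearing disambiguation for the duplicated tRNAs.  trnL1=Leu(CUN),
# trnL2=Leu(UUR); trnS1=Ser(AGN), trnS2=Ser(UCN).
_TRNA_ISOTYPE = {
    ("L", "cun"): "trnL1", ("L", "uur"): "trnL2", ("L", "uag"): "trnL1",
    ("L", "uaa"): "trnL2", ("L", "taa"): "trnL2", ("L", "tag"): "trnL1",
    ("S", "agn"): "trnS1", ("S", "ucn"): "trnS2", ("S", "uga"): "trnS2",
    ("S", "gcu"): "trnS1", ("S", "tga"): "trnS2", ("S", "gct"): "trnS1",
}


class MitoParseError(ValueError):
    """Raised when a record cannot be parsed into an AnnotatedMitogenome."""


class MitoValidationError(ValueError):
    """Raised when an otherwise parseable record violates model invariants."""


def normalize_gene_name(raw: str) -> str | None:
    """Map a gene/product label from an annotation to the canonical symbol.

    Returns ``None`` when the label is not recognized; callers record such
    features in metadata rather than dropping them.
    """
    s = raw.strip()
    key = re.sub(r"[^0-9a-z]", "", s.lower())
    if s in CANONICAL_NAMES:
        return s
    if key in _ALIASES:
        return _ALIASES[key]
    # trnX / tRNA-Xxx forms, optionally with an anticodon or isotype tag
    m = re.match(r"^trn([A-Za-z])(\d?)$", s)
    if m:
        letter, num = m.group(1).upper(), m.group(2)
        cand = f"trn{letter}{num}"
        return cand if cand in CANONICAL_NAMES else None
    m = re.match(r"^trna?[-_ ]?([A-Za-z]{3})\s*(?:\(([^)]+)\))?", s, re.IGNORECASE)
    if m:
        aa = _AA3_TO_1.get(m.group(1).lower())
        if aa is None:
            return None
        tag = (m.group(2) or "").lower()
        if aa in ("L", "S"):
            iso = _TRNA_ISOTYPE.get((aa, tag))
            return iso  # ambiguous Leu/Ser without a tag stays unresolved
        cand = f"trn{aa}"
        return cand if cand in CANONICAL_NAMES else None
    m = re.match(r"^trn([A-Za-z])\(([^)]+)\)$", s)
    if m:
        aa, tag = m.group(1).upper(), m.group(2).lower()
        if aa in ("L", "S"):
            return _TRNA_ISOTYPE.get((aa, tag))
        cand = f"trn{aa}"
        return cand if cand in CANONICAL_NAMES else None
    return None


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass
class GeneFeature:
    """One annotated gene (or the control region) on the circular molecule.

    ``start``/``end`` are 0-based half-open J-strand coordinates.  For a
    feature that wraps the origin ``wraps_origin`` is True and ``end`` is the
    post-origin endpoint (so ``end <= start`` linearly).
    """

    name: str
    start: int
    end: int
    strand: str  # "J" or "N"
    kind: str    # "PCG" | "tRNA" | "rRNA" | "CR"
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("J", "N"):
            raise MitoValidationError(f"strand must be J or N, got {self.strand!r}")
        if self.kind not in ("PCG", "tRNA", "rRNA", "CR"):
            raise MitoValidationError(f"unknown feature kind {self.kind!r}")
        if not self.wraps_origin and self.end <= self.start:
            raise MitoValidationError(
                f"{self.name}: end ({self.end}) must exceed start ({self.start}) "
                "for a non-wrapping feature"
            )

    def length(self, genome_length: int) -> int:
        if self.wraps_origin:
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome sequence plus its ordered gene features."""

    accession: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    is_circular: bool = True
    taxon_name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if not (0 <= f.start < self.length_bp) or f.end > self.length_bp:
                raise MitoValidationError(
                    f"{f.name}: interval [{f.start},{f.end}) outside genome "
                    f"of length {self.length_bp}"
                )

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    def feature_by_name(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None

    def validate_unique_names(self) -> None:
        seen: dict[str, int] = {}
        for f in self.features:
            seen[f.name] = seen.get(f.name, 0) + 1
        dups = sorted(n for n, c in seen.items() if c > 1 and n != "CR")
        if dups:
            raise MitoValidationError(f"duplicate canonical gene names: {', '.join(dups)}")


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def gene_sequence(genome: AnnotatedMitogenome, feature: GeneFeature) -> str:
    """Coding-sense sequence of a feature.

    J-strand features are returned as the forward slice; N-strand features as
    its reverse complement.  Features that wrap the origin are concatenated
    across it (tail of the sequence followed by the head).
    """
    L = genome.length_bp
    if not (0 <= feature.start < L) or feature.end > L or feature.end < 0:
        raise MitoValidationError(
            f"{feature.name}: coordinates [{feature.start},{feature.end}) "
            f"outside genome of length {L}"
        )
    if feature.wraps_origin:
        if not genome.is_circular:
            raise MitoValidationError(
                f"{feature.name} wraps the origin of a non-circular genome"
            )
        j_slice = genome.sequence[feature.start:] + genome.sequence[:feature.end]
    else:
        j_slice = genome.sequence[feature.start:feature.end]
    return j_slice if feature.strand == "J" else reverse_complement(j_slice)


# ---------------------------------------------------------------------------
# GenBank I/O (via Biopython)
# ---------------------------------------------------------------------------

_KIND_BY_FTYPE = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def _feature_label(sf: SeqFeature) -> str:
    for q in ("gene", "product", "note", "standard_name"):
        vals = sf.qualifiers.get(q)
        if vals:
            return str(vals[0])
    return ""


def parse_genbank(handle: TextIO | str) -> AnnotatedMitogenome:
    """Read one GenBank flat file into an AnnotatedMitogenome.

    GenBank 1-based inclusive coordinates become 0-based half-open; a CDS
    with a ``join(a..L,1..b)`` location on a circular record becomes a single
    origin-wrapping feature.  Features whose labels cannot be normalized are
    collected under ``metadata['unparsed_features']``.
    """
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    try:
        record = next(SeqIO.parse(handle, "genbank"))
    except StopIteration:
        raise MitoParseError("no GenBank record found in stream") from None
    try:
        seq_str = str(record.seq)
    except Exception as exc:  # undefined sequence: LOCUS length but no ORIGIN
        raise MitoParseError(f"{record.id}: record has no ORIGIN sequence") from exc
    if not seq_str:
        raise MitoParseError(f"{record.id}: record has no ORIGIN sequence")

    topology = str(record.annotations.get("topology", "")).lower()
    is_circular = topology != "linear"

    L = len(seq_str)
    features: list[GeneFeature] = []
    unparsed: list[dict] = []
    for sf in record.features:
        if sf.type in _KIND_BY_FTYPE:
            kind = _KIND_BY_FTYPE[sf.type]
        elif sf.type in ("misc_feature", "D-loop"):
            kind = "CR"
        else:
            continue
        label = _feature_label(sf)
        name = normalize_gene_name(label) if kind != "CR" else (
            normalize_gene_name(label) or ("CR" if sf.type == "D-loop" else None)
        )
        if kind == "CR" and name != "CR":
            # misc_feature with an unrelated label: not the control region
            if name is None:
                unparsed.append({"type": sf.type, "label": label, "location": str(sf.location)})
            continue
        if name is None:
            unparsed.append({"type": sf.type, "label": label, "location": str(sf.location)})
            continue
        strand = "N" if sf.location.strand == -1 else "J"
        parts = sf.location.parts
        if len(parts) == 2 and int(parts[0].end) == L and int(parts[1].start) == 0:
            start, end, wraps = int(parts[0].start), int(parts[1].end), True
        elif len(parts) == 1:
            start, end, wraps = int(sf.location.start), int(sf.location.end), False
        else:
            unparsed.append({"type": sf.type, "label": label, "location": str(sf.location)})
            continue
        features.append(GeneFeature(name=name, start=start, end=end,
                                    strand=strand, kind=kind, wraps_origin=wraps))

    taxon = record.annotations.get("organism", "") or record.description
    genome = AnnotatedMitogenome(
        accession=record.id or record.name,
        sequence=seq_str,
        features=features,
        is_circular=is_circular,
        taxon_name=taxon,
        metadata={"unparsed_features": unparsed} if unparsed else {},
    )
    genome.validate_unique_names()
    return genome


def to_seqrecord(genome: AnnotatedMitogenome) -> SeqRecord:
    """Convert back to a Biopython SeqRecord with GenBank-style features."""
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.accession,
        name=genome.accession.split(".")[0][:16] or "mitogenome",
        description=f"{genome.taxon_name} mitochondrion, complete genome".strip(),
    )
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if genome.is_circular else "linear"
    if genome.taxon_name:
        rec.annotations["organism"] = genome.taxon_name
    L = genome.length_bp
    for f in genome.features:
        strand = -1 if f.strand == "N" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                SimpleLocation(f.start, L, strand=strand),
                SimpleLocation(0, f.end, strand=strand),
            ])
        else:
            loc = SimpleLocation(f.start, f.end, strand=strand)
        if f.kind == "PCG":
            ftype, quals = "CDS", {"gene": [f.name], "transl_table": ["5"]}
        elif f.kind == "tRNA":
            ftype, quals = "tRNA", {"gene": [f.name], "product": [f.name]}
        elif f.kind == "rRNA":
            ftype, quals = "rRNA", {"gene": [f.name], "product": [f.name]}
        else:
            ftype, quals = "misc_feature", {"note": ["A+T-rich region"]}
        rec.features.append(SeqFeature(loc, type=ftype, qualifiers=quals))
    return rec


def write_genbank(genome: AnnotatedMitogenome, handle: TextIO) -> None:
    SeqIO.write([to_seqrecord(genome)], handle, "genbank")


def write_fasta(genome: AnnotatedMitogenome, handle: TextIO) -> None:
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession,
                    description=genome.taxon_name)
    SeqIO.write([rec], handle, "fasta")


def read_fasta(handle: TextIO | str) -> AnnotatedMitogenome:
    """Read a plain FASTA genome (no features)."""
    if isinstance(handle, str):
        handle = io.StringIO(handle)
    rec = next(SeqIO.parse(handle, "fasta"))
    return AnnotatedMitogenome(accession=rec.id, sequence=str(rec.seq),
                               taxon_name=rec.description.partition(" ")[2])


# ---------------------------------------------------------------------------
# Feature-table I/O (TSV, 1-based inclusive for human readability)
# ---------------------------------------------------------------------------

FEATURE_TABLE_COLUMNS = ["name", "start", "end", "strand", "length", "kind"]


def feature_table(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """One row per feature; start/end 1-based inclusive as in GenBank."""
    rows = []
    for f in genome.features:
        rows.append({
            "name": f.name,
            "start": f.start + 1,
            "end": f.end if not f.wraps_origin else f.end,  # post-origin endpoint
            "strand": f.strand,
            "length": f.length(genome.length_bp),
            "kind": f.kind,
        })
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def write_feature_table(genome: AnnotatedMitogenome, handle: TextIO) -> None:
    feature_table(genome).to_csv(handle, sep="\t", index=False)


def read_feature_table(handle: TextIO, genome_length: int) -> list[GeneFeature]:
    """Inverse of write_feature_table (needs the genome length to detect wraps)."""
    df = pd.read_csv(handle, sep="\t")
    feats = []
    for _, r in df.iterrows():
        start = int(r["start"]) - 1
        end = int(r["end"])
        wraps = end <= start
        feats.append(GeneFeature(name=str(r["name"]), start=start, end=end,
                                 strand=str(r["strand"]), kind=str(r["kind"]),
                                 wraps_origin=wraps))
    return feats


def load_ancestral_order() -> pd.DataFrame:
    """The packaged ancestral insect gene order and default gene sizes."""
    with resources.files("mitochar.data").joinpath("ancestral_order.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")
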