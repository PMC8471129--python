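"""Codon-level analyses under the invertebrate mitochondrial genetic code.

Covers translation (NCBI table 5: ATA=Met, TGA=Trp, AGA/AGG=Ser, stops
TAA/TAG only), start/stop-codon classification including the incomplete
terminal codons (a trailing T or TA completed to TAA by polyadenylation),
pooled codon counting and relative synonymous codon usage (RSCU).

RSCU of codon c in a synonymous family F is count(c) * |F| / sum of counts
over F; within any family that occurs at all, RSCU values sum to |F|.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable
from Bio.Seq import Seq

DNA = "ACGT"
ALL_CODONS = tuple("".join(p) for p in itertools.product(DNA, repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    name: str
    codon_to_aa: dict  # 64 codons -> single-letter aa, '*' for stop
    start_codons: frozenset
    stop_codons: frozenset

    def families(self) -> dict:
        """Amino acid -> tuple of synonymous codons (stops excluded)."""
        fam: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            if aa != "*":
                fam.setdefault(aa, []).append(codon)
        return {aa: tuple(sorted(cs)) for aa, cs in fam.items()}


def invertebrate_mito_code() -> GeneticCode:
    """NCBI translation table 5, via Biopython's codon tables."""
    tbl = CodonTable.unambiguous_dna_by_id[5]
    mapping = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        mapping[stop] = "*"
    assert len(mapping) == 64
    return GeneticCode(
        name="invertebrate mitochondrial (NCBI table 5)",
        codon_to_aa=mapping,
        start_codons=frozenset(tbl.start_codons),
        stop_codons=frozenset(tbl.stop_codons),
    )


def translate(seq: str, code: GeneticCode | None = None) -> str:
    """Translate a coding-sense DNA sequence; the 1-2 nt remainder of a
    non-multiple-of-3 length is ignored.  Codons containing ambiguity codes
    translate to X.  Raises ValueError when the sequence is shorter than one
    codon.
    """
    if len(seq) < 3:
        raise ValueError(f"sequence of length {len(seq)} is shorter than one codon")
    code = code or invertebrate_mito_code()
    s = seq.upper()
    usable = len(s) - len(s) % 3
    out = []
    for i in range(0, usable, 3):
        codon = s[i:i + 3]
        out.append(code.codon_to_aa.get(codon, "X"))
    return "".join(out)


def translate_biopython(seq: str) -> str:
    """Independent translation route through Bio.Seq (cross-check helper)."""
    s = seq.upper()
    usable = len(s) - len(s) % 3
    return str(Seq(s[:usable]).translate(table=5))


@dataclass(frozen=True)
class CodonInventory:
    """Start/stop classification of one annotated PCG."""

    gene: str
    start_codon: str
    start_class: str          # "ATN" | "GTG" | "nonstandard"
    stop_codon: str           # "TAA" | "TAG" | "TA" | "T" | observed triplet
    stop_complete: bool
    stop_flagged: bool        # complete-length gene whose last codon is not TAA/TAG
    length_bp: int
    internal_stops: tuple = ()


def classify_terminals(gene: str, seq: str, code: GeneticCode | None = None) -> CodonInventory:
    """Classify the start and (possibly incomplete) stop codon of a PCG.

    The reading frame starts at base 0.  Length mod 3 decides the stop type:
    remainder 0 means the final triplet must be a complete TAA/TAG (flagged
    otherwise), remainder 1 a trailing "T", remainder 2 a trailing "TA" --
    both incomplete stops completed by post-transcriptional polyadenylation.
    Internal in-frame stops are reported as 0-based codon start offsets.
    """
    if len(seq) < 6:
        raise ValueError(f"{gene}: sequence too short to classify ({len(seq)} bp)")
    code = code or invertebrate_mito_code()
    s = seq.upper()
    start = s[:3]
    if start.startswith("AT"):
        start_class = "ATN"
    elif start == "GTG":
        start_class = "GTG"
    else:
        start_class = "nonstandard"

    rem = len(s) % 3
    if rem == 0:
        stop = s[-3:]
        complete = stop in code.stop_codons
        flagged = not complete
        coding_end = len(s) - 3
    elif rem == 1:
        stop = s[-1]
        complete = False
        flagged = stop != "T"
        coding_end = len(s) - 1
    else:
        stop = s[-2:]
        complete = False
        flagged = stop != "TA"
        coding_end = len(s) - 2

    internal = tuple(
        i for i in range(3, coding_end - 2, 3) if s[i:i + 3] in code.stop_codons
    )
    return CodonInventory(gene=gene, start_codon=start, start_class=start_class,
                          stop_codon=stop, stop_complete=complete,
                          stop_flagged=flagged, length_bp=len(s),
                          internal_stops=internal)


@dataclass
class CodonUsageTable:
    """Pooled codon counts and RSCU over a set of protein-coding genes."""

    counts: dict = field(default_factory=lambda: {c: 0 for c in ALL_CODONS})
    rscu: dict = field(default_factory=dict)   # codon -> float | None
    total_codons: int = 0
    ambiguous_codons: int = 0

    def as_dataframe(self, code: GeneticCode | None = None):
        import pandas as pd
        code = code or invertebrate_mito_code()
        rows = [{"codon": c, "rna_codon": c.replace("T", "U"),
                 "aa": code.codon_to_aa[c], "count": self.counts[c],
                 "rscu": self.rscu.get(c)} for c in ALL_CODONS]
        return pd.DataFrame(rows)


def codon_usage(pcg_seqs: list[str], code: GeneticCode | None = None,
                include_start: bool = True, include_stop: bool = False) -> CodonUsageTable:
    """Pooled codon counts and RSCU over coding-sense PCG sequences.

    Defaults include the initiation codon and exclude the terminal stop
    codon (complete or incomplete; incomplete stops are not full codons and
    the trailing remainder is always dropped).  Codons containing ambiguity
    letters are tallied separately, not counted.  RSCU for codons of an
    amino acid absent from the data is None.
    """
    code = code or invertebrate_mito_code()
    table = CodonUsageTable()
    for seq in pcg_seqs:
        if len(seq) < 3:
            raise ValueError("each PCG sequence must be at least one codon long")
        s = seq.upper()
        usable = len(s) - len(s) % 3
        codons = [s[i:i + 3] for i in range(0, usable, 3)]
        if not include_stop and codons and codons[-1] in code.stop_codons:
            codons = codons[:-1]
        if not include_start and codons:
            codons = codons[1:]
        for codon in codons:
            if codon in table.counts:
                table.counts[codon] += 1
                table.total_codons += 1
            else:
                table.ambiguous_codons += 1

    for aa, fam in code.families().items():
        fam_total = sum(table.counts[c] for c in fam)
        for c in fam:
            table.rscu[c] = (table.counts[c] * len(fam) / fam_total) if fam_total else None
    return table


def most_frequent_codons(table: CodonUsageTable, k: int = 4,
                         code: GeneticCode | None = None) -> list[tuple[str, str, int]]:
    """Top-k codons by count (ties alphabetical), as (RNA codon, aa, count)."""
    code = code or invertebrate_mito_code()
    ranked = sorted(((c, n) for c, n in table.counts.items() if n > 0),
                    key=lambda cn: (-cn[1], cn[0]))
    return [(c.replace("T", "U"), code.codon_to_aa[c], n) for c, n in ranked[:k]]


def plot_rscu(table: CodonUsageTable, path: str, code: GeneticCode | None = None) -> None:
    """Optional RSCU bar chart grouped by amino acid (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    code = code or invertebrate_mito_code()
    fams = sorted(code.families().items())
    labels, heights = [], []
    for aa, fam in fams:
        for c in fam:
            labels.append(f"{c.replace('T', 'U')}\n{aa}")
            heights.append(table.rscu.get(c) or 0.0)
    fig, ax = plt.subplots(figsize=(18, 4))
    ax.bar(range(len(labels)), heights, color="steelblue")
    ax.set_xticks(range(len(labels)), labels, fontsize=5, rotation=90)
    ax.set_ylabel("RSCU")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
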