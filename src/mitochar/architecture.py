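"""Gene architecture: order, intergenic spacers, overlaps, shared motifs.

Insect mitogenomes are compact: genes frequently abut or overlap by a few
bases, and the intergenic nucleotides (IGNs) rarely exceed 20 bp.  This
module extracts the circular gene order (rotation-normalized to start at
trnI), compares orders by breakpoint distance (the number of signed gene
adjacencies of one circle absent from the other), accounts for every
spacer/overlap junction, and extracts overlap motifs shared across genomes
as minimal IUPAC consensus strings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .model import AnnotatedMitogenome, load_ancestral_order

# minimal IUPAC code covering each set of observed bases
_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
    frozenset("CGT"): "B", frozenset("AGT"): "D", frozenset("ACT"): "H",
    frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def iupac_consensus(seqs: list[str]) -> str:
    """Column-wise minimal-ambiguity IUPAC consensus of equal-length strings."""
    if len({len(s) for s in seqs}) != 1:
        raise ValueError("consensus requires equal-length sequences")
    out = []
    for col in zip(*(s.upper() for s in seqs)):
        bases = frozenset(col)
        out.append(_IUPAC.get(bases, "N"))
    return "".join(out)


@dataclass(frozen=True)
class GeneOrder:
    """Ordered (gene, strand) tokens around the circle, from trnI by convention."""

    tokens: tuple  # of (name, strand)
    circular: bool = True

    @property
    def names(self) -> tuple:
        return tuple(t[0] for t in self.tokens)


def ancestral_gene_order() -> GeneOrder:
    df = load_ancestral_order()
    return GeneOrder(tokens=tuple(zip(df["name"], df["strand"])))


def gene_order(genome: AnnotatedMitogenome, rotate_to: str = "trnI") -> GeneOrder:
    """Features in J-strand positional order, rotated to start at ``rotate_to``
    when that gene is present."""
    feats = sorted(genome.features, key=lambda f: f.start)
    tokens = [(f.name, f.strand) for f in feats]
    names = [t[0] for t in tokens]
    if rotate_to in names:
        i = names.index(rotate_to)
        tokens = tokens[i:] + tokens[:i]
    return GeneOrder(tokens=tuple(tokens), circular=genome.is_circular)


def _adjacencies(order: GeneOrder, genes: set) -> set:
    """Canonical signed adjacency set over a restricted gene vocabulary.

    Reading the circle in the opposite direction flips both strands and the
    pair order; each adjacency is stored as the lexicographic minimum of the
    two equivalent representations so comparisons are direction-invariant.
    """
    toks = [t for t in order.tokens if t[0] in genes]
    n = len(toks)
    adj = set()
    flip = {"J": "N", "N": "J"}
    rng = range(n) if order.circular else range(n - 1)
    for i in rng:
        a, b = toks[i], toks[(i + 1) % n]
        fwd = (a, b)
        rev = ((b[0], flip[b[1]]), (a[0], flip[a[1]]))
        adj.add(min(fwd, rev))
    return adj


@dataclass(frozen=True)
class OrderComparison:
    identical: bool
    breakpoints: int
    displaced_genes: tuple   # genes participating in a broken adjacency
    only_in_a: tuple
    only_in_b: tuple


def compare_orders(a: GeneOrder, b: GeneOrder) -> OrderComparison:
    """Breakpoint comparison of two circular signed gene orders.

    Genes present in only one order are listed and excluded from the
    breakpoint computation.  ``identical`` means zero breakpoints with every
    shared gene on the same strand in both orders.
    """
    genes_a = {t[0] for t in a.tokens}
    genes_b = {t[0] for t in b.tokens}
    shared = genes_a & genes_b
    adj_a = _adjacencies(a, shared)
    adj_b = _adjacencies(b, shared)
    broken = adj_a - adj_b
    displaced = sorted({g for pair in broken for (g, _s) in pair})
    strands_a = {t[0]: t[1] for t in a.tokens if t[0] in shared}
    strands_b = {t[0]: t[1] for t in b.tokens if t[0] in shared}
    same_strands = strands_a == strands_b
    return OrderComparison(
        identical=(not broken) and same_strands and not (genes_a ^ genes_b),
        breakpoints=len(broken),
        displaced_genes=tuple(displaced),
        only_in_a=tuple(sorted(genes_a - genes_b)),
        only_in_b=tuple(sorted(genes_b - genes_a)),
    )


@dataclass(frozen=True)
class SpacerOrOverlap:
    """One junction between positionally consecutive features."""

    upstream_gene: str
    downstream_gene: str
    kind: str        # "spacer" | "overlap" | "abutting"
    length_bp: int   # positive magnitude; 0 for abutting
    sequence: str    # J-strand bases of the spacer/overlap region


@dataclass(frozen=True)
class ArchitectureSummary:
    n_spacers: int
    total_spacer_bp: int
    n_overlaps: int
    total_overlap_bp: int


def spacers_and_overlaps(genome: AnnotatedMitogenome,
                         include_cr_junctions: bool = False,
                         ) -> tuple[list[SpacerOrOverlap], ArchitectureSummary]:
    """Every junction between consecutive features around the circle.

    The junction list always covers the full circle (including junctions
    flanking the CR), so that feature lengths + spacers - overlaps close to
    the genome length.  The summary follows the compact-mitogenome reporting
    convention: spacers at junctions where a gene abuts the CR are excluded
    from the IGN count (the CR itself is the "spacer" there) unless
    ``include_cr_junctions`` is set.  Overlap junctions always count.
    """
    feats = sorted(genome.features, key=lambda f: f.start)
    if not feats:
        return [], ArchitectureSummary(0, 0, 0, 0)
    L = genome.length_bp
    junctions: list[SpacerOrOverlap] = []
    n = len(feats)
    for i in range(n if genome.is_circular else n - 1):
        prev, nxt = feats[i], feats[(i + 1) % n]
        prev_end = prev.end if not prev.wraps_origin else prev.end + L
        nxt_start = nxt.start + (L if (i + 1) == n else 0)
        gap = nxt_start - prev_end
        if i + 1 < n and nxt.end < prev.end and not prev.wraps_origin:
            warnings.warn(
                f"{nxt.name} is contained within {prev.name}; junctions are "
                "computed pairwise between positional neighbours")
        if gap > 0:
            kind = "spacer"
            seq = _circular_slice(genome.sequence, prev_end % L, gap)
        elif gap == 0:
            kind, seq = "abutting", ""
        else:
            kind = "overlap"
            seq = _circular_slice(genome.sequence, nxt_start % L, -gap)
        junctions.append(SpacerOrOverlap(upstream_gene=prev.name,
                                         downstream_gene=nxt.name,
                                         kind=kind, length_bp=abs(gap), sequence=seq))

    def counts_as_ign(j: SpacerOrOverlap) -> bool:
        if include_cr_junctions:
            return True
        return "CR" not in (j.upstream_gene, j.downstream_gene)

    spacers = [j for j in junctions if j.kind == "spacer" and counts_as_ign(j)]
    overlaps = [j for j in junctions if j.kind == "overlap"]
    summary = ArchitectureSummary(
        n_spacers=len(spacers),
        total_spacer_bp=sum(j.length_bp for j in spacers),
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(j.length_bp for j in overlaps),
    )
    return junctions, summary


def _circular_slice(seq: str, start: int, length: int) -> str:
    end = start + length
    if end <= len(seq):
        return seq[start:end]
    return seq[start:] + seq[:end - len(seq)]


def architecture_closure(genome: AnnotatedMitogenome) -> int:
    """Sum of feature lengths + spacers - overlaps around the circle.

    Equals the genome length when no feature is contained in another.
    """
    junctions, _ = spacers_and_overlaps(genome, include_cr_junctions=True)
    feat_total = sum(f.length(genome.length_bp) for f in genome.features)
    spacer_total = sum(j.length_bp for j in junctions if j.kind == "spacer")
    overlap_total = sum(j.length_bp for j in junctions if j.kind == "overlap")
    return feat_total + spacer_total - overlap_total


def shared_overlap_motifs(genomes: list[AnnotatedMitogenome]) -> dict:
    """Gene-pair overlaps present in every genome, with IUPAC consensus.

    Returns ``{(upstream, downstream): {"length": int, "consensus": str}}``
    for pairs whose overlap length agrees across all genomes; pairs with
    differing lengths are reported with per-genome lengths and no consensus.
    Overlap sequences are compared on the J strand.
    """
    if len(genomes) < 1:
        raise ValueError("at least one genome required")
    per_genome: list[dict] = []
    for g in genomes:
        junctions, _ = spacers_and_overlaps(g, include_cr_junctions=True)
        per_genome.append({(j.upstream_gene, j.downstream_gene): j
                           for j in junctions if j.kind == "overlap"})
    shared_pairs = set(per_genome[0])
    for d in per_genome[1:]:
        shared_pairs &= set(d)
    out = {}
    for pair in sorted(shared_pairs):
        entries = [d[pair] for d in per_genome]
        lengths = {e.length_bp for e in entries}
        if len(lengths) == 1:
            out[pair] = {
                "length": entries[0].length_bp,
                "consensus": iupac_consensus([e.sequence for e in entries])
                if len(genomes) > 1 else entries[0].sequence,
            }
        else:
            out[pair] = {
                "length": None,
                "per_genome_lengths": {g.accession: e.length_bp
                                       for g, e in zip(genomes, entries)},
            }
    return out


def junction_table(junctions: list[SpacerOrOverlap]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"upstream": j.upstream_gene, "downstream": j.downstream_gene,
          "kind": j.kind, "length": j.length_bp, "sequence": j.sequence}
         for j in junctions],
        columns=["upstream", "downstream", "kind", "length", "sequence"])
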