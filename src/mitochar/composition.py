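"""Nucleotide composition and strand-asymmetry (skew) statistics.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C), computed from
exact base counts; A+T content is 100*(A+T)/(A+T+G+C).  IUPAC ambiguity
codes are accepted in input but excluded from every denominator and tallied
separately, since the skew formulas are defined over A, C, G, T only.

Region-level statistics follow the standard reporting layout for insect
mitogenomes: the whole molecule, the protein-coding genes split by strand
(majority J vs minority N, each taken in coding sense), all PCGs pooled, the
pooled tRNAs and rRNAs, and the A+T-rich control region (CR).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .model import AnnotatedMitogenome, gene_sequence


@dataclass(frozen=True)
class CompositionStats:
    """Base counts and derived composition statistics for one region."""

    region: str
    length_bp: int
    count_A: int
    count_T: int
    count_G: int
    count_C: int
    count_other: int        # IUPAC ambiguity codes, excluded from denominators
    at_content: float | None  # percent
    at_skew: float | None     # (A-T)/(A+T), None when A+T == 0
    gc_skew: float | None     # (G-C)/(G+C), None when G+C == 0

    def rounded(self) -> dict:
        """Report-style rounding: A+T% to 1 decimal, skews to 2 decimals."""
        return {
            "region": self.region,
            "length_bp": self.length_bp,
            "at_content": None if self.at_content is None else round(self.at_content, 1),
            "at_skew": None if self.at_skew is None else round(self.at_skew, 2),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, 2),
        }


def base_stats(seq: str, region: str = "whole") -> CompositionStats:
    """Exact composition statistics of one sequence.

    Raises ValueError on an empty sequence.  Skews with a zero denominator
    are reported as None (undefined), never as 0.
    """
    if not seq:
        raise ValueError("cannot compute composition of an empty sequence")
    s = seq.upper()
    a, t, g, c = s.count("A"), s.count("T"), s.count("G"), s.count("C")
    other = len(s) - (a + t + g + c)
    acgt = a + t + g + c
    at_content = 100.0 * (a + t) / acgt if acgt else None
    at_skew = (a - t) / (a + t) if (a + t) else None
    gc_skew = (g - c) / (g + c) if (g + c) else None
    return CompositionStats(region=region, length_bp=len(s), count_A=a, count_T=t,
                            count_G=g, count_C=c, count_other=other,
                            at_content=at_content, at_skew=at_skew, gc_skew=gc_skew)


class RegionAbsent:
    """Marker for a requested region class with no member features."""

    def __init__(self, region: str):
        self.region = region

    def __repr__(self) -> str:  # pragma: no cover
        return f"RegionAbsent({self.region!r})"


def region_stats(genome: AnnotatedMitogenome,
                 regions: tuple[str, ...] = ("whole", "PCG_J", "PCG_N", "PCG_all",
                                             "tRNA_all", "rRNA_all", "CR"),
                 ) -> list[CompositionStats | RegionAbsent]:
    """Composition statistics per region class.

    PCG_J / PCG_N pool the coding-sense sequences of majority- and
    minority-strand PCGs; overlapping genes contribute their full spans to
    each gene's slice, so region lengths are sums of gene lengths.  Regions
    with no member features yield a RegionAbsent marker.
    """
    pools: dict[str, list[str]] = {r: [] for r in regions}
    for f in genome.features:
        seq = gene_sequence(genome, f)
        if f.kind == "PCG":
            for key in ("PCG_all", "PCG_J" if f.strand == "J" else "PCG_N"):
                if key in pools:
                    pools[key].append(seq)
        elif f.kind == "tRNA" and "tRNA_all" in pools:
            pools["tRNA_all"].append(seq)
        elif f.kind == "rRNA" and "rRNA_all" in pools:
            pools["rRNA_all"].append(seq)
        elif f.kind == "CR" and "CR" in pools:
            pools["CR"].append(seq)

    out: list[CompositionStats | RegionAbsent] = []
    for r in regions:
        if r == "whole":
            out.append(base_stats(genome.sequence, region="whole"))
        elif pools[r]:
            out.append(base_stats("".join(pools[r]), region=r))
        else:
            out.append(RegionAbsent(r))
    return out


def composition_table(genomes: list[AnnotatedMitogenome], rounded: bool = True) -> pd.DataFrame:
    """Tidy per-genome, per-region composition table (report layout)."""
    rows = []
    for g in genomes:
        for st in region_stats(g):
            if isinstance(st, RegionAbsent):
                continue
            rec = st.rounded() if rounded else {
                "region": st.region, "length_bp": st.length_bp,
                "at_content": st.at_content, "at_skew": st.at_skew,
                "gc_skew": st.gc_skew,
            }
            rows.append({"accession": g.accession, "taxon": g.taxon_name, **rec})
    return pd.DataFrame(rows)
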