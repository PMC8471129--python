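"""Synthetic annotated mitogenomes with known ground truth.

The generator emulates the structure of a phasmatodean (stick-insect)
mitogenome: 37 genes in the ancestral insect order plus one A+T-rich
control region, a strong A+T bias with configurable strand skews, compact
gene packing with planted intergenic spacers and overlaps (including the
conserved trnW/trnC, COX1/trnL2, ATP8/ATP6 and ATP6/COX3 overlap motifs),
protein-coding genes that are valid open reading frames under the
invertebrate mitochondrial code (ATN starts, TAA/TAG stops, optional
incomplete terminal T), and a control region carrying planted tandem and
dispersed repeats.

Every structural choice is recorded in a GroundTruth object so downstream
modules can be tested against exactly known answers.  Generation is fully
deterministic under a fixed seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .codons import invertebrate_mito_code
from .model import AnnotatedMitogenome, GeneFeature, load_ancestral_order, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# J-strand overlap motifs conserved across phasmatodean mitogenomes
DEFAULT_OVERLAPS = (
    ("trnW", "trnC", 8, "AAGTCTTA"),
    ("COX1", "trnL2", 5, "TCTAA"),
    ("ATP8", "ATP6", 4, "ATAA"),
    ("ATP6", "COX3", 1, "A"),
)

# five spacers totalling 41 bp; the two long ones mirror the commonly
# reported trnI-trnQ and ND1-trnL1 insertions
DEFAULT_SPACERS = (
    ("trnI", "trnQ", 13),
    ("trnC", "trnY", 4),
    ("ND3", "trnA", 3),
    ("trnS1", "trnE", 3),
    ("ND1", "trnL1", 18),
)


@dataclass
class GeneratorSpec:
    """Parameters of one synthetic mitogenome."""

    seed: int = 1
    genome_at_fraction: float = 0.756
    j_strand_at_skew: float = 0.19
    j_strand_gc_skew: float = -0.22
    cr_at_fraction: float = 0.80
    gene_order: tuple | None = None          # ((name, strand), ...); default ancestral
    gene_lengths: dict | None = None         # overrides of the packaged defaults
    cr_length: int = 2200
    cr_repeats: tuple = ((32, 6.0, 1.0),)    # (unit_length, copies, identity)
    cr_dispersed: tuple = ()                 # (length, separation_bp)
    planted_overlaps: tuple = DEFAULT_OVERLAPS
    planted_spacers: tuple = DEFAULT_SPACERS
    incomplete_stop_genes: tuple = ("COX2", "ND5")
    gtg_start_genes: tuple = ()
    accession: str = "SYN000001"
    taxon_name: str = "Synthetica exempli"

    def __post_init__(self) -> None:
        for name, val in (("genome_at_fraction", self.genome_at_fraction),
                          ("cr_at_fraction", self.cr_at_fraction)):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {val}")
        for name, val in (("j_strand_at_skew", self.j_strand_at_skew),
                          ("j_strand_gc_skew", self.j_strand_gc_skew)):
            if not -1.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [-1,1], got {val}")


@dataclass
class GroundTruth:
    """What was planted, read straight off the construction."""

    genome_length: int = 0
    junctions: list = field(default_factory=list)   # (up, down, kind, length)
    cr_tandem: list = field(default_factory=list)   # dicts: start, unit_length, copies, identity, unit
    cr_dispersed: list = field(default_factory=list)  # dicts: pos1, pos2, length
    terminals: dict = field(default_factory=dict)   # gene -> {start_codon, stop_codon, stop_complete}
    gene_coordinates: dict = field(default_factory=dict)  # gene -> (start, end, strand)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.__dict__, default=list, **kwargs)


def base_probabilities(at_fraction: float, at_skew: float = 0.0,
                       gc_skew: float = 0.0) -> np.ndarray:
    """Probabilities (A, C, G, T) realizing the target composition.

    Solves p_A+p_T = at, (p_A-p_T)/(p_A+p_T) = at_skew and the GC analogue;
    with the unit-sum constraint the four probabilities are determined.
    """
    at, gc = at_fraction, 1.0 - at_fraction
    p = np.array([
        at * (1 + at_skew) / 2,   # A
        gc * (1 - gc_skew) / 2,   # C
        gc * (1 + gc_skew) / 2,   # G
        at * (1 - at_skew) / 2,   # T
    ])
    if (p < 0).any():
        raise ValueError("skew/composition combination yields negative probabilities")
    return p


def _sample(rng: np.random.Generator, probs: np.ndarray, n: int) -> str:
    if n == 0:
        return ""
    return rng.choice(_BASES, size=n, p=probs).tobytes().decode("ascii")


def _substitute(rng: np.random.Generator, arr: np.ndarray,
                rates: np.ndarray | float) -> np.ndarray:
    """Substitute bases in place-copy at per-site ``rates`` (to a different base)."""
    out = arr.copy()
    hits = np.flatnonzero(rng.random(out.size) < rates)
    if hits.size:
        # map bases to 0..3 and shift by 1..3, guaranteeing a different base
        base_index = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            base_index[b] = i
        shift = rng.integers(1, 4, size=hits.size)
        out[hits] = _BASES[(base_index[out[hits]] + shift) % 4]
    return out


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate`` (to a different base)."""
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _substitute(rng, arr, rate).tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Gene realization
# ---------------------------------------------------------------------------

def _random_codons(rng: np.random.Generator, probs: np.ndarray, n_codons: int,
                   stops: frozenset) -> list[str]:
    out: list[str] = []
    while len(out) < n_codons:
        batch = _sample(rng, probs, 3 * (n_codons - len(out)))
        for i in range(0, len(batch), 3):
            codon = batch[i:i + 3]
            if codon not in stops:
                out.append(codon)
            if len(out) == n_codons:
                break
    return out


def _realize_pcg(rng: np.random.Generator, name: str, length: int,
                 probs: np.ndarray, incomplete_stop: bool, gtg_start: bool,
                 prefix: str = "", suffix: str = "") -> str:
    """A stop-free ORF of the requested length with optional terminal overrides.

    ``length`` must be a multiple of 3; an incomplete-stop gene is realized
    2 bp shorter, ending in a bare T completed by polyadenylation in vivo.
    """
    code = invertebrate_mito_code()
    stops = code.stop_codons
    if length % 3 != 0:
        raise ValueError(f"{name}: PCG length {length} not a multiple of 3")
    if incomplete_stop:
        body_codons = length // 3 - 1
        terminal = "T"
    else:
        body_codons = length // 3 - 1
        terminal = "TAA" if rng.random() < 0.8 else "TAG"
    start = "GTG" if gtg_start else str(rng.choice(["ATG", "ATA", "ATT"]))
    interior = _random_codons(rng, probs, body_codons - 1, stops)
    seq = list(start + "".join(interior) + terminal)
    if prefix:
        seq[:len(prefix)] = prefix
    if suffix:
        seq[len(seq) - len(suffix):] = suffix
    s = "".join(seq)
    # terminal overrides may have created an in-frame stop: patch its first
    # base (never part of our short terminal constraints) to C
    coding_end = len(s) - (1 if incomplete_stop else 3)
    chars = list(s)
    for i in range(3, coding_end - 2, 3):
        if "".join(chars[i:i + 3]) in stops:
            chars[i] = "C"
    s = "".join(chars)
    if not (s.startswith("AT") or s[:3] == "GTG"):
        raise ValueError(f"{name}: start codon {s[:3]} violates ATN/GTG after constraints")
    return s


def generate_control_region(rng: np.random.Generator | int, length: int,
                            repeats: tuple = (), dispersed: tuple = (),
                            at_fraction: float = 0.80, at_skew: float = 0.0,
                            gc_skew: float = 0.0,
                            lead: int = 150) -> tuple[str, dict]:
    """AT-rich control-region sequence with planted repeat structures.

    ``repeats`` holds (unit_length, copies, identity) tandem arrays laid
    consecutively (copies may be fractional); ``dispersed`` holds
    (length, separation) non-tandem duplicate pairs.  Planted units are
    resampled until aperiodic so the (unit, copies) description is unique.
    Returns the sequence and a ground-truth dict with CR-relative
    coordinates.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    probs = base_probabilities(at_fraction, at_skew, gc_skew)
    parts: list[str] = []
    pos = 0
    truth = {"tandem": [], "dispersed": []}

    def emit(s: str) -> None:
        nonlocal pos
        parts.append(s)
        pos += len(s)

    emit(_sample(rng, probs, lead))
    for unit_len, copies, identity in repeats:
        unit = _sample(rng, probs, unit_len)
        # avoid accidentally periodic units so (unit, copies) is unique
        while any(unit_len % d == 0 and unit == unit[:d] * (unit_len // d)
                  for d in range(1, unit_len)):
            unit = _sample(rng, probs, unit_len)
        span = int(round(unit_len * copies))
        start = pos
        array = []
        laid = 0
        first = True
        while laid < span:
            copy = unit if first else _mutate(rng, unit, 1.0 - identity)
            first = False
            take = min(unit_len, span - laid)
            array.append(copy[:take])
            laid += take
        emit("".join(array))
        truth["tandem"].append({"start": start, "unit_length": unit_len,
                                "copies": copies, "identity": identity,
                                "unit": unit})
        emit(_sample(rng, probs, 100))
    for dup_len, separation in dispersed:
        copy = _sample(rng, probs, dup_len)
        p1 = pos
        emit(copy)
        emit(_sample(rng, probs, separation))
        p2 = pos
        emit(copy)
        truth["dispersed"].append({"pos1": p1, "pos2": p2, "length": dup_len})
        emit(_sample(rng, probs, 100))
    if pos > length:
        raise ValueError(
            f"cr_length {length} too short for planted repeats ({pos} bp used)")
    emit(_sample(rng, probs, length - pos))
    return "".join(parts), truth


def _build_cr(rng: np.random.Generator, spec: GeneratorSpec,
              truth: GroundTruth) -> str:
    seq, cr_truth = generate_control_region(
        rng, spec.cr_length, repeats=spec.cr_repeats,
        dispersed=spec.cr_dispersed, at_fraction=spec.cr_at_fraction,
        at_skew=spec.j_strand_at_skew, gc_skew=spec.j_strand_gc_skew)
    truth.cr_tandem.extend(cr_truth["tandem"])
    truth.cr_dispersed.extend(cr_truth["dispersed"])
    return seq


# ---------------------------------------------------------------------------
# Whole-genome assembly
# ---------------------------------------------------------------------------

def generate(spec: GeneratorSpec) -> tuple[AnnotatedMitogenome, GroundTruth]:
    """Emit one annotated synthetic mitogenome and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    ref = load_ancestral_order()
    order = spec.gene_order or tuple(zip(ref["name"], ref["strand"]))
    kinds = dict(zip(ref["name"], ref["kind"]))
    lengths = dict(zip(ref["name"], ref["default_length_bp"].astype(int)))
    if spec.gene_lengths:
        lengths.update(spec.gene_lengths)
    lengths["CR"] = spec.cr_length

    pair_index = {(order[i][0], order[(i + 1) % len(order)][0]): i
                  for i in range(len(order))}
    gaps: dict[int, int] = {}
    motifs: dict[int, str | None] = {}
    for up, down, k in spec.planted_spacers:
        if (up, down) not in pair_index:
            raise ValueError(f"planted spacer {up}/{down}: genes not adjacent in order")
        gaps[pair_index[(up, down)]] = k
    for up, down, k, motif in spec.planted_overlaps:
        if (up, down) not in pair_index:
            raise ValueError(f"planted overlap {up}/{down}: genes not adjacent in order")
        if motif is not None and len(motif) != k:
            raise ValueError(f"overlap {up}/{down}: motif length != {k}")
        i = pair_index[(up, down)]
        if i == len(order) - 1:
            raise ValueError("overlap across the origin junction is not supported")
        gaps[i] = -k
        motifs[i] = motif

    probs_j = base_probabilities(spec.genome_at_fraction, spec.j_strand_at_skew,
                                 spec.j_strand_gc_skew)
    # coding-sense distribution for N-strand genes mirrors the J-strand one
    # (A<->T, G<->C), so the J-strand projection of every feature carries the
    # same strand skew and the whole molecule realizes the target pattern
    probs_n_cs = probs_j[[3, 2, 1, 0]]
    truth = GroundTruth()
    code = invertebrate_mito_code()

    assembled: list[str] = []
    total = 0

    def tail(k: int) -> str:
        s = "".join(assembled)
        return s[-k:] if k else ""

    features: list[GeneFeature] = []
    for i, (name, strand) in enumerate(order):
        kind = kinds.get(name, "tRNA")
        glen = int(lengths[name])
        gap_before = gaps.get(i - 1, 0) if i > 0 else 0
        # J-strand terminal constraints from the flanking junctions
        j_prefix = tail(-gap_before) if gap_before < 0 else ""
        gap_after = gaps.get(i, 0)
        j_suffix = ""
        if gap_after < 0 and motifs.get(i) is not None:
            j_suffix = motifs[i]

        if kind == "PCG":
            incomplete = name in spec.incomplete_stop_genes
            if strand == "J":
                cs_prefix, cs_suffix = j_prefix, j_suffix
            else:
                cs_prefix = reverse_complement(j_suffix) if j_suffix else ""
                cs_suffix = reverse_complement(j_prefix) if j_prefix else ""
            # an incomplete-stop gene is realized 2 bp shorter than its
            # nominal (multiple-of-3) length, ending in a bare T
            cs = _realize_pcg(rng, name,
                              glen, probs_j if strand == "J" else probs_n_cs,
                              incomplete,
                              gtg_start=name in spec.gtg_start_genes,
                              prefix=cs_prefix, suffix=cs_suffix)
            truth.terminals[name] = {
                "start_codon": cs[:3],
                "stop_codon": cs[-1] if incomplete else cs[-3:],
                "stop_complete": not incomplete,
            }
        elif kind == "CR":
            cs = _build_cr(rng, spec, truth)
        else:
            cs = _sample(rng, probs_j if strand == "J" else probs_n_cs, glen)
        j_repr = cs if strand == "J" else reverse_complement(cs)
        if j_prefix:
            j_repr = j_prefix + j_repr[len(j_prefix):]  # shared bases already emitted
        if j_suffix:
            j_repr = j_repr[:len(j_repr) - len(j_suffix)] + j_suffix

        if gap_before > 0:
            assembled.append(_sample(rng, probs_j, gap_before))
            total += gap_before
        k_ov = -gap_before if gap_before < 0 else 0
        start = total - k_ov
        if k_ov:
            if j_repr[:k_ov] != tail(k_ov):
                raise AssertionError(f"{name}: overlap constraint not realized")
            assembled.append(j_repr[k_ov:])
            total += len(j_repr) - k_ov
        else:
            assembled.append(j_repr)
            total += len(j_repr)
        end = start + len(j_repr)
        features.append(GeneFeature(name=name, start=start, end=end,
                                    strand=strand, kind=kind))
        truth.gene_coordinates[name] = (start, end, strand)

    final_gap = gaps.get(len(order) - 1, 0)
    if final_gap > 0:
        assembled.append(_sample(rng, probs_j, final_gap))
        total += final_gap

    sequence = "".join(assembled)
    truth.genome_length = len(sequence)
    for i, (name, strand) in enumerate(order):
        up = name
        down = order[(i + 1) % len(order)][0]
        g = gaps.get(i, 0)
        kind = "spacer" if g > 0 else ("overlap" if g < 0 else "abutting")
        truth.junctions.append((up, down, kind, abs(g)))

    genome = AnnotatedMitogenome(accession=spec.accession, sequence=sequence,
                                 features=features, is_circular=True,
                                 taxon_name=spec.taxon_name,
                                 metadata={"synthetic": True, "seed": spec.seed})
    # construction sanity: every PCG is a clean ORF
    for f in genome.features:
        if f.kind != "PCG":
            continue
        cs = sequence[f.start:f.end] if f.strand == "J" else \
            reverse_complement(sequence[f.start:f.end])
        usable = len(cs) - len(cs) % 3
        body = [cs[i:i + 3] for i in range(3, usable - 3, 3)]
        assert not any(c in code.stop_codons for c in body), \
            f"{f.name}: internal stop in synthetic ORF"
    return genome, truth


def generate_taxon_set(n_taxa: int, divergence: float, seed: int = 1,
                       third_position_multiplier: float = 3.0,
                       spec: GeneratorSpec | None = None,
                       ) -> list[AnnotatedMitogenome]:
    """Descendants of one synthetic ancestor under i.i.d. substitutions.

    Each taxon receives independent substitutions at ``divergence`` per
    site, with PCG third codon positions mutated at an elevated rate
    (``divergence * third_position_multiplier``, capped at 0.75) to mimic
    the saturation of third positions in deep-level comparisons.  Gene
    annotations are preserved verbatim.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    spec = spec or GeneratorSpec(seed=seed)
    ancestor, _truth = generate(spec)
    rng = np.random.default_rng(seed + 1)
    L = ancestor.length_bp

    third_pos = np.zeros(L, dtype=bool)
    for f in ancestor.features:
        if f.kind != "PCG":
            continue
        glen = f.end - f.start
        usable = glen - glen % 3
        offsets = np.arange(2, usable, 3)
        if f.strand == "J":
            third_pos[f.start + offsets] = True
        else:
            third_pos[f.end - 1 - offsets] = True

    rate3 = min(0.75, divergence * third_position_multiplier)
    rates = np.where(third_pos, rate3, divergence)
    ancestor_arr = np.frombuffer(ancestor.sequence.encode("ascii"), dtype=np.uint8)
    taxa = []
    for t in range(n_taxa):
        arr = _substitute(rng, ancestor_arr, rates)
        taxa.append(AnnotatedMitogenome(
            accession=f"SYNT{t + 1:04d}",
            sequence=arr.tobytes().decode("ascii"),
            features=[GeneFeature(f.name, f.start, f.end, f.strand, f.kind,
                                  f.wraps_origin) for f in ancestor.features],
            is_circular=True,
            taxon_name=f"Synthetica_sp_{t + 1:03d}",
            metadata={"synthetic": True, "ancestor_seed": spec.seed}))
    return taxa
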