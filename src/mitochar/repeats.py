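"""Tandem and dispersed repeat detection for the A+T-rich control region.

Phasmatodean control regions commonly carry near-identical tandem repeat
arrays (e.g. units of tens to hundreds of bp repeated 2-22 times) and
occasionally long non-tandem duplications.  Both structures are detected by
self-alignment at a candidate lag u: positions i where seq[i] == seq[i+u]
form a match profile whose long runs betray a period-u repeat.

Candidate lags are seeded by exact 8 bp matches, extended greedily in both
directions while the overall identity stays at or above the threshold, and
accepted only when (a) the span covers at least ``min_copies`` units at
``min_identity``, and (b) the observed number of matched positions is far
beyond chance for an i.i.d. sequence (one-sided binomial tail at match
probability 1/4, significance ``alpha``).  The significance filter is what
keeps short borderline periodicities in random sequence from being called
while exact biological repeats -- even a 10 bp unit duplicated once -- pass
comfortably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

from .model import AnnotatedMitogenome, gene_sequence

SEED_LEN = 8          # exact-match seed within the lag-u profile
_NULL_MATCH_P = 0.25  # i.i.d. uniform null for the significance filter


@dataclass(frozen=True)
class TandemRepeat:
    start: int           # 0-based within the scanned sequence
    unit_length: int
    copy_number: float   # fractional trailing copy allowed
    consensus_unit: str
    mean_identity: float

    @property
    def span(self) -> int:
        return int(round(self.unit_length * self.copy_number))


@dataclass(frozen=True)
class DispersedRepeatPair:
    pos1: int
    pos2: int
    length: int
    identity: float


def _to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


def _true_runs(mask: np.ndarray, min_len: int) -> list[tuple[int, int]]:
    """Maximal runs of True of at least min_len, as [start, end) pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len]


def _extend_blocks(m: np.ndarray, anchor: int, u: int,
                   min_identity: float) -> tuple[int, int, int]:
    """Block-wise extension of the lag-u match profile from a seed anchor.

    Whole unit-length blocks are appended on either side only while each
    block's own identity stays at or above the threshold, which stops the
    call from leaking into flanking non-repetitive sequence (a random
    flanking block matches far below any useful threshold).  A fractional
    trailing/leading copy is then added as the longest partial block that
    itself meets the threshold and ends on a match.  Returns
    (start, end, matches) over the aligned profile.
    """
    n = m.size
    s = e = anchor
    matches = 0
    while e + u <= n and m[e:e + u].mean() >= min_identity:
        matches += int(m[e:e + u].sum())
        e += u
    while s - u >= 0 and m[s - u:s].mean() >= min_identity:
        matches += int(m[s - u:s].sum())
        s -= u
    if e == s:  # not even one clean block: bail out
        return anchor, anchor, 0
    # partial trailing copy (rightward)
    best_t, best_mt, cnt = 0, 0, 0
    for t in range(1, min(u, n - e) + 1):
        cnt += int(m[e + t - 1])
        if m[e + t - 1] and cnt / t >= min_identity:
            best_t, best_mt = t, cnt
    e += best_t
    matches += best_mt
    # partial leading copy (leftward)
    best_t, best_mt, cnt = 0, 0, 0
    for t in range(1, min(u, s) + 1):
        cnt += int(m[s - t])
        if m[s - t] and cnt / t >= min_identity:
            best_t, best_mt = t, cnt
    s -= best_t
    matches += best_mt
    return s, e, matches


def _consensus_unit(arr: np.ndarray, start: int, unit: int, n_blocks: int) -> str:
    """Column-majority consensus over the full unit-length blocks."""
    blocks = [arr[start + k * unit: start + (k + 1) * unit] for k in range(n_blocks)]
    stack = np.stack(blocks)
    out = bytearray()
    for col in stack.T:
        vals, counts = np.unique(col, return_counts=True)
        # ties broken toward the first block's base
        best = vals[counts == counts.max()]
        pick = col[0] if col[0] in best else best[0]
        out.append(int(pick))
    return out.decode("ascii")


def _primitive_period(unit: str) -> int:
    """Smallest divisor period d of the unit such that unit = (unit[:d]) * k."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return d
    return n


def find_tandem_repeats(seq: str, min_unit: int = 10, max_unit: int = 300,
                        min_copies: float = 2.0, min_identity: float = 0.85,
                        alpha: float = 1e-6) -> list[TandemRepeat]:
    """Detect tandem repeats with unit length in [min_unit, max_unit].

    Overlapping calls across unit lengths are merged preferring larger total
    span, then smaller unit, then leftmost start; the surviving calls are
    mutually non-overlapping.  Consensus units that are themselves periodic
    are reduced to their primitive unit (with the copy number scaled up)
    when the primitive period is at least ``min_unit`` and verified in the
    sequence.  Set ``alpha=1`` to disable the significance filter.
    """
    if min_unit > max_unit:
        raise ValueError(f"min_unit ({min_unit}) exceeds max_unit ({max_unit})")
    if min_unit < 1:
        raise ValueError("min_unit must be >= 1")
    n = len(seq)
    if n < 2 * min_unit:
        return []
    arr = _to_array(seq)

    candidates: list[tuple[int, int, int, int]] = []  # (start, unit, aligned, matches)
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        m = arr[:-u] == arr[u:]
        seed = min(SEED_LEN, u * max(1, int(np.ceil(min_copies)) - 1))
        runs = _true_runs(m, min_len=min(seed, m.size))
        # longest run first: the clean core of a real array sets the block
        # phase before any chance seed in the flanks can misalign it
        runs.sort(key=lambda r: (r[0] - r[1], r[0]))
        claimed: list[tuple[int, int]] = []
        for rs, re_ in runs:
            if any(cs <= rs and re_ <= ce for cs, ce in claimed):
                continue
            s, e, matches = _extend_blocks(m, rs, u, min_identity)
            if e - s <= 0:
                continue
            claimed.append((s, e))
            candidates.append((s, u, e - s, matches))

    # reduce periodic consensus units to their primitive period, re-deriving
    # the span at the fine lag (a coarse multiple-lag call must not carry its
    # span over, or chance matches at the coarse lag inflate the copy number)
    reduced: list[tuple[int, int, int, int]] = []
    for s, u, aligned, matches in candidates:
        copies = (aligned + u) / u
        unit_str = _consensus_unit(arr, s, u, max(1, int(copies)))
        d = _primitive_period(unit_str)
        if d < u and d >= min_unit:
            md = arr[:-d] == arr[d:]
            s2, e2, matches2 = _extend_blocks(md, s, d, min_identity)
            if e2 - s2 > 0:
                s, u, aligned, matches = s2, d, e2 - s2, matches2
        reduced.append((s, u, aligned, matches))

    # filter, then merge across unit lengths: larger span first, smaller unit
    surviving = []
    for s, u, aligned, matches in reduced:
        identity = matches / aligned
        copies = (aligned + u) / u
        if copies < min_copies or identity < min_identity:
            continue
        if alpha < 1.0 and binom.sf(matches - 1, aligned, _NULL_MATCH_P) > alpha:
            continue
        surviving.append((s, u, aligned, matches, copies, identity))
    # strongest evidence first: most matched positions, then smaller unit --
    # a fine-lag call always out-matches a coarse multiple-lag call over the
    # same array, so the primitive description wins
    surviving.sort(key=lambda c: (-c[3], c[1], c[0]))

    accepted: list[TandemRepeat] = []
    taken: list[tuple[int, int]] = []
    for s, u, aligned, matches, copies, identity in surviving:
        span = aligned + u
        if any(s < te and ts < s + span for ts, te in taken):
            continue
        unit_str = _consensus_unit(arr, s, u, max(1, int(copies)))
        taken.append((s, s + span))
        accepted.append(TandemRepeat(start=s, unit_length=u,
                                     copy_number=round(copies, 1),
                                     consensus_unit=unit_str,
                                     mean_identity=identity))
    accepted.sort(key=lambda r: r.start)
    return accepted


def find_dispersed_repeats(seq: str, min_length: int = 50,
                           min_identity: float = 0.9,
                           seed_kmer: int = 12) -> list[DispersedRepeatPair]:
    """Non-tandem repeated substring pairs (exact k-mer seeds, ungapped).

    A pair whose aligned length reaches its separation would consist of
    abutting or overlapping copies; such candidates are tandem repeats and
    are excluded here.
    """
    n = len(seq)
    if n < 2 * min_length:
        return []
    arr = _to_array(seq)
    s_up = seq.upper()
    kmer_pos: dict[str, list[int]] = {}
    for i in range(n - seed_kmer + 1):
        kmer_pos.setdefault(s_up[i:i + seed_kmer], []).append(i)
    lags: set[int] = set()
    for positions in kmer_pos.values():
        if len(positions) > 1:
            for a in range(len(positions) - 1):
                for b in range(a + 1, len(positions)):
                    lags.add(positions[b] - positions[a])

    # tandem arrays self-match at every multiple of their unit; mask their
    # spans so array-internal harmonics are not reported as dispersed pairs
    tandem_spans = [(t.start, t.start + t.span)
                    for t in find_tandem_repeats(seq, min_unit=2,
                                                 max_unit=min(300, n // 2))]

    def inside_tandem(a: int, b: int) -> bool:
        return any(min(b, te) - max(a, ts) >= (b - a) / 2
                   for ts, te in tandem_spans)

    raw: list[DispersedRepeatPair] = []
    for d in sorted(lags):
        m = arr[:-d] == arr[d:]
        runs = _true_runs(m, min_len=min(seed_kmer, m.size))
        runs.sort(key=lambda r: (r[0] - r[1], r[0]))
        for rs, re_ in runs:
            s, e, matches = _extend_blocks(m, rs, seed_kmer, min_identity)
            length = e - s
            if length < min_length or matches / length < min_identity:
                continue
            if length >= d:       # abutting/overlapping copies: tandem
                continue
            if inside_tandem(s, s + length) and inside_tandem(s + d, s + d + length):
                continue
            raw.append(DispersedRepeatPair(pos1=s, pos2=s + d, length=length,
                                           identity=matches / length))
    # keep maximal, mutually non-redundant pairs (longest first)
    raw.sort(key=lambda p: (-p.length, p.pos1))
    out: list[DispersedRepeatPair] = []
    for p in raw:
        redundant = any(
            abs(p.pos1 - q.pos1) < min_length and abs(p.pos2 - q.pos2) < min_length
            for q in out)
        if not redundant:
            out.append(p)
    out.sort(key=lambda p: p.pos1)
    return out


@dataclass(frozen=True)
class RepeatReport:
    """Repeat content of one genome's control region (CR-relative coords)."""

    accession: str
    cr_present: bool
    cr_length: int
    tandem: tuple
    dispersed: tuple


def repeat_report(genome: AnnotatedMitogenome, **tandem_kwargs) -> RepeatReport:
    """Run both repeat finders on the control region of a genome."""
    cr = genome.feature_by_name("CR")
    if cr is None:
        return RepeatReport(accession=genome.accession, cr_present=False,
                            cr_length=0, tandem=(), dispersed=())
    cr_seq = gene_sequence(genome, cr)
    tandem = find_tandem_repeats(cr_seq, **tandem_kwargs)
    dispersed = find_dispersed_repeats(cr_seq)
    return RepeatReport(accession=genome.accession, cr_present=True,
                        cr_length=len(cr_seq), tandem=tuple(tandem),
                        dispersed=tuple(dispersed))
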