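"""Dispersed direct, reverse and palindromic repeat detection.

A hit is a pair of disjoint copies of length >= ``min_len`` whose Hamming
distance (after transforming the second copy) is at most
``min(max_mismatch, length // 10)``, i.e. both printed REPuter-style
constraints — an absolute mismatch cap and >=90 % identity — hold at once.
Copy transforms: direct = none, palindromic = reverse complement,
reverse = reversal without complementation.

Candidates are generated from exact seed matches whose length
``(min_len - mm) // (mm + 1)`` guarantees, by pigeonhole, that every valid
hit contains at least one seed.  Along each seed diagonal the local mismatch
profile is explored and all windows flanked by mismatches (or sequence ends)
are enumerated; a window is reported when it is valid and no one-base
extension of either end is valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dna import encode, revcomp
from .genome_io import PlastomeRecord, RegionSet, classify_location
from .quadripartite import QuadripartitePartition, canonical_orientation

REPEAT_TYPES = ("direct", "reverse", "palindromic")


@dataclass
class RepeatHit:
    type: str
    length: int
    pos1: int
    pos2: int
    mismatches: int
    location1: str = ""
    region_name1: str = ""
    location2: str = ""
    region_name2: str = ""

    def key(self) -> tuple:
        return (self.type, self.pos1, self.pos2, self.length)


@dataclass
class SharedRepeatSummary:
    per_genome_counts: dict[str, dict[str, int]]
    shared_all: int
    shared_by: dict[int, int]          # #genomes sharing -> #repeat keys
    unique_per_genome: dict[str, int]
    keys_by_genome: dict[str, set] = field(default_factory=dict)


def _allowed(length: int, max_mismatch: int) -> int:
    return min(max_mismatch, length // 10)


def _transform_b(seq: str, rtype: str) -> str:
    if rtype == "direct":
        return seq
    if rtype == "palindromic":
        return revcomp(seq)
    if rtype == "reverse":
        return seq[::-1]
    raise ValueError(rtype)


def _map_positions(rtype: str, pa: int, pb: int, L: int, n: int) -> tuple[int, int]:
    """Map a window (pa in seq, pb in transformed seq) to (pos1, pos2)."""
    if rtype == "direct":
        return pa, pb
    # for both palindromic and reverse, B[q] mirrors seq position n-1-q,
    # so a window [pb, pb+L) in B covers seq [n-pb-L, n-pb)
    return pa, n - pb - L


def find_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 3,
    max_len: int = 5000,
    types: tuple[str, ...] = REPEAT_TYPES,
) -> list[RepeatHit]:
    """Maximal dispersed repeat pairs of each requested type.

    Hits contained in a longer reported hit of the same type are suppressed;
    the genome-scale IR pair is excluded by the ``max_len`` cap.
    """
    mm_floor = _allowed(min_len, max_mismatch)
    seed = max(4, (min_len - mm_floor) // (mm_floor + 1))
    if min_len < 8:
        raise ValueError("min_len must be >= 8 (seed scheme invalid below)")
    n = len(seq)
    if n < min_len:
        return []
    ea = encode(seq)
    hits: list[RepeatHit] = []
    for rtype in types:
        bseq = _transform_b(seq, rtype)
        eb = encode(bseq)
        hits.extend(
            _find_type(seq, bseq, ea, eb, rtype, seed, min_len, max_mismatch,
                       max_len, n)
        )
    # containment suppression within type
    hits.sort(key=lambda h: (-h.length, h.pos1, h.pos2, h.type))
    kept: list[RepeatHit] = []
    for h in hits:
        contained = any(
            k.type == h.type
            and k.pos1 <= h.pos1 and h.pos1 + h.length <= k.pos1 + k.length
            and k.pos2 <= h.pos2 and h.pos2 + h.length <= k.pos2 + k.length
            for k in kept
        )
        if not contained:
            kept.append(h)
    kept.sort(key=lambda h: (h.pos1, h.pos2, h.type))
    return kept


def _seed_pairs(ea: np.ndarray, eb: np.ndarray, k: int) -> pd.DataFrame:
    mult = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)

    def codes(x: np.ndarray) -> np.ndarray:
        w = np.lib.stride_tricks.sliding_window_view(x, k).astype(np.int64)
        return w @ mult

    # windows containing N never seed (code made unique negative)
    def mask_n(x: np.ndarray, c: np.ndarray) -> np.ndarray:
        hasn = np.lib.stride_tricks.sliding_window_view(x == 4, k).any(axis=1)
        c = c.copy()
        c[hasn] = -np.arange(1, hasn.sum() + 1)
        return c

    ca = mask_n(ea, codes(ea))
    cb = mask_n(eb, codes(eb))
    da = pd.DataFrame({"code": ca, "pa": np.arange(len(ca), dtype=np.int64)})
    db = pd.DataFrame({"code": cb, "pb": np.arange(len(cb), dtype=np.int64)})
    return da.merge(db, on="code")


def _find_type(
    seq: str, bseq: str, ea: np.ndarray, eb: np.ndarray, rtype: str,
    seed: int, min_len: int, max_mismatch: int, max_len: int, n: int,
) -> list[RepeatHit]:
    pairs = _seed_pairs(ea, eb, seed)
    if pairs.empty:
        return []
    pairs["diag"] = pairs["pa"] - pairs["pb"]
    pairs = pairs.sort_values(["diag", "pa"])
    diag = pairs["diag"].to_numpy()
    pa = pairs["pa"].to_numpy()
    # collapse consecutive seeds into exact runs per diagonal
    new_run = np.ones(len(pa), dtype=bool)
    new_run[1:] = (diag[1:] != diag[:-1]) | (pa[1:] != pa[:-1] + 1)
    run_idx = np.flatnonzero(new_run)
    run_end = np.append(run_idx[1:], len(pa))
    mm_floor = _allowed(min_len, max_mismatch)
    min_exact = max(seed, (min_len - mm_floor) // (mm_floor + 1))
    nb = len(bseq)
    out: dict[tuple, RepeatHit] = {}
    for ri, re_ in zip(run_idx, run_end):
        d = int(diag[ri])
        if rtype == "direct" and d == 0:
            continue
        a0, a1 = int(pa[ri]), int(pa[re_ - 1]) + seed  # exact span [a0, a1)
        if a1 - a0 < min_exact:
            continue
        # walk left collecting up to max_mismatch+1 mismatch positions
        edges: list[int] = []
        lo = a0
        left_sentinel = None
        while True:
            if lo == 0 or lo - 1 - d < 0:
                left_sentinel = lo - 1          # hard boundary
                break
            lo -= 1
            if not _match(seq, bseq, d, lo):
                edges.append(lo)
                if len(edges) > max_mismatch:
                    break
        edges.reverse()
        n_left = len(edges)
        if left_sentinel is not None:
            edges.insert(0, left_sentinel)
        # walk right
        hi = a1
        right_sentinel = None
        n_right = 0
        while True:
            if hi >= n or hi - d >= nb:
                right_sentinel = hi             # hard boundary
                break
            if not _match(seq, bseq, d, hi):
                edges.append(hi)
                n_right += 1
                if n_right > max_mismatch:
                    hi += 1
                    break
            hi += 1
        if right_sentinel is not None:
            edges.append(right_sentinel)
        # candidate windows flanked by two edges (mismatch or boundary)
        for i in range(len(edges)):
            for j in range(i + 1, len(edges)):
                h = j - i - 1                  # mismatches strictly inside
                if h > max_mismatch:
                    break
                ws, we = edges[i] + 1, edges[j]
                L = we - ws
                if L < min_len or not _budget_ok(seq, bseq, d, ws, we, h,
                                                 max_mismatch, n, nb):
                    continue
                if _can_extend(seq, bseq, d, ws, we, h, max_mismatch, n, nb):
                    continue
                if L > max_len:
                    continue                   # genome-scale IR: discarded
                p1, p2 = _map_positions(rtype, ws, ws - d, L, n)
                p1, p2 = min(p1, p2), max(p1, p2)
                if p2 < p1 + L:
                    continue                   # overlapping copies: discarded
                hit = RepeatHit(rtype, L, p1, p2, h)
                out.setdefault(hit.key(), hit)
    return list(out.values())


def _match(seq: str, bseq: str, d: int, pos: int) -> bool:
    c = seq[pos]
    return c != "N" and c == bseq[pos - d]


def _budget_ok(seq, bseq, d, ws, we, h, max_mismatch, n, nb) -> bool:
    if ws < 0 or we > n or ws - d < 0 or we - d > nb:
        return False
    return h <= _allowed(we - ws, max_mismatch)


def _can_extend(seq, bseq, d, ws, we, h, max_mismatch, n, nb) -> bool:
    """True if a one-base extension of either end stays within budget."""
    if ws - 1 >= 0 and ws - 1 - d >= 0:
        extra = 0 if _match(seq, bseq, d, ws - 1) else 1
        if _budget_ok(seq, bseq, d, ws - 1, we, h + extra, max_mismatch, n, nb):
            return True
    if we < n and we - d < nb:
        extra = 0 if _match(seq, bseq, d, we) else 1
        if _budget_ok(seq, bseq, d, ws, we + 1, h + extra, max_mismatch, n, nb):
            return True
    return False


def strip_duplicate_ir(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> tuple[str, dict]:
    """Canonical-orientation sequence with the IRa copy removed.

    Returns (sequence LSC+IRb+SSC, metadata) where the metadata records the
    coordinate map back to the canonical full genome (here the identity on
    [0, n - ir_length)).
    """
    canon, part = canonical_orientation(record, partition)
    n = len(canon.sequence)
    cut = n - part.ir_length
    return canon.sequence[:cut], {
        "record": record.id,
        "coordinate_map": "identity into canonical orientation [0, %d)" % cut,
        "ir_length_removed": part.ir_length,
    }


def annotate_hits(
    hits: list[RepeatHit], regions: RegionSet
) -> list[RepeatHit]:
    """Attach functional-location classes to both copies of each hit."""
    for h in hits:
        h.location1, h.region_name1 = classify_location(
            (h.pos1, h.pos1 + h.length), regions
        )
        h.location2, h.region_name2 = classify_location(
            (h.pos2, h.pos2 + h.length), regions
        )
    return hits


def shared_repeat_sets(
    hits_by_genome: dict[str, list[RepeatHit]],
) -> SharedRepeatSummary:
    """Shared/unique repeat accounting across genomes.

    Repeats are keyed by (type, length, ordered pair of homologous region
    names); a key present in every genome is shared, in exactly one unique.
    """
    if len(hits_by_genome) < 2:
        raise ValueError("need >= 2 genomes")
    keys_by_genome = {
        g: {(h.type, h.length, h.region_name1, h.region_name2) for h in hits}
        for g, hits in hits_by_genome.items()
    }
    all_keys = set().union(*keys_by_genome.values())
    counts_by_key = {
        key: sum(1 for ks in keys_by_genome.values() if key in ks)
        for key in all_keys
    }
    ng = len(hits_by_genome)
    shared_by: dict[int, int] = {}
    for key, c in counts_by_key.items():
        shared_by[c] = shared_by.get(c, 0) + 1
    per_genome = {
        g: {
            t: sum(1 for h in hits if h.type == t) for t in REPEAT_TYPES
        } | {"total": len(hits)}
        for g, hits in hits_by_genome.items()
    }
    unique = {
        g: sum(1 for key in ks if counts_by_key[key] == 1)
        for g, ks in keys_by_genome.items()
    }
    return SharedRepeatSummary(
        per_genome_counts=per_genome,
        shared_all=shared_by.get(ng, 0),
        shared_by=shared_by,
        unique_per_genome=unique,
        keys_by_genome=keys_by_genome,
    )


def hits_table(genome: str, hits: list[RepeatHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome": genome, "type": h.type, "length": h.length,
                "pos1": h.pos1, "pos2": h.pos2, "mismatches": h.mismatches,
                "location1": h.location1, "region1": h.region_name1,
                "location2": h.location2, "region2": h.region_name2,
            }
            for h in hits
        ]
    )
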