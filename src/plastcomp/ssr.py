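"""Microsatellite (SSR) detection and canonical motif naming.

Only perfect tandem runs are reported, at unit-length-specific minimum unit
counts (defaults 10/6/5/4/3/3 for mono- through hexanucleotides).  A run is
reported only at its primitive (smallest) period, trimmed to whole units, and
reported loci never overlap.  Motifs are named strand-independently as
``REP/REVCOMP(REP)`` where REP is the lexicographically smallest cyclic
rotation over both strands.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._dna import revcomp
from .genome_io import RegionSet, classify_location
from .quadripartite import QuadripartitePartition

DEFAULT_THRESHOLDS = {1: 10, 2: 6, 3: 5, 4: 4, 5: 3, 6: 3}


@dataclass
class SSRLocus:
    canonical_motif: str
    unit_length: int
    repeat_count: int
    start: int
    end: int          # start + unit_length * repeat_count; may exceed genome
    location: str = ""
    region_name: str = ""
    partition: str = ""

    def __post_init__(self) -> None:
        assert self.end - self.start == self.unit_length * self.repeat_count


def _is_primitive(motif: str) -> bool:
    return motif not in (motif + motif)[1:-1]


def canonical_motif(motif: str) -> str:
    """Strand-independent canonical name, e.g. ``"T" -> "A/T"``."""
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length {len(motif)} outside 1..6")
    if not _is_primitive(motif):
        raise ValueError(
            f"motif {motif!r} is not primitive; reduce to its smallest period"
        )
    candidates = []
    for m in (motif, revcomp(motif)):
        for r in range(len(m)):
            candidates.append(m[r:] + m[:r])
    rep = min(candidates)
    return f"{rep}/{revcomp(rep)}"


def find_ssrs(
    seq: str,
    thresholds: dict[int, int] | None = None,
    circular: bool = True,
) -> list[SSRLocus]:
    """Maximal perfect tandem repeats meeting the unit-count thresholds.

    On circular sequences the scan window wraps the origin; a locus wrapping
    the origin has ``end > len(seq)`` with coordinates modulo the length.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    n = len(seq)
    if n == 0:
        return []
    ext = seq + (seq if circular else "")
    m = len(ext)
    candidates: list[SSRLocus] = []
    for u, min_units in sorted(thresholds.items()):
        i = 0
        while i + u < m:
            if ext[i] != ext[i + u] or ext[i] == "N":
                i += 1
                continue
            # maximal stretch with period u starting at i
            j = i + u
            while j < m and ext[j] == ext[j - u] and ext[j] != "N":
                j += 1
            block_len = j - i          # includes the leading unit
            count = block_len // u
            motif = ext[i : i + u]
            if (
                count >= min_units
                and _is_primitive(motif)
                and i < n
                and u * count <= n
            ):
                # reject if the block extends further left on the circle
                left = (i - 1) % n
                if not (
                    circular
                    and i == 0
                    and seq[left] == seq[(left + u) % n]
                    and seq[left] != "N"
                ):
                    candidates.append(
                        SSRLocus(
                            canonical_motif=canonical_motif(motif),
                            unit_length=u,
                            repeat_count=count,
                            start=i,
                            end=i + u * count,
                        )
                    )
            i = j - u + 1 if j - u + 1 > i else i + 1
    # non-overlap: prefer longer loci, then smaller unit, then position
    candidates.sort(
        key=lambda c: (-(c.end - c.start), c.unit_length, c.start)
    )
    chosen: list[SSRLocus] = []
    for c in candidates:
        c_ivs = _unroll(c.start, c.end, n)
        if any(
            _ivs_overlap(c_ivs, _unroll(k.start, k.end, n)) for k in chosen
        ):
            continue
        chosen.append(c)
    chosen.sort(key=lambda c: c.start)
    return chosen


def _unroll(s: int, e: int, n: int) -> list[tuple[int, int]]:
    if e <= n:
        return [(s, e)]
    return [(s, n), (0, e - n)]


def _ivs_overlap(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> bool:
    return any(
        min(e1, e2) > max(s1, s2) for s1, e1 in a for s2, e2 in b
    )


def locate_ssrs(
    loci: list[SSRLocus],
    regions: RegionSet,
    partition: QuadripartitePartition | None = None,
) -> list[SSRLocus]:
    """Attach location class, region name and LSC/SSC/IR partition."""
    n = regions.genome_length
    for locus in loci:
        iv = (locus.start, min(locus.end, n))
        locus.location, locus.region_name = classify_location(iv, regions)
        if partition is not None:
            locus.partition = _partition_of(locus, partition)
    return loci


def _partition_of(locus: SSRLocus, part: QuadripartitePartition) -> str:
    n = part.genome_length
    mid = ((locus.start + locus.end) // 2) % n
    for name, iv in (("LSC", part.lsc), ("SSC", part.ssc),
                     ("IR", part.irb), ("IR", part.ira)):
        s, e = iv
        if (s <= mid < e) if e > s else (mid >= s or mid < e):
            return name
    return "?"


def ssr_summary(loci: list[SSRLocus]) -> pd.DataFrame:
    """Counts per canonical motif by location class and partition.

    One row per canonical motif with a total and
    per-location / per-partition columns (both IR copies counted).
    """
    loc_classes = ["Intron", "IGS", "CDS-IGS", "CDS"]
    parts = ["LSC", "SSC", "IR"]
    rows = {}
    for locus in loci:
        row = rows.setdefault(
            locus.canonical_motif,
            {"motif": locus.canonical_motif, "Number": 0,
             **{c: 0 for c in loc_classes}, **{p: 0 for p in parts},
             "other_location": 0},
        )
        row["Number"] += 1
        loc = {"intron": "Intron"}.get(locus.location, locus.location)
        if loc in loc_classes:
            row[loc] += 1
        else:
            row["other_location"] += 1
        if locus.partition in parts:
            row[locus.partition] += 1
    df = pd.DataFrame(list(rows.values()))
    if df.empty:
        df = pd.DataFrame(
            columns=["motif", "Number", *loc_classes, *parts, "other_location"]
        )
    return df.sort_values("motif").reset_index(drop=True)
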