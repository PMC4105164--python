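"""Substitution / indel event counting, S/I ratios, length spectra, the
per-region variability statistic and divergence-hotspot screening.

An indel event is one maximal run of gap columns with a constant gapped-row
pattern: it counts once regardless of length.  Substitution columns are typed
by unordered base pair; columns containing N are excluded from substitution
counting but remain in the aligned length L.  The region variability
statistic is (NS + ID) / L x 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .alignment import Alignment, Scoring, align_multi, align_pair
from .genome_io import PlastomeRecord, RegionSet, extract_functional_regions
from .quadripartite import QuadripartitePartition, detect_quadripartite

BASE_PAIRS = [
    frozenset(p) for p in (("A", "C"), ("A", "G"), ("A", "T"),
                           ("C", "G"), ("C", "T"), ("G", "T"))
]

SPECTRUM_BINS = ("1", "2", "3-4", "5-6", "7-10", ">10")


@dataclass
class IndelEvent:
    length: int
    column_start: int
    bearer: tuple[int, ...]   # indices of the gapped rows
    terminal: bool = False


@dataclass
class PairwiseDivergence:
    labels: tuple[str, str]
    substitutions: int
    subs_by_type: dict[frozenset, int]
    indel_events: list[IndelEvent]
    aligned_length: int

    @property
    def indels(self) -> int:
        return len(self.indel_events)

    @property
    def si(self) -> float:
        return si_ratio(self.substitutions, self.indels)


@dataclass
class RegionVariability:
    name: str
    category: str             # "coding" | "non-coding"
    ns: int
    id_: int
    aligned_length: int

    @property
    def variability_percent(self) -> float:
        if self.aligned_length == 0:
            return 0.0
        v = 100.0 * (self.ns + self.id_) / self.aligned_length
        assert 0.0 <= v <= 100.0
        return v


def _gap_blocks(aln: Alignment, exclude_terminal: bool) -> list[IndelEvent]:
    """Maximal column runs with a constant, non-empty gapped-row pattern."""
    L = aln.aligned_length
    patterns = [
        tuple(r for r, row in enumerate(aln.rows) if row[c] == "-")
        for c in range(L)
    ]
    events: list[IndelEvent] = []
    c = 0
    while c < L:
        if not patterns[c]:
            c += 1
            continue
        start = c
        while c < L and patterns[c] == patterns[start]:
            c += 1
        terminal = start == 0 or c == L
        events.append(IndelEvent(c - start, start, patterns[start], terminal))
    if exclude_terminal:
        events = [e for e in events if not e.terminal]
    return events


def count_events(
    aln: Alignment, exclude_terminal_gaps: bool = True
) -> PairwiseDivergence:
    """Substitution and indel events of a two-row alignment."""
    if len(aln.rows) != 2:
        raise ValueError("count_events is pairwise; use count_events_multi")
    r1, r2 = aln.rows
    by_type = {p: 0 for p in BASE_PAIRS}
    ns = 0
    for c1, c2 in zip(r1, r2):
        if c1 in "ACGT" and c2 in "ACGT" and c1 != c2:
            by_type[frozenset((c1, c2))] += 1
            ns += 1
    events = _gap_blocks(aln, exclude_terminal_gaps)
    return PairwiseDivergence(
        labels=(aln.labels[0], aln.labels[1]),
        substitutions=ns,
        subs_by_type=by_type,
        indel_events=events,
        aligned_length=aln.aligned_length,
    )


def count_events_multi(
    aln: Alignment, exclude_terminal_gaps: bool = True
) -> tuple[int, int]:
    """(NS, ID) for a multi-row alignment.

    NS counts columns with >= 2 distinct non-gap, non-N bases; ID counts
    distinct maximal gap blocks (identical column span and row membership).
    """
    ns = 0
    for c in range(aln.aligned_length):
        bases = {row[c] for row in aln.rows} & set("ACGT")
        if len(bases) >= 2:
            ns += 1
    return ns, len(_gap_blocks(aln, exclude_terminal_gaps))


def si_ratio(ns: int, id_: int) -> float:
    """S/I ratio, reported to 2 decimals."""
    if id_ <= 0:
        raise ZeroDivisionError("S/I undefined when the indel count is zero")
    return round(ns / id_, 2)


def indel_length_spectrum(events: list[IndelEvent]) -> pd.DataFrame:
    """Counts and fractions of indel events per length bin."""
    counts = dict.fromkeys(SPECTRUM_BINS, 0)
    for e in events:
        if e.length == 1:
            b = "1"
        elif e.length == 2:
            b = "2"
        elif e.length <= 4:
            b = "3-4"
        elif e.length <= 6:
            b = "5-6"
        elif e.length <= 10:
            b = "7-10"
        else:
            b = ">10"
        counts[b] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "bin": list(SPECTRUM_BINS),
            "count": [counts[b] for b in SPECTRUM_BINS],
            "fraction": [
                counts[b] / total if total else 0.0 for b in SPECTRUM_BINS
            ],
        }
    )


def variability_percent(
    aln: Alignment, name: str = "", category: str = "non-coding"
) -> RegionVariability:
    """The proportion-of-mutational-events statistic for one region."""
    ns, id_ = count_events_multi(aln)
    return RegionVariability(
        name=name, category=category, ns=ns, id_=id_,
        aligned_length=aln.aligned_length,
    )


def screen_markers(
    variabilities: list[RegionVariability],
    threshold: float = 1.5,
    category: str = "non-coding",
) -> list[RegionVariability]:
    """Regions of the category with variability strictly above the threshold,
    most variable first."""
    hits = [
        v for v in variabilities
        if v.category == category and v.variability_percent > threshold
    ]
    return sorted(hits, key=lambda v: -v.variability_percent)


# ---------------------------------------------------------------------------
# region-wise comparative machinery


@dataclass
class GenomeContext:
    """A genome with its regions and quadripartite partition precomputed."""

    record: PlastomeRecord
    regions: RegionSet
    partition: QuadripartitePartition | None

    @classmethod
    def build(cls, record: PlastomeRecord, min_ir: int = 10000,
              detect_partition: bool = True) -> "GenomeContext":
        part = detect_quadripartite(record, min_ir) if detect_partition else None
        return cls(record, extract_functional_regions(record), part)

    def region_sequences(self) -> dict[str, tuple[str, str]]:
        """region name -> (category, sequence); multi-interval regions are
        concatenated in genome order."""
        out = {}
        seq = self.record.sequence
        for name, cat, ivs in self.regions.regions:
            s = "".join(seq[a:b] for a, b in ivs)
            if s:
                out[name] = (cat, s)
        return out

    def partition_of(self, name: str) -> str:
        if self.partition is None:
            return "?"
        ivs = dict((n, iv) for n, _, iv in self.regions.regions)[name]
        mid = (ivs[0][0] + ivs[0][1]) // 2
        p = self.partition
        n = p.genome_length
        for pname, iv in (("LSC", p.lsc), ("SSC", p.ssc),
                          ("IR", p.irb), ("IR", p.ira)):
            s, e = iv
            inside = (s <= mid < e) if e > s else (mid >= s or mid < e)
            if inside:
                return pname
        return "?"


CODING_CATEGORIES = {"CDS", "tRNA", "rRNA"}


def region_category(cat: str) -> str:
    return "coding" if cat in CODING_CATEGORIES else "non-coding"


# per-process cache: aligning all homologous regions of a genome pair is the
# pipeline's hot spot and several stages need the same pair
_PAIR_CACHE: dict[tuple[int, int], pd.DataFrame] = {}


def pairwise_region_divergence(
    ctx_a: GenomeContext, ctx_b: GenomeContext,
    scoring: Scoring | None = None,
) -> pd.DataFrame:
    """Align homologous named regions of two genomes and count events.

    Input order does not matter: sequences are canonicalised before
    alignment, so the result is symmetric.
    """
    cache_key = (min(id(ctx_a), id(ctx_b)), max(id(ctx_a), id(ctx_b)),
                 id(scoring))
    if scoring is None and cache_key in _PAIR_CACHE:
        return _PAIR_CACHE[cache_key]
    ra = ctx_a.region_sequences()
    rb = ctx_b.region_sequences()
    rows = []
    for name in sorted(set(ra) & set(rb)):
        cat, sa = ra[name]
        _, sb = rb[name]
        swap = sa > sb
        aln = align_pair(*((sb, sa) if swap else (sa, sb)), scoring=scoring)
        div = count_events(aln)
        rows.append(
            {
                "region": name,
                "category": cat,
                "functional": region_category(cat),
                "partition": ctx_a.partition_of(name),
                "ns": div.substitutions,
                "id": div.indels,
                "aligned_length": div.aligned_length,
                "indel_lengths": tuple(
                    e.length for e in div.indel_events
                ),
                "subs_by_type": {
                    "".join(sorted(k)): v for k, v in div.subs_by_type.items()
                },
            }
        )
    df = pd.DataFrame(rows)
    if scoring is None:
        _PAIR_CACHE[cache_key] = df
    return df


def genome_pairwise_divergence(
    ctx_a: GenomeContext, ctx_b: GenomeContext,
) -> dict:
    """Whole-genome NS/ID/S-I via annotation-guided region-wise summation."""
    df = pairwise_region_divergence(ctx_a, ctx_b)
    ns = int(df["ns"].sum())
    id_ = int(df["id"].sum())
    lengths = [l for t in df["indel_lengths"] for l in t]
    return {
        "pair": (ctx_a.record.id, ctx_b.record.id),
        "ns": ns,
        "id": id_,
        "si": si_ratio(ns, id_) if id_ else float("nan"),
        "indel_lengths": lengths,
        "aligned_length": int(df["aligned_length"].sum()),
    }


def divergence_matrix(contexts: list[GenomeContext]) -> pd.DataFrame:
    """Pairwise matrix: substitutions (S/I) below the diagonal, indel counts
    above, the conventional layout for such matrices."""
    ids = [c.record.id for c in contexts]
    mat = pd.DataFrame("", index=ids, columns=ids)
    for (i, ca), (j, cb) in combinations(enumerate(contexts), 2):
        d = genome_pairwise_divergence(ca, cb)
        mat.iloc[j, i] = f"{d['ns']} ({d['si']:.2f})"
        mat.iloc[i, j] = str(d["id"])
        mat.iloc[i, i] = "/"
        mat.iloc[j, j] = "/"
    return mat


def region_variabilities(
    contexts: list[GenomeContext],
) -> list[RegionVariability]:
    """Variability of every region shared by all genomes (multi-alignment)."""
    seq_maps = [c.region_sequences() for c in contexts]
    shared = sorted(set.intersection(*(set(m) for m in seq_maps)))
    out = []
    for name in shared:
        cat = seq_maps[0][name][0]
        seqs = {
            c.record.id: m[name][1] for c, m in zip(contexts, seq_maps)
        }
        aln = align_multi(seqs)
        out.append(
            variability_percent(aln, name=name, category=region_category(cat))
        )
    return out


def partition_divergence_ratios(
    contexts: list[GenomeContext], focal: str, mode: str = "functional",
) -> tuple[dict[str, float], dict[str, float]]:
    """Divergence ratios between genome compartments for one focal genome.

    mode="functional": CDS : intron : IGS.  mode="positional": IR : LSC : SSC.
    Per partner genome, divergence of a compartment is (NS+ID)/L summed over
    its regions; partner values are averaged and normalised so the first
    compartment equals 1 (ratios reported to 1 decimal).
    Returns (raw mean divergence per compartment, normalised ratios).
    """
    if mode == "functional":
        groups = {"CDS": ("CDS",), "intron": ("intron",), "IGS": ("IGS",)}
        group_of = lambda row: next(
            (g for g, cats in groups.items() if row["category"] in cats), None
        )
        order = ["CDS", "intron", "IGS"]
    elif mode == "positional":
        group_of = lambda row: row["partition"] if row["partition"] in (
            "IR", "LSC", "SSC") else None
        order = ["IR", "LSC", "SSC"]
    else:
        raise ValueError(mode)
    focal_ctx = next(c for c in contexts if c.record.id == focal)
    partners = [c for c in contexts if c.record.id != focal]
    if not partners:
        raise ValueError("need at least one partner genome")
    sums: dict[str, list[float]] = {g: [] for g in order}
    for partner in partners:
        df = pairwise_region_divergence(focal_ctx, partner)
        ev = {g: 0 for g in order}
        ln = {g: 0 for g in order}
        for _, row in df.iterrows():
            g = group_of(row)
            if g is None:
                continue
            ev[g] += row["ns"] + row["id"]
            ln[g] += row["aligned_length"]
        for g in order:
            if ln[g]:
                sums[g].append(ev[g] / ln[g])
    mean = {g: (sum(v) / len(v) if v else 0.0) for g, v in sums.items()}
    base = mean[order[0]]
    if base == 0:
        raise ZeroDivisionError(
            f"zero divergence in normalising compartment {order[0]!r}"
        )
    ratios = {g: round(mean[g] / base, 1) for g in order}
    return mean, ratios
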