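"""Synthetic annotated quadripartite plastomes and their evolution along a
tree, with full ground-truth tables for every downstream analysis stage.

The ancestor generator plants, at configurable scale: a quadripartite layout
(defaults ~157 kb: LSC 86.6 kb, SSC 18.3 kb, IR 26.1 kb) with IRb exactly the
reverse complement of IRa; an annotated gene set with introns, two-intron
genes, overlapping gene pairs, IR-duplicated genes and a ycf1 analog spanning
the SSC/IRa junction; AT-rich background at a target GC; SSR loci dominated
by A/T mononucleotides; and dispersed repeats in single-copy regions.

Evolution applies substitutions (two-rate transition/transversion scheme),
indel events with a 1-bp-dominated length mixture in which insertions mostly
duplicate the adjacent upstream sequence, and SSR slippage, at region rates
that make the IR evolve more slowly than the single-copy regions.  With
concerted evolution enabled, every IR mutation is mirrored into the other
copy, so IRa = revcomp(IRb) holds at every tip.  All events are recorded so
that replaying the truth table against the ancestor reproduces each tip
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dataclasses_replace
from pathlib import Path

import dendropy
import numpy as np

from ._dna import complement, revcomp
from .genome_io import (
    Feature,
    PlastomeRecord,
    write_fasta,
    write_genbank,
)

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

# real plastid gene names, used in layout order so synthetic annotations read
# like genuine ones
_LSC_PROTEIN = [
    "psbA", "matK", "rps16", "psbK", "psbI", "atpA", "atpF", "atpH", "atpI",
    "rps2", "rpoC2", "rpoC1", "rpoB", "petN", "psbM", "psbD", "psbC", "psbZ",
    "rps14", "psaB", "psaA", "ycf3", "rps4", "ndhJ", "ndhK", "ndhC", "atpE",
    "atpB", "rbcL", "accD", "psaI", "ycf4", "cemA", "petA", "psbJ", "psbL",
    "psbF", "psbE", "petL", "petG", "psaJ", "rpl33", "rps18", "rpl20",
    "rps12", "clpP", "psbB", "psbT", "psbN", "psbH", "petB", "petD", "rpoA",
    "rps11", "rpl36", "infA", "rps8", "rpl14", "rpl16", "rps3", "rpl22",
    "rps19",
]
_LSC_TRNA = [
    "trnH-GUG", "trnK-UUU", "trnQ-UUG", "trnS-GCU", "trnG-GCC", "trnR-UCU",
    "trnC-GCA", "trnD-GUC", "trnY-GUA", "trnE-UUC", "trnT-GGU", "trnS-UGA",
    "trnG-UCC", "trnfM-CAU", "trnS-GGA", "trnT-UGU", "trnL-UAA", "trnF-GAA",
    "trnV-UAC", "trnM-CAU", "trnW-CCA", "trnP-UGG",
]
_IR_GENES = [
    ("rpl2", "CDS"), ("rpl23", "CDS"), ("trnI-CAU", "tRNA"),
    ("ycf2", "CDS"), ("trnL-CAA", "tRNA"), ("ndhB", "CDS"),
    ("rps7", "CDS"), ("trnV-GAC", "tRNA"), ("rrn16", "rRNA"),
    ("trnI-GAU", "tRNA"), ("trnA-UGC", "tRNA"), ("rrn23", "rRNA"),
    ("rrn4.5", "rRNA"), ("rrn5", "rRNA"), ("trnR-ACG", "tRNA"),
    ("trnN-GUU", "tRNA"), ("ycf15", "CDS"),
]
_SSC_PROTEIN = [
    "ndhF", "rpl32", "ccsA", "ndhD", "psaC", "ndhE", "ndhG", "ndhI",
    "ndhA", "ndhH", "rps15",
]
_SSC_TRNA = ["trnL-UAG"]
_INTRON_GENES = {
    "rps16", "atpF", "rpoC1", "ycf3", "clpP", "petB", "petD", "rpl16",
    "rpl2", "ndhB", "ndhA", "trnK-UUU", "trnG-GCC", "trnL-UAA", "trnV-UAC",
    "trnI-GAU", "trnA-UGC", "trnL-CAA",
}
_TWO_INTRON = {"ycf3", "clpP"}

SPECTRUM_BIN_RANGES = {
    "1": (1, 1), "2": (2, 2), "3-4": (3, 4), "5-6": (5, 6),
    "7-10": (7, 10), ">10": (11, 20),
}


@dataclass
class AncestorConfig:
    """Layout of the synthetic ancestral plastome (defaults ~157 kb)."""

    lsc_len: int = 86600
    ssc_len: int = 18280
    ir_len: int = 26090
    gc_fraction: float = 0.373
    gene_density: float = 0.55      # fraction of each partition that is genic
    ycf1_ir_overlap: int = 1068     # bp of the ycf1 analog inside IRa
    # (capped at ir_len // 4 for scaled-down genomes at build time)
    n_ssr_mono: int = 40            # planted A/T mononucleotide loci
    n_ssr_hexa: int = 2
    n_repeats: int = 8              # planted dispersed repeats (single-copy)
    with_genes: bool = True
    seed: int = 0

    @property
    def genome_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len


@dataclass
class EvolutionConfig:
    """Evolution along a tree (branch lengths = expected substitutions/site
    in the fastest compartment class before region multipliers)."""

    tree: str                                 # newick with branch lengths
    indel_to_sub_ratio: float = 1.0 / 3.0     # per Table-5-like S/I of ~3
    indel_length_mix: dict[str, float] = field(
        default_factory=lambda: {
            "1": 0.45, "2": 0.08, "3-4": 0.10, "5-6": 0.22,
            "7-10": 0.10, ">10": 0.05,
        }
    )
    adjacent_duplication_fraction: float = 0.8
    region_multipliers: dict[str, float] = field(
        default_factory=lambda: {"IR": 1.0, "LSC": 3.0, "SSC": 3.0}
    )
    kappa: float = 2.0                        # transition/transversion bias
    ir_concerted: bool = True
    ssr_slippage_rate: float = 0.05           # per locus per unit branch length
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.indel_length_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel length mixture must sum to 1")


@dataclass
class PlantedSSR:
    motif: str
    start: int
    count: int
    partition: str


@dataclass
class PlantedRepeat:
    type: str
    length: int
    pos1: int
    pos2: int          # coordinates on the IR-stripped (LSC+IRb+SSC) sequence
    mismatches: int


@dataclass
class TruthTable:
    config: AncestorConfig
    boundaries: tuple[int, int, int, int]     # JLB, JSB, JSA, genome end
    planted_ssrs: list[PlantedSSR] = field(default_factory=list)
    planted_repeats: list[PlantedRepeat] = field(default_factory=list)
    gene_counts: dict[str, int] = field(default_factory=dict)
    branch_events: dict[tuple[str, str], list[tuple]] = field(
        default_factory=dict
    )
    tip_boundaries: dict[str, tuple[int, int, int, int]] = field(
        default_factory=dict
    )
    tip_records: dict[str, PlastomeRecord] = field(default_factory=dict)
    tree: "dendropy.Tree | None" = None


# ---------------------------------------------------------------------------
# ancestor construction


def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    """Random bases at the target GC with homopolymer runs capped at 8."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=n, p=p)
    # break runs of length >= 9 by resampling every 9th position of a run
    for _ in range(10):
        same = np.flatnonzero(
            np.convolve(
                np.concatenate([[1], (arr[1:] == arr[:-1]).astype(int)]),
                np.ones(9, dtype=int), mode="valid",
            ) == 9
        )
        if len(same) == 0:
            break
        for pos in same + 8:
            choices = [b for b in range(4) if b != arr[pos]]
            arr[pos] = rng.choice(choices)
    return arr


def _layout_partition(
    rng: np.random.Generator,
    part_len: int,
    entries: list[tuple[str, str]],      # (name, feature kind)
    density: float,
) -> list[dict]:
    """Place genes left to right with random spacers; returns layout dicts."""
    if not entries:
        return []
    budget = int(part_len * density)
    lens = {}
    for name, kind in entries:
        if kind == "tRNA":
            # intron-bearing tRNAs span their (sometimes kilobase) intron
            lens[name] = (int(rng.integers(700, 2600))
                          if name in _INTRON_GENES
                          else int(rng.integers(72, 91)))
        elif kind == "rRNA":
            lens[name] = int(rng.integers(1200, 2900))
        else:
            lens[name] = int(rng.integers(250, 1600))
    scale = budget / max(1, sum(lens.values()))
    if scale < 1.0:
        lens = {k: max(60, int(v * scale)) for k, v in lens.items()}
    total_genes = sum(lens.values())
    # overlapping pairs share sequence, freeing a little space
    overlaps = {}
    names = [n for n, _ in entries]
    for a, b, ov in (("psbD", "psbC", 52), ("atpB", "atpE", 3)):
        if a in names and b in names and names.index(b) == names.index(a) + 1:
            overlaps[b] = min(ov, lens[a] - 1, lens[b] - 1)
    total_genes -= sum(overlaps.values())
    free = part_len - total_genes
    n_gaps = len(entries) + 1
    if free < n_gaps * 20:
        raise ValueError(
            f"gene plan overflow: {total_genes} bp of genes in a "
            f"{part_len} bp partition"
        )
    gaps = rng.multinomial(free - n_gaps * 20, np.ones(n_gaps) / n_gaps) + 20
    layout = []
    pos = int(gaps[0])
    for idx, (name, kind) in enumerate(entries):
        if name in overlaps:
            pos -= overlaps[name] + int(gaps[idx])  # overlap previous gene
        start = pos
        end = start + lens[name]
        n_introns = (
            2 if name in _TWO_INTRON
            else 1 if name in _INTRON_GENES
            else 0
        )
        layout.append(
            {
                "name": name, "kind": kind, "start": start, "end": end,
                "strand": "+" if rng.random() < 0.5 else "-",
                "n_introns": n_introns,
            }
        )
        pos = end + int(gaps[idx + 1])
    return layout


def _exon_intervals(
    rng: np.random.Generator, start: int, end: int, n_introns: int, strand: str
) -> list[tuple[int, int, str]]:
    length = end - start
    if n_introns == 0 or length < 150:
        return [(start, end, strand)]
    cuts = sorted(
        int(c) for c in rng.integers(40, length - 40, size=2 * n_introns)
    )
    while len(set(cuts)) < 2 * n_introns or min(
        b - a for a, b in zip(cuts, cuts[1:])
    ) < 20:
        cuts = sorted(
            int(c) for c in rng.integers(40, length - 40, size=2 * n_introns)
        )
    ivs = []
    prev = start
    for k in range(n_introns):
        ivs.append((prev, start + cuts[2 * k], strand))
        prev = start + cuts[2 * k + 1]
    ivs.append((prev, end, strand))
    return ivs


def make_ancestor(
    config: AncestorConfig | None = None,
) -> tuple[PlastomeRecord, TruthTable]:
    """Build the annotated ancestral plastome and its truth table."""
    cfg = config or AncestorConfig()
    if cfg.ycf1_ir_overlap >= cfg.ir_len // 4:
        cfg = dataclasses_replace(cfg, ycf1_ir_overlap=cfg.ir_len // 4)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.genome_length
    b1, b2, b3 = cfg.lsc_len, cfg.lsc_len + cfg.ir_len, \
        cfg.lsc_len + cfg.ir_len + cfg.ssc_len

    sc_len = cfg.lsc_len + cfg.ir_len + cfg.ssc_len   # LSC+IRb+SSC
    arr = _background(rng, sc_len, cfg.gc_fraction)

    truth = TruthTable(config=cfg, boundaries=(b1, b2, b3, n))

    # ---- gene layout ------------------------------------------------------
    features: list[Feature] = []
    if cfg.with_genes:
        scale_l = cfg.lsc_len / 86600
        scale_s = cfg.ssc_len / 18280
        scale_i = cfg.ir_len / 26090
        lsc_names = _interleave(
            _take(_LSC_PROTEIN, max(2, round(len(_LSC_PROTEIN) * scale_l))),
            _take(_LSC_TRNA, round(len(_LSC_TRNA) * scale_l)),
        )
        ssc_names = _interleave(
            _take(_SSC_PROTEIN, max(1, round(len(_SSC_PROTEIN) * scale_s))),
            _take(_SSC_TRNA, round(len(_SSC_TRNA) * scale_s)),
        )
        ir_entries = [
            (nm, kd) for nm, kd in
            _take(_IR_GENES, max(1, round(len(_IR_GENES) * scale_i)))
        ]
        lsc_layout = _layout_partition(rng, cfg.lsc_len, lsc_names,
                                       cfg.gene_density)
        irb_layout = _layout_partition(rng, cfg.ir_len, ir_entries,
                                       cfg.gene_density)
        ycf1_ssc_part = (min(4500, cfg.ssc_len // 4)
                         if 0 < cfg.ycf1_ir_overlap < cfg.ir_len else 0)
        ssc_layout = _layout_partition(
            rng, cfg.ssc_len - ycf1_ssc_part - 60, ssc_names,
            cfg.gene_density,
        )
        for g in lsc_layout:
            _add_gene(features, rng, g, offset=0, copy_tag=None)
        for g in irb_layout:
            _add_gene(features, rng, g, offset=b1, copy_tag="IRb")
        for g in ssc_layout:
            _add_gene(features, rng, g, offset=b2, copy_tag=None)
        # ycf1 analog: starts in SSC, runs ycf1_ir_overlap bp into IRa
        if 0 < cfg.ycf1_ir_overlap < cfg.ir_len:
            y_start = b3 - ycf1_ssc_part
            y_end = b3 + cfg.ycf1_ir_overlap
            strand = "-"
            features.append(
                Feature("ycf1", "gene", [(y_start, y_end, strand)])
            )
            features.append(
                Feature("ycf1", "CDS", [(y_start, y_end, strand)])
            )
        # IRa duplicates of IRb genes (mirrored coordinates)
        for f in [f for f in features if f.copy_tag == "IRb"]:
            mirrored = sorted(
                (b3 + cfg.ir_len - (e - b1), b3 + cfg.ir_len - (s - b1),
                 "-" if st == "+" else "+")
                for s, e, st in f.intervals
            )
            features.append(Feature(f.name, f.kind, mirrored, "IRa"))

    # ---- planted SSRs (single-copy + IRb; IRa mirrors them) --------------
    occupied = _occupied_map(features, sc_len)
    for _ in range(cfg.n_ssr_mono):
        count = int(rng.integers(10, 15))
        _plant_ssr(rng, arr, occupied, "A" if rng.random() < 0.5 else "T",
                   count, truth, (b1, b2, b3))
    for _ in range(cfg.n_ssr_hexa):
        motif = "AAAAAG" if rng.random() < 0.5 else "CTTTTT"
        _plant_ssr(rng, arr, occupied, motif, 3, truth, (b1, b2, b3))

    # ---- planted dispersed repeats (LSC and SSC only) ---------------------
    for _ in range(cfg.n_repeats):
        _plant_repeat(rng, arr, occupied, truth, (b1, b2, b3))

    # ---- assemble circle: LSC + IRb + SSC + IRa = revcomp(IRb) -----------
    seq_sc = "".join(BASES[arr])
    ira = revcomp(seq_sc[b1:b2])
    seq = list(seq_sc + ira)
    # junction guards (all four guard bases lie in single-copy sequence):
    # extension of the IR match past JLB would pair the last LSC base with the
    # first genome base; past JSB it would pair the first and last SSC bases
    if seq[b1 - 1] == complement(seq[0]):
        seq[b1 - 1] = _other(seq[b1 - 1], seq[0])
    if seq[b2] == complement(seq[b3 - 1]):
        seq[b2] = _other(seq[b2], seq[b3 - 1])
    sequence = "".join(seq)

    record = PlastomeRecord(
        id=f"ancestor-seed{cfg.seed}", sequence=sequence, circular=True,
        features=features, source="synthetic",
    )
    census = {"total": len(record.genes())}
    for f in record.genes():
        kind = ("trna" if f.name.startswith("trn")
                else "rrna" if f.name.startswith("rrn") else "protein")
        census[kind] = census.get(kind, 0) + 1
    truth.gene_counts = census
    return record, truth


def _take(lst, k):
    return lst[: max(0, min(len(lst), k))]


def _interleave(proteins, trnas):
    out = [(p, "CDS") for p in proteins]
    step = max(1, len(out) // (len(trnas) + 1)) if trnas else 1
    for i, t in enumerate(trnas):
        out.insert(min(len(out), (i + 1) * step + i), (t, "tRNA"))
    return out


def _add_gene(features, rng, g, offset, copy_tag):
    start, end = g["start"] + offset, g["end"] + offset
    features.append(
        Feature(g["name"], "gene", [(start, end, g["strand"])], copy_tag)
    )
    ivs = _exon_intervals(rng, start, end, g["n_introns"], g["strand"])
    features.append(Feature(g["name"], g["kind"], ivs, copy_tag))


def _occupied_map(features: list[Feature], n: int) -> np.ndarray:
    occ = np.zeros(n, dtype=bool)
    for f in features:
        for s, e, _ in f.intervals:
            if s < n:
                occ[s : min(e, n)] = True
    return occ


def _free_slot(rng, occupied, length, lo, hi, margin=4):
    for _ in range(200):
        p = int(rng.integers(lo + margin, max(lo + margin + 1,
                                              hi - length - margin)))
        if not occupied[p - margin : p + length + margin].any():
            return p
    return None


def _partition_name(pos: int, b1: int, b2: int, b3: int) -> str:
    return "LSC" if pos < b1 else "IR" if pos < b2 else "SSC"


def _plant_ssr(rng, arr, occupied, motif, count, truth, bounds):
    b1, b2, b3 = bounds
    L = len(motif) * count
    lo, hi = (0, b1) if rng.random() < 0.75 else (
        (b2, b3) if rng.random() < 0.5 else (b1, b2)
    )
    p = _free_slot(rng, occupied, L, lo, hi)
    if p is None:
        log.warning("no free slot for SSR %s x%d", motif, count)
        return
    unit = np.array([("ACGT".index(c)) for c in motif])
    arr[p : p + L] = np.tile(unit, count)
    u = len(motif)
    # guards: the run must not extend by a unit at either end
    if arr[p - 1] == arr[p - 1 + u]:
        arr[p - 1] = (arr[p - 1 + u] + 1 + int(rng.integers(3))) % 4
    if arr[p + L] == arr[p + L - u]:
        arr[p + L] = (arr[p + L - u] + 1 + int(rng.integers(3))) % 4
    occupied[p - 1 : p + L + 1] = True
    truth.planted_ssrs.append(
        PlantedSSR(motif, p, count, _partition_name(p, b1, b2, b3))
    )


def _plant_repeat(rng, arr, occupied, truth, bounds):
    b1, b2, b3 = bounds
    rtype = ("direct", "reverse", "palindromic")[int(rng.integers(3))]
    L = int(rng.integers(30, 61))
    mm = int(rng.integers(0, 3))
    copy1 = rng.integers(0, 4, size=L)
    copy2 = copy1.copy()
    if rtype == "palindromic":
        copy2 = 3 - copy2[::-1]
    elif rtype == "reverse":
        copy2 = copy2[::-1]
    for q in rng.choice(L, size=mm, replace=False):
        copy2[q] = (copy2[q] + 1 + int(rng.integers(3))) % 4
    # both copies in single-copy regions (first in LSC, second in LSC or SSC)
    p1 = _free_slot(rng, occupied, L, 0, b1)
    if p1 is None:
        log.warning("no free slot for planted repeat")
        return
    occupied[p1 : p1 + L] = True
    lo2, hi2 = (0, b1) if rng.random() < 0.6 else (b2, b3)
    p2 = _free_slot(rng, occupied, L, lo2, hi2)
    if p2 is None:
        log.warning("no free slot for planted repeat")
        return
    if p2 < p1:
        # the pair relations are symmetric, so swapping keeps the same type
        p1, p2 = p2, p1
    if p2 < p1 + L:
        return
    arr[p1 : p1 + L] = copy1
    arr[p2 : p2 + L] = copy2
    occupied[p1 : p1 + L] = True
    occupied[p2 : p2 + L] = True
    truth.planted_repeats.append(PlantedRepeat(rtype, L, p1, p2, mm))


def _other(base: str, avoid: str) -> str:
    for c in "ACGT":
        if c != base and c != complement(avoid):
            return c
    return "A"


# ---------------------------------------------------------------------------
# evolution along a tree


class _GenomeState:
    """Mutable genome with liftover of boundaries, features and SSR loci."""

    def __init__(self, record: PlastomeRecord, boundaries, ssrs):
        self.chars = list(record.sequence)
        self.boundaries = list(boundaries)      # [b1, b2, b3, b4]
        self.features = [
            Feature(f.name, f.kind, list(f.intervals), f.copy_tag)
            for f in record.features
        ]
        self.ssrs = [PlantedSSR(s.motif, s.start, s.count, s.partition)
                     for s in ssrs]
        self.events: list[tuple] = []

    def clone(self) -> "_GenomeState":
        new = object.__new__(_GenomeState)
        new.chars = list(self.chars)
        new.boundaries = list(self.boundaries)
        new.features = [
            Feature(f.name, f.kind, list(f.intervals), f.copy_tag)
            for f in self.features
        ]
        new.ssrs = [PlantedSSR(s.motif, s.start, s.count, s.partition)
                    for s in self.ssrs]
        new.events = []
        return new

    # -- edits -------------------------------------------------------------

    def substitute(self, pos: int, new: str) -> None:
        old = self.chars[pos]
        self.chars[pos] = new
        self.events.append(("sub", pos, old, new))

    def delete(self, pos: int, length: int) -> None:
        removed = "".join(self.chars[pos : pos + length])
        del self.chars[pos : pos + length]
        self._shift_del(pos, length)
        self.events.append(("del", pos, length, removed))

    def insert(self, pos: int, s: str, mech: str) -> None:
        self.chars[pos:pos] = list(s)
        self._shift_ins(pos, len(s))
        self.events.append(("ins", pos, s, mech))

    def _shift_del(self, p: int, L: int) -> None:
        def f(x: int) -> int:
            return x - L if x >= p + L else (p if x > p else x)

        self.boundaries = [f(b) for b in self.boundaries]
        for feat in self.features:
            feat.intervals = [
                (f(s), f(e), st) for s, e, st in feat.intervals
                if f(e) > f(s)
            ] or [(f(feat.intervals[0][0]), f(feat.intervals[0][0]), "+")]
        self.features = [
            ft for ft in self.features
            if any(e > s for s, e, _ in ft.intervals)
        ]
        for s_ in self.ssrs:
            s_.start = f(s_.start)

    def _shift_ins(self, p: int, L: int) -> None:
        def f(x: int) -> int:
            return x + L if x >= p else x

        self.boundaries = [f(b) for b in self.boundaries]
        for feat in self.features:
            feat.intervals = [
                (f(s), e + L if e > p else e, st)
                for s, e, st in feat.intervals
            ]
        for s_ in self.ssrs:
            s_.start = f(s_.start)

    # -- regions -----------------------------------------------------------

    def spans(self) -> dict[str, tuple[int, int]]:
        b1, b2, b3, b4 = self.boundaries
        return {"LSC": (0, b1), "IRb": (b1, b2), "SSC": (b2, b3),
                "IRa": (b3, b4)}

    def mirror_pos(self, pos: int) -> int:
        """IRb position -> corresponding IRa position (same site)."""
        b1, b2, b3, b4 = self.boundaries
        return b3 + (b2 - b1) - 1 - (pos - b1)


def replay(ancestor_sequence: str, event_lists: list[list[tuple]]) -> str:
    """Apply recorded branch events in order; returns the descendant sequence."""
    chars = list(ancestor_sequence)
    for events in event_lists:
        for ev in events:
            if ev[0] == "sub":
                _, pos, old, new = ev
                assert chars[pos] == old, "replay mismatch"
                chars[pos] = new
            elif ev[0] == "del":
                _, pos, length, removed = ev
                assert "".join(chars[pos : pos + length]) == removed
                del chars[pos : pos + length]
            else:
                _, pos, s, _mech = ev
                chars[pos:pos] = list(s)
    return "".join(chars)


def _draw_indel_length(rng, mix: dict[str, float]) -> int:
    bins = list(mix)
    probs = np.array([mix[b] for b in bins])
    b = bins[int(rng.choice(len(bins), p=probs / probs.sum()))]
    lo, hi = SPECTRUM_BIN_RANGES[b]
    return int(rng.integers(lo, hi + 1))


def _draw_sub(rng, old: str, kappa: float) -> str:
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if old not in "ACGT":
        return old
    if rng.random() < kappa / (kappa + 2.0):
        return transitions[old]
    tv = [b for b in "ACGT" if b != old and b != transitions[old]]
    return tv[int(rng.integers(2))]


def _overlaps_ssr(state: _GenomeState, pos: int, length: int) -> bool:
    return any(
        pos < s.start + len(s.motif) * s.count and s.start < pos + length
        for s in state.ssrs
    )


def _evolve_branch(
    state: _GenomeState, bl: float, cfg: EvolutionConfig,
    rng: np.random.Generator,
) -> None:
    mults = cfg.region_multipliers
    regions = (["LSC", "IRb", "SSC"] if cfg.ir_concerted
               else ["LSC", "IRb", "SSC", "IRa"])
    plan: list[tuple[str, str]] = []
    for rname in regions:
        rs, re_ = state.spans()[rname]
        mult = mults["IR" if rname.startswith("IR") else rname]
        lam = bl * mult * (re_ - rs)
        n_sub = rng.poisson(lam)
        n_indel = rng.poisson(lam * cfg.indel_to_sub_ratio)
        plan += [(rname, "sub")] * n_sub + [(rname, "indel")] * n_indel
        # SSR slippage per locus in this region
        for s in list(state.ssrs):
            if rs <= s.start < re_ and rng.random() < cfg.ssr_slippage_rate * bl:
                plan.append((rname, "slip:%d" % state.ssrs.index(s)))
    rng.shuffle(plan)  # type: ignore[arg-type]
    for rname, what in plan:
        rs, re_ = state.spans()[rname]
        if re_ - rs < 50:
            continue
        mirror = cfg.ir_concerted and rname == "IRb"
        if what == "sub":
            pos = int(rng.integers(rs, re_))
            new = _draw_sub(rng, state.chars[pos], cfg.kappa)
            if new == state.chars[pos]:
                continue
            if mirror:
                mp = state.mirror_pos(pos)
                state.substitute(mp, complement(new))
            state.substitute(pos, new)
        elif what == "indel":
            L = _draw_indel_length(rng, cfg.indel_length_mix)
            deletion = rng.random() < 0.5
            pos = None
            for _ in range(30):
                cand = int(rng.integers(rs + L + 1, re_ - L - 1))
                if not _overlaps_ssr(state, cand, L if deletion else 0):
                    pos = cand
                    break
            if pos is None:
                continue
            if deletion:
                if mirror:
                    mstart = state.mirror_pos(pos + L - 1)
                    state.delete(mstart, L)
                state.delete(pos, L)
            else:
                if rng.random() < cfg.adjacent_duplication_fraction:
                    s = "".join(state.chars[pos - L : pos])
                    mech = "adjacent-duplication"
                else:
                    s = "".join(BASES[rng.integers(0, 4, size=L)])
                    mech = "random"
                if mirror:
                    mp = state.mirror_pos(pos) + 1   # after the mirrored site
                    state.insert(mp, revcomp(s), mech)
                state.insert(pos, s, mech)
        else:                                       # SSR slippage
            idx = int(what.split(":")[1])
            s_ = state.ssrs[idx]
            u = len(s_.motif)
            locus_end = s_.start + u * s_.count
            if not (rs <= s_.start < re_):
                continue
            grow = rng.random() < 0.5 or s_.count <= 2
            if mirror:
                pass  # slippage inside IRb mirrors like any indel
            if grow:
                unit = "".join(state.chars[locus_end - u : locus_end])
                if mirror:
                    state.insert(state.mirror_pos(locus_end) + 1,
                                 revcomp(unit), "slippage")
                state.insert(locus_end, unit, "slippage")
                s_.count += 1
            else:
                if mirror:
                    state.delete(state.mirror_pos(locus_end - 1), u)
                state.delete(locus_end - u, u)
                s_.count -= 1


def evolve_along_tree(
    ancestor: PlastomeRecord,
    truth: TruthTable,
    config: EvolutionConfig,
) -> tuple[dict[str, PlastomeRecord], TruthTable]:
    """Evolve the ancestor along the newick tree; tips become records."""
    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    # never mutate the caller's truth table: one ancestor may seed many runs
    truth = dataclasses_replace(
        truth, branch_events={}, tip_boundaries={}, tip_records={}, tree=tree,
    )
    rng = np.random.default_rng(config.seed)
    root_state = _GenomeState(ancestor, truth.boundaries, truth.planted_ssrs)
    states = {id(tree.seed_node): root_state}
    tips: dict[str, PlastomeRecord] = {}
    counter = [0]

    def node_name(node) -> str:
        if node.taxon is not None:
            return node.taxon.label
        if node is tree.seed_node:
            return "root"
        if not hasattr(node, "_synth_label"):
            counter[0] += 1
            node._synth_label = f"node{counter[0]}"
        return node._synth_label

    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        if bl < 0:
            raise ValueError(f"negative branch length at {node_name(node)}")
        parent = states[id(node.parent_node)]
        st = parent.clone()
        _evolve_branch(st, bl, config, rng)
        states[id(node)] = st
        truth.branch_events[(node_name(node.parent_node),
                             node_name(node))] = list(st.events)
        if node.is_leaf():
            label = node_name(node)
            rec = PlastomeRecord(
                id=label, sequence="".join(st.chars), circular=True,
                features=[Feature(f.name, f.kind, list(f.intervals),
                                  f.copy_tag) for f in st.features],
                source="synthetic",
            )
            tips[label] = rec
            truth.tip_boundaries[label] = tuple(st.boundaries)
            truth.tip_records[label] = rec
    return tips, truth


def path_events(truth: TruthTable, tip: str) -> list[list[tuple]]:
    """Ordered branch event lists from the root down to one tip."""
    node = truth.tree.find_node_with_taxon_label(tip)
    chain = []
    while node.parent_node is not None:
        chain.append(node)
        node = node.parent_node
    chain.reverse()
    out = []
    for nd in chain:
        for (pname, cname), evs in truth.branch_events.items():
            label = nd.taxon.label if nd.taxon else getattr(
                nd, "_synth_label", None)
            if cname == label:
                out.append(evs)
                break
    return out


def write_fixture_set(
    records: dict[str, PlastomeRecord],
    truth: TruthTable,
    tree_newick: str,
    out_dir: str | Path,
) -> list[Path]:
    """GenBank + FASTA per tip, the tree, and truth TSVs (deterministic names)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not records:
        log.warning("empty tip map: nothing to write")
        return written
    for label in sorted(records):
        gb = out / f"{label}.gb"
        fa = out / f"{label}.fasta"
        write_genbank(records[label], gb)
        write_fasta([records[label]], fa)
        written += [gb, fa]
    tr = out / "tree.nwk"
    tr.write_text(tree_newick.strip() + "\n")
    written.append(tr)
    tsv = out / "truth_ssrs.tsv"
    with open(tsv, "w") as fh:
        fh.write("motif\tstart\tcount\tpartition\n")
        for s in truth.planted_ssrs:
            fh.write(f"{s.motif}\t{s.start}\t{s.count}\t{s.partition}\n")
    written.append(tsv)
    tsv = out / "truth_repeats.tsv"
    with open(tsv, "w") as fh:
        fh.write("type\tlength\tpos1\tpos2\tmismatches\n")
        for r in truth.planted_repeats:
            fh.write(f"{r.type}\t{r.length}\t{r.pos1}\t{r.pos2}\t"
                     f"{r.mismatches}\n")
    written.append(tsv)
    tsv = out / "truth_boundaries.tsv"
    with open(tsv, "w") as fh:
        fh.write("genome\tJLB\tJSB\tJSA\tend\n")
        b = truth.boundaries
        fh.write(f"ancestor\t{b[0]}\t{b[1]}\t{b[2]}\t{b[3]}\n")
        for label in sorted(truth.tip_boundaries):
            b = truth.tip_boundaries[label]
            fh.write(f"{label}\t{b[0]}\t{b[1]}\t{b[2]}\t{b[3]}\n")
    written.append(tsv)
    return written
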