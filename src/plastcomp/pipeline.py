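"""End-to-end comparative pipeline: structure, repeats, SSRs, divergence,
markers, and indel mapping, orchestrated from one config."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import pandas as pd

from . import __version__
from .alignment import align_multi
from .divergence import (
    GenomeContext,
    divergence_matrix,
    partition_divergence_ratios,
    region_variabilities,
    screen_markers,
)
from .genome_io import (
    PlastomeRecord,
    gene_census,
    read_fasta,
    read_genbank,
)
from .phylo_indels import build_indel_matrix, classify_characters, fitch_assign
from .quadripartite import detect_quadripartite, junction_report
from .repeats import annotate_hits, find_repeats, hits_table, shared_repeat_sets
from .ssr import find_ssrs, locate_ssrs, ssr_summary

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genomes: list[str | Path] = field(default_factory=list)
    tree: str | Path | None = None
    outgroup: str | None = None
    out_dir: str | Path = "plastcomp-out"
    stages: tuple[str, ...] = (
        "structure", "repeats", "ssr", "divergence", "markers", "indel-map",
    )
    min_ir: int = 10000
    repeat_min_len: int = 30
    repeat_max_mismatch: int = 3
    ssr_thresholds: dict[int, int] | None = None
    marker_threshold: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_threshold <= 0 or self.repeat_min_len <= 0:
            raise ValueError("thresholds must be positive")


def load_genome(path: str | Path) -> PlastomeRecord:
    path = Path(path)
    if path.suffix.lower() in (".gb", ".gbk", ".genbank"):
        return read_genbank(path)
    return read_fasta(path)[0]


def run_compare(config: RunConfig) -> dict:
    """Run the comparative pipeline; returns the report bundle and writes
    TSVs plus a JSON manifest under config.out_dir."""
    if not config.genomes:
        raise ValueError("need at least one genome")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {
            k: str(v) for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
        "checksums": {},
    }
    bundle: dict = {}
    records = [load_genome(p) for p in config.genomes]
    contexts: list[GenomeContext] = []

    def stage(name):
        return name in config.stages

    def run_stage(name, fn):
        t0 = time.time()
        try:
            fn()
            manifest["stages"][name] = {
                "status": "ok", "seconds": round(time.time() - t0, 2),
            }
        except Exception as exc:   # partial outputs are retained
            log.exception("stage %s failed", name)
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}

    # ---- structure --------------------------------------------------------
    def _structure():
        rows = []
        junc_rows = []
        for rec in records:
            part = detect_quadripartite(rec, config.min_ir)
            contexts.append(
                GenomeContext(rec, _regions_or_empty(rec), part)
            )
            census = gene_census(rec) if rec.genes() else None
            rows.append(
                {
                    "genome": rec.id,
                    "length": len(rec),
                    "lsc_len": part.lsc_length,
                    "ssc_len": part.ssc_length,
                    "ir_len": part.ir_length,
                    "gc_percent": round(rec.gc_percent, 2),
                    **part.junctions,
                    "genes_total": census.total if census else 0,
                }
            )
            if rec.genes():
                rep = junction_report(rec, part)
                for r in rep.rows:
                    junc_rows.append({"genome": rec.id, **r})
        df = pd.DataFrame(rows)
        df.to_csv(out / "structure.tsv", sep="\t", index=False)
        bundle["structure"] = df
        jdf = pd.DataFrame(junc_rows)
        jdf.to_csv(out / "junctions.tsv", sep="\t", index=False)
        bundle["junctions"] = jdf

    run_stage("structure", _structure)
    if not contexts:      # structure disabled or failed: minimal contexts
        contexts.extend(
            GenomeContext(rec, _regions_or_empty(rec), None)
            for rec in records
        )

    # ---- repeats ----------------------------------------------------------
    def _repeats():
        from .repeats import strip_duplicate_ir

        all_tables = []
        hits_by_genome = {}
        for ctx in contexts:
            if ctx.partition is not None:
                seq, _meta = strip_duplicate_ir(ctx.record, ctx.partition)
            else:
                seq = ctx.record.sequence
            hits = find_repeats(
                seq, config.repeat_min_len, config.repeat_max_mismatch
            )
            if ctx.regions.regions:
                annotate_hits(hits, ctx.regions)
            hits_by_genome[ctx.record.id] = hits
            all_tables.append(hits_table(ctx.record.id, hits))
        df = pd.concat(all_tables, ignore_index=True) if all_tables else \
            pd.DataFrame()
        df.to_csv(out / "repeats.tsv", sep="\t", index=False)
        bundle["repeats"] = df
        if len(hits_by_genome) >= 2:
            summary = shared_repeat_sets(hits_by_genome)
            bundle["shared_repeats"] = summary
            with open(out / "shared_repeats.json", "w") as fh:
                json.dump(
                    {
                        "per_genome": summary.per_genome_counts,
                        "shared_all": summary.shared_all,
                        "shared_by": {
                            str(k): v for k, v in summary.shared_by.items()
                        },
                        "unique": summary.unique_per_genome,
                    },
                    fh, indent=1,
                )

    if stage("repeats"):
        run_stage("repeats", _repeats)

    # ---- ssr --------------------------------------------------------------
    def _ssr():
        frames = []
        for ctx in contexts:
            loci = find_ssrs(ctx.record.sequence, config.ssr_thresholds)
            if ctx.regions.regions:
                locate_ssrs(loci, ctx.regions, ctx.partition)
            summary = ssr_summary(loci)
            summary.insert(0, "genome", ctx.record.id)
            frames.append(summary)
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
        df.to_csv(out / "ssr.tsv", sep="\t", index=False)
        bundle["ssr"] = df

    if stage("ssr"):
        run_stage("ssr", _ssr)

    # ---- divergence -------------------------------------------------------
    def _divergence():
        if len(contexts) < 2:
            log.warning("single genome: divergence stage skipped")
            return
        mat = divergence_matrix(contexts)
        mat.to_csv(out / "divergence_matrix.tsv", sep="\t")
        bundle["divergence_matrix"] = mat
        ratios = {}
        for ctx in contexts:
            for mode in ("functional", "positional"):
                try:
                    _, r = partition_divergence_ratios(
                        contexts, ctx.record.id, mode
                    )
                    ratios[f"{ctx.record.id}:{mode}"] = r
                except (ZeroDivisionError, ValueError) as exc:
                    log.warning("ratios %s/%s: %s", ctx.record.id, mode, exc)
        bundle["partition_ratios"] = ratios
        with open(out / "partition_ratios.json", "w") as fh:
            json.dump(ratios, fh, indent=1)

    if stage("divergence"):
        run_stage("divergence", _divergence)

    # ---- markers ----------------------------------------------------------
    def _markers():
        if len(contexts) < 2:
            log.warning("single genome: marker stage skipped")
            return
        varis = region_variabilities(contexts)
        df = pd.DataFrame(
            [
                {
                    "region": v.name, "category": v.category, "ns": v.ns,
                    "id": v.id_, "aligned_length": v.aligned_length,
                    "variability_percent": round(v.variability_percent, 2),
                }
                for v in varis
            ]
        )
        df.to_csv(out / "region_variability.tsv", sep="\t", index=False)
        bundle["region_variability"] = df
        markers = screen_markers(varis, config.marker_threshold)
        mdf = pd.DataFrame(
            [
                {
                    "region": v.name,
                    "variability_percent": round(v.variability_percent, 2),
                }
                for v in markers
            ]
        )
        mdf.to_csv(out / "markers.tsv", sep="\t", index=False)
        bundle["markers"] = mdf
        bundle["_variabilities"] = varis

    if stage("markers"):
        run_stage("markers", _markers)

    # ---- indel mapping ----------------------------------------------------
    def _indel_map():
        if config.tree is None or len(contexts) < 3:
            log.warning("no tree or too few genomes: indel mapping skipped")
            return
        tree = dendropy.Tree.get(path=str(config.tree), schema="newick")
        seq_maps = [c.region_sequences() for c in contexts]
        shared = sorted(set.intersection(*(set(m) for m in seq_maps)))
        alns = []
        for name in shared:
            seqs = {
                c.record.id: m[name][1]
                for c, m in zip(contexts, seq_maps)
            }
            alns.append((name, align_multi(seqs)))
        matrix = build_indel_matrix(alns)
        outgroup = config.outgroup or contexts[-1].record.id
        mapping = fitch_assign(tree, matrix, outgroup)
        df = classify_characters(mapping)
        df.to_csv(out / "indel_characters.tsv", sep="\t", index=False)
        bundle["indel_characters"] = df

    if stage("indel-map"):
        run_stage("indel-map", _indel_map)

    # ---- manifest ---------------------------------------------------------
    for f in sorted(out.glob("*.tsv")) + sorted(out.glob("*.json")):
        if f.name == "manifest.json":
            continue
        manifest["checksums"][f.name] = hashlib.sha256(
            f.read_bytes()
        ).hexdigest()
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    bundle["manifest"] = manifest
    return bundle


def _regions_or_empty(rec: PlastomeRecord):
    from .genome_io import RegionSet, extract_functional_regions

    if rec.genes():
        return extract_functional_regions(rec)
    return RegionSet(regions=[], genome_length=len(rec))
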