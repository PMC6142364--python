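"""End-to-end pipeline orchestration with one config and derived seeds.

``run_pipeline`` chains: (optional) genome simulation -> canonical models ->
ES/IR junction libraries -> effective mappability + QC -> read mapping ->
corrected counts -> event rates and classes -> binned species profiles ->
architecture features -> signed-KS association matrix. Every stage draws its
randomness from a per-stage child of the run seed, so a rerun with the same
config is byte-identical; a provenance manifest records parameters, input
hashes and event tallies.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .archstats import (
    ES_FEATURES,
    association_matrix,
    build_splice_site_model,
    extract_features_es,
    extract_features_ir,
)
from .genemodel import extract_canonical_models
from .io import read_fasta, iter_fastq_seqs, write_fastq
from .junctions import build_es_library, build_ir_library, DEFAULT_FLANK
from .mapper import JunctionIndex, qc_filter_report
from .quantify import quantify_es, quantify_ir, species_frequency
from .synthetic import GenomeSpec, TruthConfig, generate_genome, simulate_reads

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Pipeline parameters; defaults are the pipeline's printed constants."""

    # inputs: either paths...
    genome: str | None = None
    annotation: str | None = None
    reads: str | None = None
    # ...or a synthetic run
    simulate: GenomeSpec | None = None
    truth: TruthConfig | None = None
    n_reads: int = 200_000

    flank: int = DEFAULT_FLANK  # 42
    read_len: int = 50
    max_mismatches: int = 2
    both_strands: bool = True
    n_bins: int = 100
    bin_size: int = 100
    reads_per_bin: int = 10_000
    ks_alpha: float = 0.01
    seed: int = 0

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "simulate" in d and d["simulate"] is not None:
            d["simulate"] = GenomeSpec(**d["simulate"])
        if "truth" in d and d["truth"] is not None:
            t = d["truth"]
            for k in ("skip_choices", "retention_choices", "coupling_beta"):
                if k in t:
                    t[k] = tuple(t[k])
            d["truth"] = TruthConfig(**t)
        return cls(**d)


def _stage_seeds(seed: int, names: list[str]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    return {
        n: int(child.generate_state(1)[0] % 2**31)
        for n, child in zip(names, ss.spawn(len(names)))
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run every stage, write per-stage TSVs under ``outdir``, and return the
    provenance manifest (also written as manifest.json)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed, ["simulate", "reads", "profile_es", "profile_ir"])
    manifest: dict = {
        "tool": "splicearch",
        "version": __version__,
        "config": _config_dict(config),
        "stage_seeds": seeds,
        "stages": {},
        "inputs": {},
    }

    # --- inputs ---------------------------------------------------------
    if config.simulate is not None:
        syn = generate_genome(config.simulate, config.truth)
        syn.write(out)
        genome, models = syn.genome, syn.models
        reads = simulate_reads(models, genome, syn.truth, config.n_reads,
                               config.read_len, seeds["reads"])
        write_fastq(reads, out / "reads.fastq")
        manifest["stages"]["simulate"] = {
            "n_genes": len(models),
            "n_reads": len(reads),
        }
    else:
        for name in ("genome", "annotation", "reads"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"stage 'inputs': missing {name} file: {p}")
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}
        genome = read_fasta(config.genome)
        models = extract_canonical_models(config.annotation)
        reads = list(iter_fastq_seqs(config.reads))

    # --- junction libraries + mappability -------------------------------
    results: dict = {"models": models}
    for kind, builder in (("es", build_es_library), ("ir", build_ir_library)):
        lib = builder(models, genome, config.flank)
        if not lib.junctions:
            logger.warning("no %s junctions (intron-poor annotation)", kind.upper())
            manifest["stages"][f"junctions_{kind}"] = {"n_junctions": 0, "n_events": 0}
            continue
        idx = JunctionIndex(lib.sequences, config.read_len, config.max_mismatches,
                            config.both_strands)
        mapp = idx.effective_mappability(lib.flanks())
        mapp.to_csv(out / f"mappability_{kind}.tsv", sep="\t")
        qc = qc_filter_report(lib, mapp)
        qc.to_csv(out / f"qc_{kind}.tsv", sep="\t", index=False)
        counts, stats = idx.map_reads(reads)
        pd.Series(dict(counts), name="raw_count").rename_axis("jid").to_csv(
            out / f"counts_{kind}.tsv", sep="\t"
        )
        if kind == "es":
            events = quantify_es(lib.es_triplets, counts, mapp)
            n_events = len(lib.es_triplets)
        else:
            events = quantify_ir(lib.ir_triads, counts, mapp)
            n_events = len(lib.ir_triads)
        events.to_csv(out / f"events_{kind}.tsv", sep="\t", index=False)
        profile = species_frequency(
            events, counts, mapp, kind,
            config.n_bins, config.bin_size, config.reads_per_bin,
            seed=seeds[f"profile_{kind}"],
        )
        pd.DataFrame({
            "bin": np.arange(profile.n_bins),
            "mean_rate_percent": profile.bin_values,
            "reads_subsampled": profile.reads_subsampled,
        }).to_csv(out / f"profile_{kind}.tsv", sep="\t", index=False)
        manifest["stages"][f"junctions_{kind}"] = {
            "n_junctions": len(lib.junctions),
            "n_events": n_events,
            "n_passed": int(events["passed"].sum()),
            "mapping": stats,
            "status_counts": events["status"].value_counts().to_dict(),
        }
        results[f"library_{kind}"] = lib
        results[f"mappability_{kind}"] = mapp
        results[f"counts_{kind}"] = counts
        results[f"events_{kind}"] = events
        results[f"profile_{kind}"] = profile

    # --- architecture features + associations ---------------------------
    try:
        ss_model = build_splice_site_model(models, genome)
    except ValueError:
        ss_model = None
    if ss_model is not None and "events_es" in results:
        feats = extract_features_es(models, genome, ss_model)
        feats.to_csv(out / "features_es.tsv", sep="\t", index=False)
        ev = results["events_es"]
        merged = feats.merge(
            ev[["gene_id", "exon_index", "r_es", "status"]],
            on=["gene_id", "exon_index"], how="inner",
        )
        pos = merged[merged["status"] == "positive"]
        neg = merged[merged["status"] == "negative"]
        if len(pos) >= 10 and len(neg) >= 10:
            assoc = association_matrix(pos, neg, ES_FEATURES, alpha=config.ks_alpha)
            assoc.to_csv(out / "assoc_es.tsv", sep="\t", index=False)
            results["assoc_es"] = assoc
            manifest["stages"]["assoc_es"] = {"n_positive": len(pos), "n_negative": len(neg)}
        results["features_es"] = merged

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    results["manifest"] = manifest
    return results


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
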