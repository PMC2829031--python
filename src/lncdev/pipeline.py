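"""End-to-end orchestration: simulate -> annotate -> DE -> context ->
screens/enrichment -> qPCR -> report, from a single YAML configuration.

All randomness flows from one seed fanned out per stage by fixed offsets;
a rerun with identical configuration produces byte-identical outputs and
manifest.  The manifest records the configuration hash, seed, package
version, per-stage row counts and a SHA-256 per output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import write_bed, write_fasta, write_gff3, write_tsv
from .config import STAGES, TEMPLATE_MARKERS, SimConfig
from .context import classify_contexts, enhancer_summary, positional_conservation, structure_summary
from .de import run_de
from .mapping import GenomeIndex, MapperParams, classify_probe_targets, map_probes
from .qpcr import tsa_response_table
from .screens import (
    R_THRESHOLD_DEFAULT,
    StageProfiles,
    discordant_pair_screen,
    gaban_olp_switching,
    lineage_switch_screen,
    marker_correlation_screen,
    stage_exclusive_screen,
    term_enrichment,
)
from .simulate import (
    simulate_annotation,
    simulate_expression,
    simulate_probes,
    simulate_qpcr,
    simulate_term_map,
    simulate_truth,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    b_threshold: float = 1.0
    r_threshold: float = float(R_THRESHOLD_DEFAULT)
    structure_p: float = 0.9
    enrichment_fdr: float = 0.05
    bidirectional_window: int = 1000
    tss_window: int = 5000
    loess_span: float = 0.3
    p_prior: float = 0.01
    min_identity: float = 99.0
    min_score: int = 50
    seed_length: int = 11
    qpcr_n_perm: int = 2000
    inputs: dict[str, str] = field(default_factory=dict)  # optional pre-existing files

    def __post_init__(self) -> None:
        if not 0 < self.structure_p <= 1:
            raise ValueError("structure_p must be in (0, 1]")
        if not 0 < self.r_threshold <= 1:
            raise ValueError("r_threshold must be in (0, 1]")
        if not 0 < self.enrichment_fdr < 1:
            raise ValueError("enrichment_fdr must be in (0, 1)")
        if self.bidirectional_window <= 0 or self.tss_window <= 0:
            raise ValueError("windows must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim_raw = raw.pop("sim", {})
        if "lfc_range" in sim_raw:
            sim_raw["lfc_range"] = tuple(sim_raw["lfc_range"])
        if "template_groups" in sim_raw:
            sim_raw["template_groups"] = {
                k: tuple(v) for k, v in sim_raw["template_groups"].items()
            }
        if seed is not None:
            sim_raw["seed"] = seed
        return cls(sim=SimConfig(**sim_raw), **raw)

    def config_hash(self) -> str:
        d = {k: v for k, v in self.__dict__.items() if k != "sim"}
        d["sim"] = self.sim.to_dict()
        return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]


def validate_inputs(config: PipelineConfig) -> None:
    """Fail before any stage runs if a referenced input file is missing."""
    for key, path in config.inputs.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"input {key!r}: no such file {path}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in dependency order; returns the manifest dict
    (also written to ``manifest.json``).  On stage failure, partial outputs
    are retained and the error names the stage."""
    validate_inputs(config)
    out = Path(outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    (out / "report").mkdir(exist_ok=True)
    sim = config.sim
    chash, seed = sim.config_hash(), sim.seed
    counts: dict[str, int] = {}

    def emit(df: pd.DataFrame, rel: str) -> None:
        write_tsv(df, out / rel, config_hash=chash, seed=seed)
        counts[rel] = len(df)

    stage = "simulate"
    try:
        bundle = simulate_annotation(sim)
        probes = simulate_probes(bundle, sim)
        truth = simulate_truth(sim, probes=probes, context_truth=bundle.context_truth)
        spots = simulate_expression(truth, sim)
        ct = simulate_qpcr(truth, sim)
        terms = simulate_term_map(truth, sim)

        write_fasta(bundle.genome_a.sequences, out / "inputs/genome_a.fa")
        write_fasta(bundle.genome_b.sequences, out / "inputs/genome_b.fa")
        write_gff3(bundle.genome_a.models, out / "inputs/annotation_a.gff3", chash, seed)
        write_gff3(bundle.genome_b.models, out / "inputs/annotation_b.gff3", chash, seed)
        emit(bundle.ortholog_map, "inputs/orthologs.tsv")
        write_bed(bundle.enhancers, out / "inputs/enhancers.bed", chash, seed)
        write_bed(bundle.structure_windows, out / "inputs/structures.bed", chash, seed)
        write_fasta(
            dict(zip(probes.probe_id, probes.sequence)), out / "inputs/probes.fa"
        )
        emit(probes.drop(columns=["sequence"]), "inputs/probe_targets.tsv")
        emit(spots, "inputs/spots.tsv")
        emit(ct, "inputs/ct.tsv")
        emit(terms, "inputs/terms.tsv")
        emit(truth.probes, "inputs/truth_probes.tsv")
        emit(truth.lfc.reset_index(), "inputs/truth_lfc.tsv")
        emit(bundle.context_truth, "inputs/truth_context.tsv")
        emit(truth.qpcr, "inputs/truth_qpcr.tsv")

        stage = "annotate"
        index = GenomeIndex(bundle.genome_a.sequences, seed_length=config.seed_length)
        params = MapperParams(
            seed_length=config.seed_length,
            min_identity=config.min_identity,
            min_score=config.min_score,
        )
        hits, status = map_probes(probes, index, params)
        target_class = classify_probe_targets(hits, bundle.genome_a.models)
        emit(hits, "probe_hits.tsv")
        emit(status, "probe_status.tsv")
        emit(target_class, "target_class.tsv")

        stage = "de"
        controls = set(probes.probe_id[probes.is_control])
        de_table, hyper, _fit = run_de(
            spots,
            controls,
            span=config.loess_span,
            p_prior=config.p_prior,
            b_threshold=config.b_threshold,
        )
        emit(de_table, "de_results.tsv")

        stage = "context"
        ncrnas_a = bundle.genome_a.ncrnas()
        calls = classify_contexts(
            ncrnas_a, bundle.genome_a.genes(), config.bidirectional_window
        )
        conservation = positional_conservation(
            calls,
            bundle.ortholog_map,
            bundle.genome_b.ncrnas(),
            bundle.genome_b.genes(),
            config.bidirectional_window,
        )
        enh = enhancer_summary(ncrnas_a, bundle.enhancers, config.tss_window)
        struct = structure_summary(ncrnas_a, bundle.structure_windows, config.structure_p)
        emit(calls, "context_calls.tsv")
        emit(conservation, "conservation.tsv")
        emit(enh, "enhancer_assoc.tsv")
        emit(struct, "structure_summary.tsv")

        stage = "screens"
        class_of = dict(zip(target_class.probe_id, target_class.target_class))
        is_ncrna = pd.Series(
            {p: class_of.get(p, "") == "noncoding" for p in de_table.probe_id.unique()}
        )
        profiles = StageProfiles.from_de_table(de_table, is_ncrna=is_ncrna)
        marker_rows = []
        for tmpl, marker_probe in truth.markers.items():
            pos, neg = marker_correlation_screen(
                profiles, marker_probe, r_threshold=config.r_threshold
            )
            for res, kind in ((pos, "correlated"), (neg, "anticorrelated")):
                for pid in res.members:
                    marker_rows.append(
                        {
                            "marker": TEMPLATE_MARKERS.get(tmpl, tmpl),
                            "marker_probe": marker_probe,
                            "set": kind,
                            "probe_id": pid,
                        }
                    )
        marker_sets = pd.DataFrame(
            marker_rows, columns=["marker", "marker_probe", "set", "probe_id"]
        )
        ls_rows = []
        for up, down, name in (
            ("GABAN", ["OLP"], "gaban_up_ol_down"),
            ("OLP", ["GABAN"], "olp_up_gaban_down"),
        ):
            res = lineage_switch_screen(profiles, up, down, strict=False)
            ls_rows += [{"screen": name, "probe_id": p} for p in res.members]
        lineage = pd.DataFrame(ls_rows, columns=["screen", "probe_id"])
        excl = stage_exclusive_screen(profiles, "OLP")
        exclusive = pd.DataFrame(
            {"probe_id": excl.members, "direction": excl.stats.direction if len(excl.stats) else []}
        )
        pairs = discordant_pair_screen(calls, profiles)
        switching = gaban_olp_switching(profiles)
        emit(marker_sets, "marker_correlated.tsv")
        emit(lineage, "lineage_switch.tsv")
        emit(exclusive, "stage_exclusive_olp.tsv")
        emit(pairs, "discordant_pairs.tsv")
        emit(switching, "gaban_olp_switching.tsv")

        stage = "enrichment"
        mrna_probes = set(target_class.probe_id[target_class.target_class == "protein_coding"])
        gene_of = dict(zip(probes.probe_id, probes.target_id))
        expressed_genes = sorted(
            {
                gene_of[p]
                for p in de_table.probe_id[de_table.expressed].unique()
                if p in mrna_probes
            }
        )
        enr_frames = []
        for contrast in STAGES:
            sub = de_table[(de_table.contrast == contrast) & de_table.de_call]
            for direction, sel in (("up", sub.M > 0), ("down", sub.M < 0)):
                glist = sorted(
                    {gene_of[p] for p in sub.probe_id[sel] if p in mrna_probes}
                )
                glist = [g for g in glist if g in set(expressed_genes)]
                if not glist:
                    continue
                res = term_enrichment(glist, expressed_genes, terms, config.enrichment_fdr)
                res.insert(0, "direction", direction)
                res.insert(0, "contrast", contrast)
                enr_frames.append(res)
        enrichment = (
            pd.concat(enr_frames, ignore_index=True)
            if enr_frames
            else pd.DataFrame()
        )
        emit(enrichment, "enrichment.tsv")

        stage = "qpcr"
        tsa = tsa_response_table(ct, n_perm=config.qpcr_n_perm, seed=seed)
        emit(tsa, "tsa_response.tsv")

        stage = "report"
        write_report(out, counts)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    manifest = {
        "config_hash": config.config_hash(),
        "sim_config_hash": chash,
        "seed": seed,
        "version": __version__,
        "row_counts": dict(sorted(counts.items())),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


DATA_DICTIONARY = [
    ("mrna_de.tsv", "probe_id", "probe identifier (protein-coding target)"),
    ("mrna_de.tsv", "contrast", "stage-vs-NSC contrast"),
    ("mrna_de.tsv", "M", "mean normalized log2 ratio (M-statistic)"),
    ("mrna_de.tsv", "fold_change", "2^M"),
    ("mrna_de.tsv", "A", "mean log2 intensity"),
    ("mrna_de.tsv", "B", "posterior log-odds of differential expression"),
    ("mrna_de.tsv", "p_value", "moderated-t two-sided p"),
    ("mrna_de.tsv", "adj_p", "Benjamini-Hochberg adjusted p"),
    ("mrna_de.tsv", "expressed", "above-background call"),
    ("mrna_de.tsv", "de_call", "expressed and B > threshold"),
    ("ncrna_de.tsv", "*", "same columns as mrna_de.tsv, noncoding targets"),
    ("context_conservation.tsv", "ncrna_id", "ncRNA locus identifier"),
    ("context_conservation.tsv", "context_class", "antisense / intronic_(anti)sense / bidirectional / intergenic"),
    ("context_conservation.tsv", "host_gene", "associated protein-coding gene"),
    ("context_conservation.tsv", "conserved", "positionally conserved in second genome"),
    ("context_conservation.tsv", "structured", "high-confidence structure window on an exon"),
    ("context_conservation.tsv", "enhancer_assoc", "enhancer overlapping locus or near TSS"),
    ("discordant_switching.tsv", "*", "ncRNA/host pairs both DE, labeled discordant/concordant"),
    ("marker_correlated_sets.tsv", "*", "ncRNAs with signed-r concordant/anticorrelated marker profiles"),
    ("enrichment.tsv", "*", "hypergeometric term over-representation per DE gene list"),
    ("tsa.tsv", "*", "TSA-vs-untreated ratios per gene, arm, timepoint"),
]


def write_report(run_dir: str | Path, counts: dict | None = None) -> None:
    """Emit the report table set from stage outputs (tables shaped like the
    study's supplementary files); missing stage outputs are skipped with a
    warning."""
    run_dir = Path(run_dir)
    rpt = run_dir / "report"
    rpt.mkdir(exist_ok=True)

    def load(name: str) -> pd.DataFrame | None:
        p = run_dir / name
        if not p.exists():
            log.warning("stage output %s missing; report table skipped", name)
            return None
        return pd.read_csv(p, sep="\t", comment="#")

    de = load("de_results.tsv")
    target_class = load("target_class.tsv")
    if de is not None and target_class is not None:
        cls = dict(zip(target_class.probe_id, target_class.target_class))
        de = de.assign(target_class=de.probe_id.map(cls))
        de[de.target_class == "protein_coding"].drop(columns="target_class").to_csv(
            rpt / "mrna_de.tsv", sep="\t", index=False
        )
        de[de.target_class == "noncoding"].drop(columns="target_class").to_csv(
            rpt / "ncrna_de.tsv", sep="\t", index=False
        )
    calls = load("context_calls.tsv")
    cons = load("conservation.tsv")
    struct = load("structure_summary.tsv")
    enh = load("enhancer_assoc.tsv")
    if calls is not None and cons is not None:
        merged = calls.merge(cons, on="ncrna_id", how="left")
        if struct is not None:
            merged = merged.merge(struct[["ncrna_id", "structured"]], on="ncrna_id", how="left")
        if enh is not None:
            merged = merged.merge(enh[["ncrna_id", "enhancer_assoc"]], on="ncrna_id", how="left")
        merged.to_csv(rpt / "context_conservation.tsv", sep="\t", index=False)
    pairs = load("discordant_pairs.tsv")
    if pairs is not None:
        pairs.to_csv(rpt / "discordant_switching.tsv", sep="\t", index=False)
    markers = load("marker_correlated.tsv")
    if markers is not None:
        markers.to_csv(rpt / "marker_correlated_sets.tsv", sep="\t", index=False)
    enrich = load("enrichment.tsv")
    if enrich is not None:
        enrich.to_csv(rpt / "enrichment.tsv", sep="\t", index=False)
    tsa = load("tsa_response.tsv")
    if tsa is not None:
        tsa.to_csv(rpt / "tsa.tsv", sep="\t", index=False)
    pd.DataFrame(DATA_DICTIONARY, columns=["table", "column", "description"]).to_csv(
        rpt / "data_dictionary.tsv", sep="\t", index=False
    )
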