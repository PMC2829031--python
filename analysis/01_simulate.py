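"""Generate the synthetic study: two annotated genomes with planted ncRNA
contexts and conservation, the probe pools, reference-design spot
intensities with planted differential expression, TSA qPCR tables and a
term map.  All downstream steps read these files from results/run/inputs."""

from common import RUN, emit, load_config
from lncdev.annotation import write_bed, write_fasta, write_gff3
from lncdev.simulate import (
    simulate_annotation,
    simulate_expression,
    simulate_probes,
    simulate_qpcr,
    simulate_term_map,
    simulate_truth,
)


def main() -> None:
    cfg = load_config()
    sim = cfg.sim
    chash, seed = sim.config_hash(), sim.seed
    print(f"simulating study (seed={seed}, {sim.n_genes} genes, {sim.n_ncrnas} ncRNAs)")

    bundle = simulate_annotation(sim)
    probes = simulate_probes(bundle, sim)
    truth = simulate_truth(sim, probes=probes, context_truth=bundle.context_truth)
    spots = simulate_expression(truth, sim)
    ct = simulate_qpcr(truth, sim)
    terms = simulate_term_map(truth, sim)

    inputs = RUN / "inputs"
    inputs.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.genome_a.sequences, inputs / "genome_a.fa")
    write_fasta(bundle.genome_b.sequences, inputs / "genome_b.fa")
    write_gff3(bundle.genome_a.models, inputs / "annotation_a.gff3", chash, seed)
    write_gff3(bundle.genome_b.models, inputs / "annotation_b.gff3", chash, seed)
    write_bed(bundle.enhancers, inputs / "enhancers.bed", chash, seed)
    write_bed(bundle.structure_windows, inputs / "structures.bed", chash, seed)
    write_fasta(dict(zip(probes.probe_id, probes.sequence)), inputs / "probes.fa")
    emit(bundle.ortholog_map, "inputs/orthologs.tsv", chash, seed)
    emit(probes.drop(columns=["sequence"]), "inputs/probe_targets.tsv", chash, seed)
    emit(spots, "inputs/spots.tsv", chash, seed)
    emit(ct, "inputs/ct.tsv", chash, seed)
    emit(terms, "inputs/terms.tsv", chash, seed)
    emit(truth.probes, "inputs/truth_probes.tsv", chash, seed)
    emit(truth.lfc.reset_index(), "inputs/truth_lfc.tsv", chash, seed)
    emit(bundle.context_truth, "inputs/truth_context.tsv", chash, seed)
    emit(truth.qpcr, "inputs/truth_qpcr.tsv", chash, seed)

    ctx = bundle.context_truth.context_class.value_counts()
    print("planted context classes:", dict(ctx))
    print(f"planted conserved (anchored): {int(bundle.context_truth.conserved.sum())}")
    print(f"spot table: {len(spots)} spots over "
          f"{spots.array_id.nunique()} arrays (5 stages x {sim.n_replicates} replicates vs NSC)")


if __name__ == "__main__":
    main()
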