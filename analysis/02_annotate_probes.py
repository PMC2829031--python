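"""Re-annotate the probe set: map every probe to genome A with the
seed-and-extend mapper (99% identity, score >= 50, ambiguous hits dropped)
and classify each reliably mapped probe's target as protein-coding or
noncoding by strand-aware feature overlap."""

from common import RUN, emit, load_config
from lncdev.annotation import read_fasta, read_gff3
from lncdev.mapping import GenomeIndex, MapperParams, classify_probe_targets, map_probes


def main() -> None:
    cfg = load_config()
    chash, seed = cfg.sim.config_hash(), cfg.sim.seed
    inputs = RUN / "inputs"
    genome = read_fasta(inputs / "genome_a.fa")
    models = read_gff3(inputs / "annotation_a.gff3")
    probe_seqs = read_fasta(inputs / "probes.fa")
    import pandas as pd

    probes = pd.DataFrame(
        {"probe_id": list(probe_seqs), "sequence": list(probe_seqs.values())}
    )
    print(f"mapping {len(probes)} probes against {sum(map(len, genome.values())):,} bp")
    index = GenomeIndex(genome, seed_length=cfg.seed_length)
    params = MapperParams(
        seed_length=cfg.seed_length,
        min_identity=cfg.min_identity,
        min_score=cfg.min_score,
    )
    hits, status = map_probes(probes, index, params)
    target_class = classify_probe_targets(hits, models)

    emit(hits, "probe_hits.tsv", chash, seed)
    emit(status, "probe_status.tsv", chash, seed)
    emit(target_class, "target_class.tsv", chash, seed)

    print("probe status:", status.status.value_counts().to_dict())
    print("target classes:", target_class.target_class.value_counts().to_dict())
    print("probes excluded as unreliably mapped are dropped from the study downstream")


if __name__ == "__main__":
    main()
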