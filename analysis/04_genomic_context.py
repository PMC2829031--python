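"""Genomic context of the ncRNAs: strand-aware classification against the
protein-coding genes (antisense / intronic / bidirectional / intergenic),
positional conservation against genome B through the ortholog map, and
intersection with enhancer elements and structure-prediction windows."""

from common import RUN, emit, load_config, read
from lncdev.annotation import read_bed, read_gff3
from lncdev.context import (
    classify_contexts,
    enhancer_summary,
    positional_conservation,
    structure_summary,
)


def main() -> None:
    cfg = load_config()
    chash, seed = cfg.sim.config_hash(), cfg.sim.seed
    inputs = RUN / "inputs"
    models_a = read_gff3(inputs / "annotation_a.gff3")
    models_b = read_gff3(inputs / "annotation_b.gff3")
    genes_a = [m for m in models_a if m.biotype == "protein_coding"]
    ncrnas_a = [m for m in models_a if m.biotype == "ncRNA"]
    orth = read("inputs/orthologs.tsv")
    enhancers = read_bed(inputs / "enhancers.bed")
    windows = read_bed(inputs / "structures.bed", extra=["P"])

    calls = classify_contexts(ncrnas_a, genes_a, cfg.bidirectional_window)
    cons = positional_conservation(
        calls, orth,
        [m for m in models_b if m.biotype == "ncRNA"],
        [m for m in models_b if m.biotype == "protein_coding"],
        cfg.bidirectional_window,
    )
    enh = enhancer_summary(ncrnas_a, enhancers, cfg.tss_window)
    struct = structure_summary(ncrnas_a, windows, cfg.structure_p)

    emit(calls, "context_calls.tsv", chash, seed)
    emit(cons, "conservation.tsv", chash, seed)
    emit(enh, "enhancer_assoc.tsv", chash, seed)
    emit(struct, "structure_summary.tsv", chash, seed)

    print("context classes:", calls.context_class.value_counts().to_dict())
    print(f"positionally conserved: {int(cons.conserved.sum())} "
          f"of {int(cons.evaluable.sum())} evaluable (intergenic loci have no anchor)")
    print(f"enhancer-associated ncRNAs: {int(enh.enhancer_assoc.sum())}")
    print(f"structured ncRNAs: {int((struct.n_windows_p90 > 0).sum())} at P > 0.9, "
          f"{int((struct.n_windows_p50 > 0).sum())} at P > 0.5 (exonic windows only)")

    truth = read("inputs/truth_context.tsv")
    merged = truth.merge(calls, on="ncrna_id", suffixes=("_planted", ""))
    acc = (merged.context_class_planted == merged.context_class).mean()
    print(f"planted-context recovery: {100*acc:.1f}%")


if __name__ == "__main__":
    main()
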