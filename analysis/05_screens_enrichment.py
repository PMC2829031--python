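"""Candidate-selection screens over the DE results: marker-correlated
ncRNA sets (Olig1/Mog/Melk templates, signed Pearson r), lineage-switch and
stage-exclusive selections, discordant ncRNA/host pairs, the GABAN-vs-OLP
switching table, and hypergeometric term enrichment of the DE gene lists."""

import pandas as pd

from common import emit, load_config, read
from lncdev.config import STAGES, TEMPLATE_MARKERS
from lncdev.screens import (
    StageProfiles,
    discordant_pair_screen,
    gaban_olp_switching,
    lineage_switch_screen,
    marker_correlation_screen,
    stage_exclusive_screen,
    term_enrichment,
)


def main() -> None:
    cfg = load_config()
    chash, seed = cfg.sim.config_hash(), cfg.sim.seed
    de = read("de_results.tsv")
    target_class = read("target_class.tsv")
    calls = read("context_calls.tsv")
    truth_probes = read("inputs/truth_probes.tsv")
    terms = read("inputs/terms.tsv")
    targets = read("inputs/probe_targets.tsv")

    cls = dict(zip(target_class.probe_id, target_class.target_class))
    is_ncrna = pd.Series({p: cls.get(p, "") == "noncoding" for p in de.probe_id.unique()})
    profiles = StageProfiles.from_de_table(de, is_ncrna=is_ncrna)

    markers = {
        row.template: row.probe_id
        for row in truth_probes.itertuples()
        if row.template_sign == 1 and not row.is_ncrna and row.template
    }
    rows = []
    for tmpl, marker_probe in sorted(markers.items()):
        pos, neg = marker_correlation_screen(profiles, marker_probe, cfg.r_threshold)
        name = TEMPLATE_MARKERS.get(tmpl, tmpl)
        print(f"{name}-correlated ncRNAs (r >= {cfg.r_threshold:.4f}): {len(pos.members)}; "
              f"anti-correlated: {len(neg.members)}")
        for res, kind in ((pos, "correlated"), (neg, "anticorrelated")):
            rows += [{"marker": name, "marker_probe": marker_probe,
                      "set": kind, "probe_id": p} for p in res.members]
    emit(pd.DataFrame(rows, columns=["marker", "marker_probe", "set", "probe_id"]),
         "marker_correlated.tsv", chash, seed)

    ls_rows = []
    for up, down, label in (("GABAN", ["OLP"], "up in GABAN, down in OL lineage"),
                            ("OLP", ["GABAN"], "up in OLP, down in GABAN")):
        res = lineage_switch_screen(profiles, up, down, strict=False)
        print(f"{label}: {len(res.members)} ncRNA/mRNA probes")
        ls_rows += [{"screen": f"{up}_up", "probe_id": p} for p in res.members]
    emit(pd.DataFrame(ls_rows, columns=["screen", "probe_id"]), "lineage_switch.tsv", chash, seed)

    excl = stage_exclusive_screen(profiles, "OLP")
    up = int((excl.stats.direction == 1).sum()) if len(excl.stats) else 0
    down = len(excl.members) - up
    print(f"DE only in OLPs: {len(excl.members)} ({up} up, {down} down)")
    emit(pd.DataFrame({"probe_id": excl.members}), "stage_exclusive_olp.tsv", chash, seed)

    pairs = discordant_pair_screen(calls, profiles)
    print("ncRNA/host pairs both DE:", pairs.label.value_counts().to_dict())
    emit(pairs, "discordant_pairs.tsv", chash, seed)
    emit(gaban_olp_switching(profiles), "gaban_olp_switching.tsv", chash, seed)

    gene_of = dict(zip(targets.probe_id, targets.target_id))
    coding = {p for p, c in cls.items() if c == "protein_coding"}
    universe = sorted({gene_of[p] for p in de.probe_id[de.expressed].unique() if p in coding})
    frames = []
    for contrast in STAGES:
        sub = de[(de.contrast == contrast) & de.de_call]
        for direction, sel in (("up", sub.M > 0), ("down", sub.M < 0)):
            glist = sorted({gene_of[p] for p in sub.probe_id[sel] if p in coding})
            glist = [g for g in glist if g in set(universe)]
            if not glist:
                continue
            res = term_enrichment(glist, universe, terms, cfg.enrichment_fdr)
            res.insert(0, "direction", direction)
            res.insert(0, "contrast", contrast)
            frames.append(res)
    enrichment = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    emit(enrichment, "enrichment.tsv", chash, seed)
    if len(enrichment):
        sig = enrichment[enrichment.significant]
        print(f"enriched terms at BH FDR < {cfg.enrichment_fdr}: {len(sig)} "
              f"across {sig.contrast.nunique() if len(sig) else 0} contrasts")


if __name__ == "__main__":
    main()
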