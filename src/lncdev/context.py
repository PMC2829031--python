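"""Strand-aware genomic context of ncRNAs relative to protein-coding genes.

Classes, in precedence order: antisense (>= 1 nt exon-exon overlap on the
opposite strand), intronic sense/antisense (ncRNA wholly within one intron),
bidirectional (divergent head-to-head promoters within a window), else
intergenic.  All qualifying relationships are retained alongside the primary
call; ties within the winning class resolve to the lexicographically
smallest gene id so the call never depends on input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .annotation import TranscriptModel

ANTISENSE = "antisense"
INTRONIC_SENSE = "intronic_sense"
INTRONIC_ANTISENSE = "intronic_antisense"
BIDIRECTIONAL = "bidirectional"
INTERGENIC = "intergenic"

_PRECEDENCE = {ANTISENSE: 0, INTRONIC_SENSE: 1, INTRONIC_ANTISENSE: 1, BIDIRECTIONAL: 2}


@dataclass
class ContextCall:
    ncrna_id: str
    context_class: str
    host_gene_id: str | None = None
    distance_to_tss: int | None = None  # bidirectional only
    all_matches: list[tuple[str, str]] = field(default_factory=list)


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _tss_gap(ncrna: TranscriptModel, gene: TranscriptModel) -> int | None:
    """Distance between divergent head-to-head TSSs, or None if the pair is
    not in bidirectional arrangement (overlapping, convergent, or the gene
    lies on the ncRNA's downstream side)."""
    if ncrna.strand == gene.strand:
        return None
    if _overlap((ncrna.start, ncrna.end), (gene.start, gene.end)):
        return None
    if gene.strand == "+" and ncrna.strand == "-" and ncrna.end <= gene.start:
        return gene.start - ncrna.end + 1
    if gene.strand == "-" and ncrna.strand == "+" and gene.end <= ncrna.start:
        return ncrna.start - gene.end + 1
    return None


def classify_context(
    ncrna: TranscriptModel,
    genes: list[TranscriptModel],
    bidirectional_window: int = 1000,
) -> ContextCall:
    """Classify one ncRNA against a set of protein-coding genes."""
    matches: list[tuple[str, str, int | None]] = []  # (class, gene, distance)
    for g in genes:
        if g.chrom != ncrna.chrom:
            continue
        if g.strand != ncrna.strand and any(
            _overlap(ne, ge) for ne in ncrna.exons for ge in g.exons
        ):
            matches.append((ANTISENSE, g.gene_id, None))
        for i0, i1 in g.introns():
            if i0 <= ncrna.start and ncrna.end <= i1:
                cls = INTRONIC_SENSE if ncrna.strand == g.strand else INTRONIC_ANTISENSE
                matches.append((cls, g.gene_id, None))
                break
        gap = _tss_gap(ncrna, g)
        if gap is not None and 0 < gap <= bidirectional_window:
            matches.append((BIDIRECTIONAL, g.gene_id, gap))

    if not matches:
        return ContextCall(ncrna.gene_id, INTERGENIC, host_gene_id=None)
    best_rank = min(_PRECEDENCE[c] for c, _, _ in matches)
    winners = [m for m in matches if _PRECEDENCE[m[0]] == best_rank]
    # deterministic tie-break: nearest TSS first for bidirectional, then id
    winners.sort(key=lambda m: (m[2] if m[2] is not None else 0, m[1], m[0]))
    cls, host, dist = winners[0]
    return ContextCall(
        ncrna.gene_id,
        cls,
        host_gene_id=host,
        distance_to_tss=dist,
        all_matches=sorted((c, g) for c, g, _ in matches),
    )


def classify_contexts(
    ncrnas: list[TranscriptModel],
    genes: list[TranscriptModel],
    bidirectional_window: int = 1000,
) -> pd.DataFrame:
    rows = []
    for nc in ncrnas:
        call = classify_context(nc, genes, bidirectional_window)
        rows.append(
            {
                "ncrna_id": call.ncrna_id,
                "context_class": call.context_class,
                "host_gene": call.host_gene_id or "",
                "distance_to_tss": call.distance_to_tss,
                "all_matches": ";".join(f"{c}:{g}" for c, g in call.all_matches),
            }
        )
    return pd.DataFrame(
        rows, columns=["ncrna_id", "context_class", "host_gene", "distance_to_tss", "all_matches"]
    )


# ---------------------------------------------------------------------------
# positional conservation
# ---------------------------------------------------------------------------

@dataclass
class ConservationCall:
    ncrna_id: str
    conserved: bool
    evaluable: bool
    counterpart_id: str | None = None
    counterpart_class: str | None = None


def positional_conservation(
    context_calls: pd.DataFrame,
    ortholog_map: pd.DataFrame,
    ncrnas_b: list[TranscriptModel],
    genes_b: list[TranscriptModel],
    bidirectional_window: int = 1000,
) -> pd.DataFrame:
    """A ncRNA is positionally conserved when some ncRNA in the second
    genome receives the same context class relative to the ortholog of its
    host gene.  Intergenic ncRNAs have no anchor and are not evaluable;
    likewise hosts without an ortholog."""
    calls_b = classify_contexts(ncrnas_b, genes_b, bidirectional_window)
    orth = dict(zip(ortholog_map.gene_a, ortholog_map.gene_b))
    by_host_class: dict[tuple[str, str], str] = {}
    for row in calls_b.itertuples():
        if row.host_gene:
            by_host_class.setdefault((row.host_gene, row.context_class), row.ncrna_id)
    rows = []
    for row in context_calls.itertuples():
        if row.context_class == INTERGENIC or not row.host_gene:
            rows.append((row.ncrna_id, False, False, "", ""))
            continue
        host_b = orth.get(row.host_gene)
        if host_b is None:
            rows.append((row.ncrna_id, False, False, "", ""))
            continue
        counterpart = by_host_class.get((host_b, row.context_class))
        if counterpart is None:
            rows.append((row.ncrna_id, False, True, "", ""))
        else:
            rows.append((row.ncrna_id, True, True, counterpart, row.context_class))
    return pd.DataFrame(
        rows, columns=["ncrna_id", "conserved", "evaluable", "counterpart_id", "counterpart_class"]
    )


# ---------------------------------------------------------------------------
# enhancer association and structure intersection
# ---------------------------------------------------------------------------

def associate_enhancer(
    ncrna: TranscriptModel, enhancers: pd.DataFrame, tss_window: int = 5000
) -> pd.DataFrame:
    """Enhancers overlapping the ncRNA locus (distance 0) or whose nearest
    base lies within ``tss_window`` bp of its TSS."""
    rows = []
    tss = ncrna.tss
    for e in enhancers.itertuples():
        if e.chrom != ncrna.chrom:
            continue
        if _overlap((e.start, e.end), (ncrna.start, ncrna.end)):
            dist = 0
        elif e.start <= tss < e.end:
            dist = 0
        elif e.end <= tss:
            dist = tss - e.end + 1
        else:
            dist = e.start - tss
        if dist <= tss_window:
            rows.append({"ncrna_id": ncrna.gene_id, "enhancer": e.name, "distance": dist, "score": e.score})
    return pd.DataFrame(rows, columns=["ncrna_id", "enhancer", "distance", "score"])


def intersect_structures(
    ncrna: TranscriptModel, windows: pd.DataFrame, threshold: float = 0.9
) -> tuple[bool, pd.DataFrame]:
    """Structured iff >= 1 window with P strictly above the threshold
    overlaps >= 1 ncRNA exon (exonic overlap required; intron-only windows
    never qualify).  Returns (flag, supporting windows with exon overlap)."""
    if ((windows.P < 0) | (windows.P > 1)).any():
        raise ValueError("structure window P outside [0, 1]")
    rows = []
    for w in windows.itertuples():
        if w.chrom != ncrna.chrom:
            continue
        if any(_overlap((w.start, w.end), ex) for ex in ncrna.exons):
            rows.append({"ncrna_id": ncrna.gene_id, "window": w.name, "P": w.P})
    support = pd.DataFrame(rows, columns=["ncrna_id", "window", "P"])
    structured = bool((support.P > threshold).any()) if len(support) else False
    return structured, support


def structure_summary(
    ncrnas: list[TranscriptModel], windows: pd.DataFrame, threshold: float = 0.9
) -> pd.DataFrame:
    """Per-ncRNA structured flag at the working threshold plus supporting
    window counts at the two conventional confidence levels (0.5, 0.9)."""
    rows = []
    for nc in ncrnas:
        structured, support = intersect_structures(nc, windows, threshold)
        rows.append(
            {
                "ncrna_id": nc.gene_id,
                "structured": structured,
                "n_windows_p50": int((support.P > 0.5).sum()),
                "n_windows_p90": int((support.P > 0.9).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["ncrna_id", "structured", "n_windows_p50", "n_windows_p90"])


def enhancer_summary(
    ncrnas: list[TranscriptModel], enhancers: pd.DataFrame, tss_window: int = 5000
) -> pd.DataFrame:
    rows = []
    for nc in ncrnas:
        matches = associate_enhancer(nc, enhancers, tss_window)
        rows.append(
            {
                "ncrna_id": nc.gene_id,
                "enhancer_assoc": len(matches) > 0,
                "n_enhancers": len(matches),
                "enhancers": ";".join(matches.enhancer),
            }
        )
    return pd.DataFrame(rows, columns=["ncrna_id", "enhancer_assoc", "n_enhancers", "enhancers"])
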