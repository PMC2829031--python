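"""Independent brute-force oracles used by the tests and the acceptance
script.  These deliberately re-derive results from first principles
(exhaustive scans, plain nested loops, enumeration) without sharing logic
with the package implementation."""

from __future__ import annotations

from itertools import combinations

import numpy as np

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# exhaustive sliding-window probe mapping
# ---------------------------------------------------------------------------

def sliding_window_hits(
    sequence: str,
    genomes: dict[str, str],
    min_identity: float = 99.0,
    min_score: int = 50,
    ambiguity_window: int = 1,
):
    """All-position, both-strand Hamming scan.  Returns (status, accepted
    hit set) where accepted hits are (chrom, start, strand) after applying
    the identity/score filters and the near-best ambiguity rule."""
    L = len(sequence)
    scored = []
    for chrom, g in genomes.items():
        garr = np.frombuffer(g.encode(), dtype=np.uint8)
        if len(garr) < L:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(garr, L)
        for strand, query in (("+", sequence), ("-", rc(sequence))):
            qarr = np.frombuffer(query.encode(), dtype=np.uint8)
            mism = (windows != qarr).sum(axis=1)
            n_amb = sum(c not in "ACGT" for c in query)  # N never matches
            for pos in np.flatnonzero(mism <= L - min_score):  # coarse cut
                mm = int(mism[pos])
                # positions where the query has N but genome coincidentally
                # equals the byte are impossible (genome is ACGT); recount
                if n_amb:
                    mm = sum(
                        a != b or a not in "ACGT"
                        for a, b in zip(query, g[pos : pos + L])
                    )
                matches = L - mm
                identity = 100.0 * matches / L
                score = matches - mm
                ok = identity >= min_identity and score >= min_score
                scored.append((chrom, int(pos), strand, score, ok))
    accepted = [h for h in scored if h[4]]
    if not accepted:
        return ("unmapped", set())
    best = max(h[3] for h in accepted)
    near = [h for h in accepted if h[3] >= best - ambiguity_window]
    if len(near) > 1:
        return ("rejected_ambiguous", set())
    return ("accepted", {(h[0], h[1], h[2]) for h in near})


# ---------------------------------------------------------------------------
# brute-force genomic context rules
# ---------------------------------------------------------------------------

def brute_force_context(nc, genes, window: int = 1000) -> tuple[str, str | None]:
    """Plain-loop re-derivation of the context classification (class,
    host).  ``nc`` and each gene expose chrom/start/end/strand/exons and
    introns() like the package's transcript model."""
    antisense, intronic, bidirectional = [], [], []
    for g in genes:
        if g.chrom != nc.chrom:
            continue
        if g.strand != nc.strand:
            hit = False
            for ns, ne in nc.exons:
                for gs, ge in g.exons:
                    if ns < ge and gs < ne:
                        hit = True
            if hit:
                antisense.append(g.gene_id)
        for i0, i1 in g.introns():
            if i0 <= nc.start and nc.end <= i1:
                cls = "intronic_sense" if nc.strand == g.strand else "intronic_antisense"
                intronic.append((g.gene_id, cls))
                break
        if g.strand != nc.strand and not (nc.start < g.end and g.start < nc.end):
            d = None
            if g.strand == "+" and nc.strand == "-" and nc.end <= g.start:
                d = g.start - nc.end + 1
            if g.strand == "-" and nc.strand == "+" and g.end <= nc.start:
                d = nc.start - g.end + 1
            if d is not None and 0 < d <= window:
                bidirectional.append((d, g.gene_id))
    if antisense:
        return "antisense", sorted(antisense)[0]
    if intronic:
        host, cls = sorted(intronic)[0]
        return cls, host
    if bidirectional:
        return "bidirectional", sorted(bidirectional)[0][1]
    return "intergenic", None


def random_loci(rng: np.random.Generator, n_genes: int, n_ncrnas: int, chrom_len: int):
    """Random gene and ncRNA models for oracle-vs-implementation trials."""
    from lncdev.annotation import NCRNA, PROTEIN_CODING, TranscriptModel

    genes, ncrnas = [], []
    for i in range(n_genes):
        start = int(rng.integers(0, chrom_len - 6000))
        e1 = int(rng.integers(200, 500))
        i1 = int(rng.integers(200, 1500))
        e2 = int(rng.integers(200, 500))
        i2 = int(rng.integers(200, 1500))
        e3 = int(rng.integers(200, 500))
        exons = [
            (start, start + e1),
            (start + e1 + i1, start + e1 + i1 + e2),
            (start + e1 + i1 + e2 + i2, start + e1 + i1 + e2 + i2 + e3),
        ]
        genes.append(
            TranscriptModel(
                gene_id=f"rg{i:04d}", chrom="chrR", start=exons[0][0], end=exons[-1][1],
                strand=str(rng.choice(["+", "-"])), biotype=PROTEIN_CODING,
                exons=exons, cds=list(exons),
            )
        )
    for i in range(n_ncrnas):
        start = int(rng.integers(0, chrom_len - 3000))
        if rng.random() < 0.5:
            exons = [(start, start + int(rng.integers(150, 800)))]
        else:
            l1 = int(rng.integers(100, 400))
            gap = int(rng.integers(80, 400))
            l2 = int(rng.integers(100, 400))
            exons = [(start, start + l1), (start + l1 + gap, start + l1 + gap + l2)]
        ncrnas.append(
            TranscriptModel(
                gene_id=f"rn{i:04d}", chrom="chrR", start=exons[0][0], end=exons[-1][1],
                strand=str(rng.choice(["+", "-"])), biotype=NCRNA, exons=exons,
            )
        )
    return genes, ncrnas


# ---------------------------------------------------------------------------
# exact enumeration for the hypergeometric tail
# ---------------------------------------------------------------------------

def hypergeom_tail_enumeration(n_universe: int, term_size: int, list_size: int, k: int) -> float:
    """P(overlap >= k) by enumerating every list of ``list_size`` drawn from
    the universe (feasible for n_universe <= 12)."""
    universe = range(n_universe)
    term = set(range(term_size))
    total = hits = 0
    for pick in combinations(universe, list_size):
        total += 1
        if len(term & set(pick)) >= k:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# screen membership derived from planted truth
# ---------------------------------------------------------------------------

def truth_screen_members(lfc, kind: str, **kw) -> set[str]:
    """Expected screen membership from the planted log2 fold-change matrix
    (DE truth = nonzero lfc), derived directly from the screen definitions."""
    de = lfc != 0
    if kind == "lineage_switch":
        up, down = kw["up"], kw["down"]
        sel = de[up] & (lfc[up] > 0) & de[down] & (lfc[down] < 0)
        return set(lfc.index[sel])
    if kind == "stage_exclusive":
        c = kw["contrast"]
        others = [x for x in lfc.columns if x != c]
        sel = de[c] & ~de[others].any(axis=1)
        return set(lfc.index[sel])
    raise ValueError(kind)
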