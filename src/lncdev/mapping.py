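"""Seed-and-extend probe mapping and probe target classification.

Short oligonucleotide probes (65/70-mers) are aligned ungapped to a genome:
at 99% identity a 65-mer tolerates zero gaps in practice, so seed-and-extend
with exact k-mer seeds on both strands recovers every hit that could pass
the filters.  Probes with more than one accepted hit within one score point
of the best are treated as unreliably mapped and excluded, mirroring how
ambiguous probes are dropped from array re-annotation pipelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation import NCRNA, PROTEIN_CODING, TranscriptModel, revcomp

ACCEPTED = "accepted"
REJECTED_IDENTITY = "rejected_identity"
REJECTED_SCORE = "rejected_score"
REJECTED_AMBIGUOUS = "rejected_ambiguous"
UNMAPPED = "unmapped"


@dataclass
class MapperParams:
    seed_length: int = 11
    min_identity: float = 99.0
    min_score: int = 50
    max_hits_reported: int | None = None
    ambiguity_window: int = 1  # accepted hits within best-1 => all ambiguous

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 100:
            raise ValueError("min_identity must be in (0, 100]")
        if self.seed_length < 4:
            raise ValueError("seed_length must be >= 4")


@dataclass
class ProbeHit:
    probe_id: str
    chrom: str
    start: int  # forward-strand coordinates, 0-based half-open
    end: int
    strand: str  # strand of the targeted transcript
    matches: int
    mismatches: int
    identity: float
    score: int
    status: str


_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i


class GenomeIndex:
    """Sorted k-mer position index over forward-strand chromosome sequence."""

    def __init__(self, sequences: dict[str, str], seed_length: int = 11):
        self.seed_length = seed_length
        self.sequences = sequences
        self._codes: dict[str, np.ndarray] = {}
        self._order: dict[str, np.ndarray] = {}
        k = seed_length
        for chrom, seq in sequences.items():
            if len(seq) < k:
                continue
            enc = _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            n = len(seq) - k + 1
            codes = np.zeros(n, dtype=np.int64)
            valid = np.ones(n, dtype=bool)
            for j in range(k):
                win = enc[j : j + n]
                valid &= win != 255
                codes = (codes << 2) | np.where(win == 255, 0, win).astype(np.int64)
            codes[~valid] = -1
            order = np.argsort(codes, kind="stable")
            self._codes[chrom] = codes[order]
            self._order[chrom] = order

    def _encode_kmer(self, kmer: str) -> int | None:
        code = 0
        for ch in kmer:
            v = _ENCODE[ord(ch)]
            if v == 255:
                return None
            code = (code << 2) | int(v)
        return code

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        code = self._encode_kmer(kmer)
        if code is None:
            return []
        out = []
        for chrom, codes in self._codes.items():
            lo = np.searchsorted(codes, code, side="left")
            hi = np.searchsorted(codes, code, side="right")
            out += [(chrom, int(p)) for p in self._order[chrom][lo:hi]]
        return out


def _hamming(a: str, b: str) -> int:
    # N (or any non-ACGT symbol) never matches
    return sum(x != y or x not in "ACGT" for x, y in zip(a, b))


def map_probe(
    sequence: str,
    index: GenomeIndex,
    params: MapperParams | None = None,
    probe_id: str = "",
) -> list[ProbeHit]:
    """Map one probe on both strands.  Returns every extended hit with its
    acceptance/rejection status ([] when the sequence is shorter than the
    seed or no seed matches)."""
    params = params or MapperParams()
    k = params.seed_length
    L = len(sequence)
    if L < k:
        return []
    candidates: set[tuple[str, int, str]] = set()
    for strand, query in (("+", sequence), ("-", revcomp(sequence))):
        offsets = list(range(0, L - k + 1, k))
        if offsets[-1] != L - k:
            offsets.append(L - k)
        for off in offsets:
            for chrom, pos in index.positions(query[off : off + k]):
                start = pos - off
                if 0 <= start <= len(index.sequences[chrom]) - L:
                    candidates.add((chrom, start, strand))

    hits = []
    for chrom, start, strand in sorted(candidates):
        query = sequence if strand == "+" else revcomp(sequence)
        target = index.sequences[chrom][start : start + L]
        mm = _hamming(query, target)
        matches = L - mm
        identity = 100.0 * matches / L
        score = matches - mm
        if identity < params.min_identity:
            status = REJECTED_IDENTITY
        elif score < params.min_score:
            status = REJECTED_SCORE
        else:
            status = ACCEPTED
        hits.append(
            ProbeHit(probe_id, chrom, start, start + L, strand, matches, mm, identity, score, status)
        )

    accepted = [h for h in hits if h.status == ACCEPTED]
    if accepted:
        best = max(h.score for h in accepted)
        near_best = [h for h in accepted if h.score >= best - params.ambiguity_window]
        if len(near_best) > 1:
            for h in near_best:
                h.status = REJECTED_AMBIGUOUS
    hits.sort(key=lambda h: (-h.score, h.chrom, h.start, h.strand))
    if params.max_hits_reported is not None:
        hits = hits[: params.max_hits_reported]
    return hits


def map_probes(
    probes: pd.DataFrame, index: GenomeIndex, params: MapperParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Map a probe table (probe_id, sequence).  Returns (hit table, per-probe
    status table); probes with no extended hit are reported unmapped."""
    params = params or MapperParams()
    hit_rows, status_rows = [], []
    for row in probes.itertuples():
        hits = map_probe(row.sequence, index, params, probe_id=row.probe_id)
        for h in hits:
            hit_rows.append(h.__dict__)
        n_acc = sum(h.status == ACCEPTED for h in hits)
        if not hits:
            status = UNMAPPED
        elif n_acc == 1:
            status = ACCEPTED
        elif any(h.status == REJECTED_AMBIGUOUS for h in hits):
            status = REJECTED_AMBIGUOUS
        else:
            status = UNMAPPED
        status_rows.append({"probe_id": row.probe_id, "status": status, "n_hits": len(hits)})
    hit_cols = [
        "probe_id", "chrom", "start", "end", "strand",
        "matches", "mismatches", "identity", "score", "status",
    ]
    hits_df = pd.DataFrame(hit_rows, columns=hit_cols)
    return hits_df, pd.DataFrame(status_rows)


# ---------------------------------------------------------------------------
# target classification
# ---------------------------------------------------------------------------

PROTEIN_CODING_CLASS = "protein_coding"
NONCODING_CLASS = "noncoding"
EXCLUDED_CLASS = "excluded"


@dataclass
class TargetClass:
    probe_id: str
    target_class: str
    evidence: list[str] = field(default_factory=list)
    reason: str = ""


class AnnotationIndex:
    """Strand-aware interval trees over CDS exons and ncRNA exons."""

    def __init__(self, models: list[TranscriptModel]):
        self._cds: dict[tuple[str, str], IntervalTree] = {}
        self._nc_exons: dict[tuple[str, str], IntervalTree] = {}
        for m in models:
            if m.biotype == PROTEIN_CODING:
                tree = self._cds.setdefault((m.chrom, m.strand), IntervalTree())
                for s, e in m.cds:
                    tree[s:e] = m.gene_id
            elif m.biotype == NCRNA:
                tree = self._nc_exons.setdefault((m.chrom, m.strand), IntervalTree())
                for s, e in m.exons:
                    tree[s:e] = m.gene_id

    def _query(self, trees, chrom, strand, start, end) -> list[str]:
        tree = trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted({iv.data for iv in tree.overlap(start, end)})

    def cds_overlaps(self, chrom, strand, start, end) -> list[str]:
        return self._query(self._cds, chrom, strand, start, end)

    def ncrna_overlaps(self, chrom, strand, start, end) -> list[str]:
        return self._query(self._nc_exons, chrom, strand, start, end)


def classify_probe_target(
    hits: list[ProbeHit], index: AnnotationIndex, probe_id: str = ""
) -> TargetClass:
    """Classify a mapped probe's target as protein-coding or noncoding.

    Requires exactly one accepted hit; the hit's strand must match the
    overlapped feature's strand (a probe on the strand opposite a CDS that
    matches an annotated antisense ncRNA exon is noncoding).
    """
    accepted = [h for h in hits if h.status == ACCEPTED]
    pid = probe_id or (hits[0].probe_id if hits else "")
    if len(accepted) != 1:
        reason = "unmapped" if not hits else (
            REJECTED_AMBIGUOUS
            if any(h.status == REJECTED_AMBIGUOUS for h in hits)
            else "no accepted hit"
        )
        return TargetClass(pid, EXCLUDED_CLASS, reason=reason)
    h = accepted[0]
    cds = index.cds_overlaps(h.chrom, h.strand, h.start, h.end)
    if cds:
        return TargetClass(pid, PROTEIN_CODING_CLASS, evidence=cds)
    nc = index.ncrna_overlaps(h.chrom, h.strand, h.start, h.end)
    if nc:
        return TargetClass(pid, NONCODING_CLASS, evidence=nc)
    return TargetClass(pid, EXCLUDED_CLASS, reason="no qualifying feature overlap")


def classify_probe_targets(
    hits_df: pd.DataFrame, models: list[TranscriptModel]
) -> pd.DataFrame:
    index = AnnotationIndex(models)
    out = []
    for pid, grp in hits_df.groupby("probe_id", sort=True):
        hits = [ProbeHit(**rec) for rec in grp.to_dict("records")]
        tc = classify_probe_target(hits, index, probe_id=pid)
        out.append(
            {
                "probe_id": pid,
                "target_class": tc.target_class,
                "evidence": ",".join(tc.evidence),
                "reason": tc.reason,
            }
        )
    return pd.DataFrame(out, columns=["probe_id", "target_class", "evidence", "reason"])
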