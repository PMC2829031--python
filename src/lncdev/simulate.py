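"""Synthetic study generator.

Emulates the full design the downstream analysis assumes: two synthetic
genomes with planted ncRNA/gene genomic relationships and conserved
counterparts, probe pools extracted from transcript sequence, two-colour
reference-design spot intensities with planted differential expression, and
TSA-response qPCR Ct tables under two culture arms.  Every draw flows from a
single seed, so identical configuration + seed reproduce byte-identical
output files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import NCRNA, PROTEIN_CODING, SyntheticGenome, TranscriptModel, revcomp
from .config import STAGES, TEMPLATES, SimConfig

log = logging.getLogger(__name__)

# fixed genome layout (bp): one locus per slot, >= 5 kb between loci unless a
# context class requires overlap/adjacency
SLOT = 15_000
GENE_OFFSET = 6_000
EXON_LEN = 300
INTRON_LEN = 1_000
GENE_SPAN = 3 * EXON_LEN + 2 * INTRON_LEN  # 2900
GENOME_B_SHIFT = 10_000

# deterministic per-stage seed offsets (fanned out from config.seed)
SEED_ANNOTATION = 1
SEED_PROBES = 2
SEED_TRUTH = 3
SEED_EXPRESSION = 4
SEED_QPCR = 5
SEED_TERMS = 6


def _rng(config: SimConfig, offset: int, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    return np.random.default_rng((base + offset) % (2**31))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    return alphabet[rng.integers(0, 4, size=length)].tobytes().decode()


def _largest_remainder(proportions: dict[str, float], total: int) -> dict[str, int]:
    raw = {k: v * total for k, v in proportions.items()}
    counts = {k: int(np.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (raw[k] - counts[k], k), reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    genome_a: SyntheticGenome
    genome_b: SyntheticGenome
    ortholog_map: pd.DataFrame  # gene_a, gene_b
    enhancers: pd.DataFrame  # BED6
    structure_windows: pd.DataFrame  # BED6 + P
    context_truth: pd.DataFrame  # per-ncRNA planted ground truth


def _gene_model(gene_id: str, chrom: str, g0: int, strand: str) -> TranscriptModel:
    exons = [
        (g0, g0 + EXON_LEN),
        (g0 + EXON_LEN + INTRON_LEN, g0 + 2 * EXON_LEN + INTRON_LEN),
        (g0 + 2 * (EXON_LEN + INTRON_LEN), g0 + GENE_SPAN),
    ]
    return TranscriptModel(
        gene_id=gene_id,
        chrom=chrom,
        start=g0,
        end=g0 + GENE_SPAN,
        strand=strand,
        biotype=PROTEIN_CODING,
        exons=exons,
        cds=list(exons),
    )


def _ncrna_model(
    nc_id: str, chrom: str, rec: dict, host: TranscriptModel | None, shift: int
) -> TranscriptModel:
    """Materialize one ncRNA locus from its abstract placement record."""
    cls = rec["class"]
    if cls == "antisense":
        g0 = host.start
        start = g0 + EXON_LEN + INTRON_LEN - 100  # overlaps middle exon
        exons = [(start, start + 500)]
        strand = "-" if host.strand == "+" else "+"
    elif cls == "intronic":
        intron_start = host.exons[0][1]
        start = intron_start + 300
        exons = [(start, start + 400)]
        same = rec["orientation"] == "sense"
        strand = host.strand if same else ("-" if host.strand == "+" else "+")
    elif cls == "bidirectional":
        gap = rec["gap"]
        if host.strand == "+":
            end = host.start - gap
            exons = [(end - 600, end)]
            strand = "-"
        else:
            start = host.end + gap
            exons = [(start, start + 600)]
            strand = "+"
        start = exons[0][0]
    elif cls == "intergenic":
        start = rec["slot"] * SLOT + 7_000 + shift
        exons = [(start, start + 250), (start + 350, start + 600)]
        strand = rec["strand"]
    else:  # pragma: no cover
        raise ValueError(f"unknown context class {cls!r}")
    return TranscriptModel(
        gene_id=nc_id,
        chrom=chrom,
        start=exons[0][0],
        end=exons[-1][1],
        strand=strand,
        biotype=NCRNA,
        exons=exons,
    )


def simulate_annotation(config: SimConfig, seed: int | None = None) -> AnnotationBundle:
    """Generate two annotated genomes, an ortholog map, enhancer and
    structure-prediction windows, and the planted context ground truth.

    Genome B carries orthologs of every gene and, for the configured
    conserved fraction of anchored ncRNAs, a counterpart in the same context
    class relative to the ortholog of the host gene.
    """
    rng = _rng(config, SEED_ANNOTATION, seed)
    counts = _largest_remainder(config.context_proportions, config.n_ncrnas)
    n_anchored = counts["antisense"] + counts["intronic"] + counts["bidirectional"]
    if n_anchored > config.n_genes:
        raise ValueError(
            f"placement failure: {n_anchored} anchored ncRNAs need distinct "
            f"host genes but only {config.n_genes} genes are configured"
        )

    gene_strands = rng.choice(["+", "-"], size=config.n_genes)

    # abstract placement records, shared between the two genomes
    records: list[dict] = []
    host_idx = 0
    for cls in ("antisense", "intronic", "bidirectional"):
        for _ in range(counts[cls]):
            rec = {"class": cls, "host": host_idx}
            if cls == "intronic":
                rec["orientation"] = str(rng.choice(["sense", "antisense"]))
            if cls == "bidirectional":
                rec["gap"] = int(rng.integers(100, 901))
            records.append(rec)
            host_idx += 1
    n_intergenic = counts["intergenic"]
    for j in range(n_intergenic):
        records.append(
            {
                "class": "intergenic",
                "host": None,
                "slot": config.n_genes + j,
                "strand": str(rng.choice(["+", "-"])),
            }
        )

    anchored = [i for i, r in enumerate(records) if r["host"] is not None]
    conserved_flags = np.zeros(len(records), dtype=bool)
    if anchored:
        conserved_flags[anchored] = rng.random(len(anchored)) < config.conserved_fraction

    bg_slot0 = config.n_genes + n_intergenic
    n_slots = bg_slot0 + config.n_background_enhancers + config.n_background_structures
    chrom_len = (n_slots + 1) * SLOT

    def build(prefix: str, chrom: str, shift: int, keep: np.ndarray) -> SyntheticGenome:
        models = []
        for i in range(config.n_genes):
            g0 = i * SLOT + GENE_OFFSET + shift
            models.append(_gene_model(f"{prefix}{i + 1:04d}", chrom, g0, gene_strands[i]))
        genes = list(models)
        for i, rec in enumerate(records):
            if not keep[i]:
                continue
            host = genes[rec["host"]] if rec["host"] is not None else None
            models.append(
                _ncrna_model(f"nc{prefix}{i + 1:04d}", chrom, rec, host, shift)
            )
        seq = _random_sequence(rng, chrom_len + shift)
        return SyntheticGenome(sequences={chrom: seq}, models=models)

    keep_a = np.ones(len(records), dtype=bool)
    keep_b = conserved_flags.copy()  # only conserved ncRNAs have counterparts
    genome_a = build("gA", "chrA", 0, keep_a)
    genome_b = build("gB", "chrB", GENOME_B_SHIFT, keep_b)

    ortholog_map = pd.DataFrame(
        {
            "gene_a": [f"gA{i + 1:04d}" for i in range(config.n_genes)],
            "gene_b": [f"gB{i + 1:04d}" for i in range(config.n_genes)],
        }
    )

    # per-ncRNA planted truth (classes resolved to their oriented form)
    genes_a = genome_a.genes()
    rows = []
    for i, rec in enumerate(records):
        nc_id = f"ncgA{i + 1:04d}"
        host = genes_a[rec["host"]] if rec["host"] is not None else None
        cls = rec["class"]
        if cls == "intronic":
            cls = "intronic_sense" if rec["orientation"] == "sense" else "intronic_antisense"
        rows.append(
            {
                "ncrna_id": nc_id,
                "context_class": cls,
                "host_gene": host.gene_id if host else "",
                "conserved": bool(conserved_flags[i]),
                "counterpart_id": f"ncgB{i + 1:04d}" if conserved_flags[i] else "",
            }
        )
    context_truth = pd.DataFrame(rows)

    ncrnas_a = {m.gene_id: m for m in genome_a.ncrnas()}

    # enhancers: a planted subset overlapping ncRNA first exons, the rest in
    # dedicated empty slots far from every locus
    n_nc = len(context_truth)
    enh_flags = rng.random(n_nc) < config.enhancer_fraction
    enh_rows = []
    for i, flagged in enumerate(enh_flags):
        if not flagged:
            continue
        nc = ncrnas_a[context_truth.ncrna_id[i]]
        s = nc.exons[0][0] + 50
        enh_rows.append(("chrA", s, s + 100, f"enh_{nc.gene_id}", int(rng.integers(300, 900)), "."))
    for j in range(config.n_background_enhancers):
        s = (bg_slot0 + j) * SLOT + 7_000
        enh_rows.append(("chrA", s, s + 200, f"enh_bg{j + 1:03d}", int(rng.integers(100, 900)), "."))
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end", "name", "score", "strand"])

    # structure-prediction windows: high-confidence exonic (structured), mid
    # confidence exonic, high-P intron-only decoys, and background windows
    hi_flags = rng.random(n_nc) < config.structured_hi_fraction
    mid_flags = (~hi_flags) & (rng.random(n_nc) < config.structured_mid_fraction)
    win_rows = []
    for i in range(n_nc):
        nc = ncrnas_a[context_truth.ncrna_id[i]]
        s = nc.exons[0][0] + 100
        if hi_flags[i]:
            win_rows.append(("chrA", s, s + 120, f"win_{nc.gene_id}", 0, nc.strand, float(rng.uniform(0.92, 0.995))))
        elif mid_flags[i]:
            win_rows.append(("chrA", s, s + 120, f"win_{nc.gene_id}", 0, nc.strand, float(rng.uniform(0.55, 0.85))))
        if len(nc.exons) > 1 and rng.random() < 0.3:
            # intron-only window: high P but no exon overlap
            intron_s = nc.exons[0][1]
            win_rows.append(("chrA", intron_s + 10, intron_s + 90, f"win_intron_{nc.gene_id}", 0, nc.strand, float(rng.uniform(0.9, 0.99))))
    for j in range(config.n_background_structures):
        s = (bg_slot0 + config.n_background_enhancers + j) * SLOT + 7_000
        win_rows.append(("chrA", s, s + 120, f"win_bg{j + 1:03d}", 0, ".", float(rng.uniform(0.0, 1.0))))
    structure_windows = pd.DataFrame(
        win_rows, columns=["chrom", "start", "end", "name", "score", "strand", "P"]
    )
    context_truth["enhancer_assoc"] = enh_flags
    context_truth["structured"] = hi_flags

    return AnnotationBundle(
        genome_a=genome_a,
        genome_b=genome_b,
        ortholog_map=ortholog_map,
        enhancers=enhancers,
        structure_windows=structure_windows,
        context_truth=context_truth,
    )


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def simulate_probes(
    bundle: AnnotationBundle, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Design one probe per transcript (65-mers on mRNAs, 70-mers on ncRNAs)
    plus negative-control probes matching neither genome.

    Probes are extracted from exonic sequence (wholly within one exon, so
    they align ungapped).  Transcripts shorter than the probe are skipped
    with a warning.
    """
    rng = _rng(config, SEED_PROBES, seed)
    chrom_a = bundle.genome_a.sequences["chrA"]
    rows = []
    for m in bundle.genome_a.models:
        plen = config.probe_len_ncrna if m.biotype == NCRNA else config.probe_len_mrna
        eligible = [(s, e) for s, e in m.exons if e - s >= plen]
        if m.spliced_length() < plen or not eligible:
            log.warning("transcript %s shorter than probe length, skipped", m.gene_id)
            continue
        s, e = eligible[int(rng.integers(0, len(eligible)))]
        off = int(rng.integers(0, e - s - plen + 1))
        gstart = s + off
        sub = chrom_a[gstart : gstart + plen]
        seq = sub if m.strand == "+" else revcomp(sub)
        rows.append(
            {
                "probe_id": f"p_{m.gene_id}",
                "target_id": m.gene_id,
                "is_ncrna": m.biotype == NCRNA,
                "is_control": False,
                "sequence": seq,
                "chrom": m.chrom,
                "start": gstart,
                "end": gstart + plen,
                "strand": m.strand,
            }
        )

    genomes = [g.sequences for g in (bundle.genome_a, bundle.genome_b)]

    def matches_somewhere(seq: str) -> bool:
        return any(
            seq in chrom or revcomp(seq) in chrom
            for seqs in genomes
            for chrom in seqs.values()
        )

    for j in range(config.n_negative_controls):
        for _ in range(100):
            seq = _random_sequence(rng, config.probe_len_mrna)
            if not matches_somewhere(seq):
                break
        else:  # pragma: no cover - 65-mers collide with ~Mb genomes never
            raise RuntimeError(f"could not draw negative control ctrl_{j + 1:03d}")
        rows.append(
            {
                "probe_id": f"ctrl_{j + 1:03d}",
                "target_id": "",
                "is_ncrna": False,
                "is_control": True,
                "sequence": seq,
                "chrom": "",
                "start": -1,
                "end": -1,
                "strand": ".",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# truth + expression
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Planted ground truth: per-probe DE labels and effects, per-ncRNA
    context/conservation/feature flags, marker template assignments and
    per-gene TSA fold changes."""

    probes: pd.DataFrame  # probe_id, target_id, is_ncrna, is_control, is_silent, template, template_sign
    lfc: pd.DataFrame  # index probe_id, columns STAGES, planted log2 FC
    markers: dict[str, str]  # template -> marker probe_id
    context: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None  # gene_id, arm, timepoint, log2_fc
    sigma_sq: pd.Series | None = field(default=None, repr=False)

    def expected_de(self) -> pd.DataFrame:
        """Planted DE indicator per probe x contrast (lfc != 0)."""
        return self.lfc != 0.0

    def marker_group(self, template: str, sign: int = 1) -> list[str]:
        p = self.probes
        sel = p[(p.template == template) & (p.template_sign == sign) & p.is_ncrna]
        return sorted(sel.probe_id)


def _qpcr_truth(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Planted TSA log2 fold changes (treated vs untreated) per gene, arm
    and timepoint.  One Neat1-like gene responds with opposite sign in the
    two culture arms; most other responders are repressed, a few induced,
    and one gene is null."""
    rows = []
    for tp in ("24h", "48h"):
        rows.append(("neat1_like", "stochastic", tp, 2.0))
        rows.append(("neat1_like", "instructive", tp, -2.0))
    n_rest = config.n_qpcr_genes - 1
    n_down = max(0, int(round(n_rest * 0.65)))
    n_up = max(0, n_rest - n_down - 1)
    gid = 0
    for _ in range(n_down):
        gid += 1
        base = float(rng.uniform(-3.0, -1.0))
        for arm in ("instructive", "stochastic"):
            for tp, scale in (("24h", 0.7), ("48h", 1.0)):
                rows.append((f"tsa_g{gid:02d}", arm, tp, base * scale))
    for _ in range(n_up):
        gid += 1
        base = float(rng.uniform(1.0, 2.0))
        for arm in ("instructive", "stochastic"):
            for tp, scale in (("24h", 0.7), ("48h", 1.0)):
                rows.append((f"tsa_g{gid:02d}", arm, tp, base * scale))
    if n_rest > n_down + n_up:
        gid += 1
        for arm in ("instructive", "stochastic"):
            for tp in ("24h", "48h"):
                rows.append((f"tsa_g{gid:02d}", arm, tp, 0.0))
    return pd.DataFrame(rows, columns=["gene_id", "arm", "timepoint", "log2_fc"])


def simulate_truth(
    config: SimConfig,
    seed: int | None = None,
    probes: pd.DataFrame | None = None,
    context_truth: pd.DataFrame | None = None,
) -> SimTruth:
    """Assign planted expression truth to a probe set.

    With ``probes=None`` an abstract probe pool (no genomes) of the
    configured sizes is used, which is sufficient for expression-only
    studies; otherwise the probe table from :func:`simulate_probes` links
    truth to genomic loci and enables planted ncRNA/host-gene pairs.
    """
    rng = _rng(config, SEED_TRUTH, seed)
    if probes is None:
        rows = []
        for i in range(config.n_genes):
            rows.append((f"m_{i + 1:04d}", f"m_{i + 1:04d}", False, False))
        for i in range(config.n_ncrnas):
            rows.append((f"nc_{i + 1:04d}", f"nc_{i + 1:04d}", True, False))
        for i in range(config.n_negative_controls):
            rows.append((f"ctrl_{i + 1:03d}", "", False, True))
        probes = pd.DataFrame(rows, columns=["probe_id", "target_id", "is_ncrna", "is_control"])
    probes = probes.copy().reset_index(drop=True)

    n = len(probes)
    is_nc = probes.is_ncrna.to_numpy()
    is_ctrl = probes.is_control.to_numpy()

    silent_p = np.where(is_nc, config.silent_fraction_ncrna, config.silent_fraction_mrna)
    is_silent = (rng.random(n) < silent_p) | is_ctrl

    template = np.full(n, "", dtype=object)
    template_sign = np.zeros(n, dtype=int)
    markers: dict[str, str] = {}

    nc_idx = np.flatnonzero(is_nc & ~is_ctrl)
    nc_pool = list(rng.permutation(nc_idx))
    m_idx = np.flatnonzero(~is_nc & ~is_ctrl)
    m_pool = list(rng.permutation(m_idx))
    for tmpl, (n_pos, n_neg) in config.template_groups.items():
        if not m_pool:
            raise ValueError("template groups require at least one mRNA probe each")
        if n_pos + n_neg > len(nc_pool):
            raise ValueError(
                f"template group {tmpl!r} needs {n_pos + n_neg} ncRNA probes, "
                f"only {len(nc_pool)} unassigned"
            )
        mk = m_pool.pop(0)
        template[mk], template_sign[mk] = tmpl, 1
        markers[tmpl] = probes.probe_id[mk]
        for _ in range(n_pos):
            i = nc_pool.pop(0)
            template[i], template_sign[i] = tmpl, 1
        for _ in range(n_neg):
            i = nc_pool.pop(0)
            template[i], template_sign[i] = tmpl, -1
    has_template = template_sign != 0
    is_silent[has_template] = False

    # random per-contrast DE outside the templates
    pi = np.where(is_nc, config.pi_de_ncrna, config.pi_de_mrna)
    lo, hi = config.lfc_range
    free = ~is_silent & ~is_ctrl & ~has_template
    de = (rng.random((n, len(STAGES))) < pi[:, None]) & free[:, None]
    mag = rng.uniform(lo, hi, size=(n, len(STAGES)))
    sign = rng.choice([-1.0, 1.0], size=(n, len(STAGES)))
    lfc = np.where(de, sign * mag, 0.0)
    for tmpl in TEMPLATES:
        sel = template == tmpl
        if sel.any():
            lfc[sel] = np.outer(template_sign[sel], TEMPLATES[tmpl])

    probes["is_silent"] = is_silent
    probes["template"] = template
    probes["template_sign"] = template_sign
    lfc_df = pd.DataFrame(lfc, index=probes.probe_id, columns=list(STAGES))

    # planted discordant/concordant ncRNA-host pairs (context mode only)
    if context_truth is not None:
        pid = {p: i for i, p in enumerate(probes.probe_id)}
        anchored = context_truth[context_truth.host_gene != ""]
        candidates = []
        for _, row in anchored.iterrows():
            nc_p, host_p = f"p_{row.ncrna_id}", f"p_{row.host_gene}"
            if nc_p in pid and host_p in pid:
                if not has_template[pid[nc_p]] and not has_template[pid[host_p]]:
                    candidates.append((pid[nc_p], pid[host_p]))
        want = config.n_discordant_pairs + config.n_concordant_pairs
        for j, (i_nc, i_host) in enumerate(candidates[:want]):
            c = j % len(STAGES)
            discordant = j < config.n_discordant_pairs
            lfc_df.iloc[i_nc, c] = 2.0
            lfc_df.iloc[i_host, c] = -2.0 if discordant else 2.0
            probes.loc[[i_nc, i_host], "is_silent"] = False

    qpcr = _qpcr_truth(config, rng)
    return SimTruth(
        probes=probes, lfc=lfc_df, markers=markers, context=context_truth, qpcr=qpcr
    )


def simulate_expression(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Per-spot two-channel foreground/background intensities for every
    stage x replicate array (channel 1 = stage sample, channel 2 = NSC
    reference).

    The expected normalized log-ratio equals the planted log2 fold change;
    per-probe residual variances follow a scaled inverse-chi-square law with
    the configured prior, and a smooth cubic intensity-dependent dye bias is
    injected into every spot.  Silent probes and negative controls carry
    background-level signal only.
    """
    rng = _rng(config, SEED_EXPRESSION, seed)
    probes = truth.probes
    n = len(probes)
    lfc = truth.lfc.to_numpy()
    is_ctrl = probes.is_control.to_numpy()
    silent = probes.is_silent.to_numpy() | is_ctrl

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n)
    d0, s0sq = config.noise_prior_df, config.noise_prior_scale
    sigma_sq = d0 * s0sq / rng.chisquare(d0, n)
    # marker-template probes emulate well-measured marker genes: they follow
    # their deterministic stage template plus typical-scale noise, exempt
    # from the heavy tail of the variance prior
    sigma_sq[probes.template_sign.to_numpy() != 0] = s0sq
    truth.sigma_sq = pd.Series(sigma_sq, index=probes.probe_id, name="sigma_sq")

    crosshyb = np.where(is_ctrl, config.control_crosshyb_log, 0.0)
    frames = []
    n_clamped = 0
    for s_i, stage in enumerate(STAGES):
        for rep in range(1, config.n_replicates + 1):
            noise_sd = np.sqrt(sigma_sq / 2.0)
            x1 = baseline + lfc[:, s_i] / 2.0 + rng.normal(0.0, 1.0, n) * noise_sd
            x2 = baseline - lfc[:, s_i] / 2.0 + rng.normal(0.0, 1.0, n) * noise_sd
            a = 0.5 * (x1 + x2)
            z = (a - config.baseline_log2_mean) / (2.0 * config.baseline_log2_sd)
            bias = config.dye_bias_amplitude * z**3
            x1 = x1 + bias / 2.0
            x2 = x2 - bias / 2.0
            signal1 = np.where(silent, 0.0, 2.0**x1)
            signal2 = np.where(silent, 0.0, 2.0**x2)
            cols = {}
            for ch, signal in (("ch1", signal1), ("ch2", signal2)):
                bg_true = rng.lognormal(config.background_log_mean, config.background_log_sd, n)
                spot_fluct = np.exp(crosshyb + rng.normal(0.0, 0.15, n))
                bg_reported = bg_true * np.exp(rng.normal(0.0, 0.05, n))
                fg = signal + bg_true * spot_fluct
                low = fg < config.intensity_floor
                n_clamped += int(low.sum())
                cols[f"fg_{ch}"] = np.maximum(fg, config.intensity_floor)
                cols[f"bg_{ch}"] = bg_reported
            frames.append(
                pd.DataFrame(
                    {
                        "array_id": f"{stage}_r{rep}",
                        "stage": stage,
                        "replicate": rep,
                        "probe_id": probes.probe_id.to_numpy(),
                        **cols,
                    }
                )
            )
    if n_clamped:
        log.warning("%d spot intensities clamped to the floor", n_clamped)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------

QPCR_REFERENCE = "ref18s"


def simulate_qpcr(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> pd.DataFrame:
    """Replicate Ct tables realizing the planted TSA fold changes at
    efficiency E = 2, with an invariant reference gene, under treated and
    untreated conditions for both culture arms at T0/24h/48h."""
    rng = _rng(config, SEED_QPCR, seed)
    plan = truth.qpcr
    if plan is None:
        raise ValueError("truth carries no qPCR fold-change plan")
    if (2.0 ** plan.log2_fc.to_numpy() <= 0).any():  # defensive: fc must be > 0
        raise ValueError("planted fold change <= 0")
    genes = list(dict.fromkeys(plan.gene_id))
    base = {g: float(rng.uniform(20.0, 26.0)) for g in genes}
    base[QPCR_REFERENCE] = 12.0
    fc = {
        (r.gene_id, r.arm, r.timepoint): r.log2_fc for r in plan.itertuples()
    }
    sd = config.qpcr_ct_sd
    rows = []
    for arm in ("instructive", "stochastic"):
        for tp in ("T0", "24h", "48h"):
            conditions = ["untreated"] if tp == "T0" else ["untreated", "treated"]
            for cond in conditions:
                for g in [QPCR_REFERENCE] + genes:
                    shift = 0.0
                    if cond == "treated" and g != QPCR_REFERENCE:
                        shift = fc.get((g, arm, tp), 0.0)
                    for rep in range(1, config.n_qpcr_replicates + 1):
                        ct = base[g] - shift + rng.normal(0.0, sd)
                        rows.append((g, cond, arm, tp, rep, round(ct, 4), config.qpcr_efficiency))
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "arm", "timepoint", "replicate", "Ct", "E"]
    )


# ---------------------------------------------------------------------------
# term map
# ---------------------------------------------------------------------------

def simulate_term_map(
    truth: SimTruth, config: SimConfig, seed: int | None = None, n_terms: int = 20
) -> pd.DataFrame:
    """Synthetic term -> gene map over the mRNA targets.  Two terms are
    deliberately biased toward genes planted as upregulated at the GABAN
    contrast, so the enrichment stage has real signal to find."""
    rng = _rng(config, SEED_TERMS, seed)
    p = truth.probes
    mrna = p[~p.is_ncrna & ~p.is_control]
    universe = mrna.target_id.to_numpy()
    up_gaban = mrna.target_id[
        (truth.lfc.loc[mrna.probe_id, "GABAN"] > 0).to_numpy()
    ].to_numpy()
    rows = []
    for t in range(1, n_terms + 1):
        term = f"TERM{t:04d}"
        size = int(rng.integers(10, min(41, len(universe))))
        if t <= 2 and len(up_gaban) >= 5:
            n_bias = min(int(round(size * 0.7)), len(up_gaban))
            chosen = set(rng.choice(up_gaban, size=n_bias, replace=False))
            rest = [g for g in universe if g not in chosen]
            chosen |= set(rng.choice(rest, size=size - n_bias, replace=False))
        else:
            chosen = set(rng.choice(universe, size=size, replace=False))
        rows += [(term, g) for g in sorted(chosen)]
    return pd.DataFrame(rows, columns=["term_id", "gene_id"])
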