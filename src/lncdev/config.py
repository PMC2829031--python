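"""Study-design configuration for the synthetic data generator.

The defaults encode the emulated experiment: six cell states (NSC reference;
N/OP, GABAN, OLP, PMO, MYO), three replicate two-colour arrays per stage each
hybridized against the NSC sample, probe pools targeting mRNAs (65-mers) and
ncRNAs (70-mers) plus negative controls, and planted differential-expression,
genomic-context, conservation and TSA-response ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

#: stage-vs-NSC contrasts, in developmental order
STAGES = ("NOP", "GABAN", "OLP", "PMO", "MYO")

REFERENCE_STAGE = "NSC"

#: fixed stage templates (log2 vs NSC) for marker-like expression shapes:
#: an OLP-peaking profile (Olig1-like), a monotone myelination ramp
#: (Mog-like) and a monotone proliferative decline (Melk-like).
TEMPLATES: dict[str, tuple[float, ...]] = {
    "olp_peak": (0.3, -0.3, 2.8, 1.2, 0.5),
    "mono_up": (0.1, 0.3, 0.9, 2.0, 3.2),
    "mono_down": (-0.2, -0.6, -1.2, -2.2, -3.0),
}

#: marker gene aliases for the template shapes (probe ids in the synthetic
#: probe set; the marker-correlation screen anchors on these)
TEMPLATE_MARKERS = {"olp_peak": "Olig1", "mono_up": "Mog", "mono_down": "Melk"}

CONTEXT_CLASSES = ("antisense", "intronic", "bidirectional", "intergenic")


@dataclass
class SimConfig:
    seed: int = 0
    n_genes: int = 300
    n_ncrnas: int = 150
    context_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "antisense": 0.20,
            "intronic": 0.30,
            "bidirectional": 0.20,
            "intergenic": 0.30,
        }
    )
    conserved_fraction: float = 0.5
    # fraction of probes differentially expressed per stage contrast
    pi_de_mrna: float = 0.16
    pi_de_ncrna: float = 0.05
    lfc_range: tuple[float, float] = (1.0, 3.0)
    # scaled inverse-chi-square noise prior on per-probe M variance
    noise_prior_df: float = 4.0
    noise_prior_scale: float = 0.02
    dye_bias_amplitude: float = 0.3
    n_replicates: int = 3
    n_negative_controls: int = 50

    # fraction of probes with no transcript present (below background);
    # defaults mirror the emulated platform's expressed-above-background
    # fractions (31% of mRNA probes, 9% of ncRNA probes)
    silent_fraction_mrna: float = 0.69
    silent_fraction_ncrna: float = 0.91

    # marker-template co-expression groups: template -> (n_correlated,
    # n_anti_correlated) ncRNA probes sharing (or inverting) the template
    template_groups: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "olp_peak": (6, 2),
            "mono_up": (8, 2),
            "mono_down": (27, 2),
        }
    )
    # planted ncRNA/host-gene expression relationships
    n_discordant_pairs: int = 8
    n_concordant_pairs: int = 8

    # probe design
    probe_len_mrna: int = 65
    probe_len_ncrna: int = 70

    # spot intensity model
    baseline_log2_mean: float = 10.0
    baseline_log2_sd: float = 1.2
    background_log_mean: float = 3.6889  # ln 40
    background_log_sd: float = 0.4
    # low-level nonspecific binding on negative-control spots (log scale);
    # makes the control-derived background threshold conservative
    control_crosshyb_log: float = 0.12
    intensity_floor: float = 1.0

    # genomic feature planting
    enhancer_fraction: float = 0.15
    structured_hi_fraction: float = 0.20
    structured_mid_fraction: float = 0.15
    n_background_enhancers: int = 15
    n_background_structures: int = 15

    # qPCR / TSA arm design
    n_qpcr_genes: int = 15
    # 4 replicates per group: the exhaustive 4v4 fixed-reallocation test has
    # 70 partitions, so its smallest two-sided p (2/70 ~ 0.029) can clear the
    # 0.05 significance level (3v3 bottoms out at 0.1)
    n_qpcr_replicates: int = 4
    qpcr_ct_sd: float = 0.2
    qpcr_efficiency: float = 2.0

    def __post_init__(self) -> None:
        total = sum(self.context_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"context_proportions sum to {total}, expected 1")
        if set(self.context_proportions) != set(CONTEXT_CLASSES):
            raise ValueError(
                f"context_proportions keys must be {CONTEXT_CLASSES}"
            )
        lo, hi = self.lfc_range
        if lo < 0.585:
            raise ValueError("lfc_range lower bound must be >= 0.585 (1.5-fold)")
        if hi < lo:
            raise ValueError("lfc_range must be (low, high) with high >= low")
        for name in (
            "conserved_fraction",
            "pi_de_mrna",
            "pi_de_ncrna",
            "silent_fraction_mrna",
            "silent_fraction_ncrna",
            "enhancer_fraction",
            "structured_hi_fraction",
            "structured_mid_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("n_genes", "n_ncrnas", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.noise_prior_df <= 0 or self.noise_prior_scale <= 0:
            raise ValueError("noise prior df and scale must be positive")
        if not 1.0 < self.qpcr_efficiency <= 2.0:
            raise ValueError("qpcr_efficiency must be in (1, 2]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lfc_range"] = list(self.lfc_range)
        d["template_groups"] = {k: list(v) for k, v in self.template_groups.items()}
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
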