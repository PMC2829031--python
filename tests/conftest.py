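from pathlib import Path

import numpy as np
import pytest

from lncdev.config import SimConfig

REPO = Path(__file__).resolve().parents[1]
DEMO_CONFIG = REPO / "analysis" / "demo_config.yaml"


def small_sim_config(seed: int = 1, **kw) -> SimConfig:
    """Annotation-scale configuration: small genomes, all context classes."""
    defaults = dict(
        seed=seed,
        n_genes=40,
        n_ncrnas=24,
        n_negative_controls=20,
        template_groups={"olp_peak": (3, 1), "mono_up": (3, 1), "mono_down": (4, 1)},
        n_discordant_pairs=3,
        n_concordant_pairs=3,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def expression_config(seed: int = 1, n_probes: int = 2000, **kw) -> SimConfig:
    """Expression-only configuration (abstract probes, no genomes):
    clean measurement conditions for statistical checks."""
    n_nc = n_probes * 3 // 10
    defaults = dict(
        seed=seed,
        n_genes=n_probes - n_nc,
        n_ncrnas=n_nc,
        n_negative_controls=50,
        silent_fraction_mrna=0.0,
        silent_fraction_ncrna=0.0,
        template_groups={},
        n_discordant_pairs=0,
        n_concordant_pairs=0,
    )
    defaults.update(kw)
    return SimConfig(**defaults)


@pytest.fixture(scope="session")
def annotation_bundle():
    from lncdev.simulate import simulate_annotation

    return simulate_annotation(small_sim_config())


@pytest.fixture(scope="session")
def probe_table(annotation_bundle):
    from lncdev.simulate import simulate_probes

    return simulate_probes(annotation_bundle, small_sim_config())


@pytest.fixture(scope="session")
def mapper_fixture():
    """50-probe fixture over a small genome: exact singletons (both
    strands), one-mismatch probes, exactly duplicated loci and random
    never-present sequences."""
    rng = np.random.default_rng(20240917)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = alphabet[rng.integers(0, 4, 40_000)].tobytes().decode()
    # plant a duplicated segment
    dup = genome[5000:5200]
    genome = genome[:30000] + dup + genome[30200:]
    from lncdev.annotation import revcomp

    probes = []
    # 20 exact forward, 10 exact reverse-strand
    for i in range(30):
        start = 100 + i * 900
        seq = genome[start : start + 65]
        probes.append((f"exact_{i:02d}", seq if i < 20 else revcomp(seq)))
    # 10 with exactly one mismatch to their best locus
    for i in range(10):
        start = 200 + i * 900
        seq = list(genome[start : start + 65])
        old = seq[30]
        seq[30] = {"A": "C", "C": "G", "G": "T", "T": "A"}[old]
        probes.append((f"mm1_{i:02d}", "".join(seq)))
    # 5 inside the duplicated segment (two exact genomic copies)
    for i in range(5):
        seq = dup[10 + i * 20 : 75 + i * 20]
        probes.append((f"dup_{i:02d}", seq))
    # 5 random sequences absent from the genome
    n_rand = 0
    while n_rand < 5:
        seq = alphabet[rng.integers(0, 4, 65)].tobytes().decode()
        if seq not in genome and revcomp(seq) not in genome:
            probes.append((f"rand_{n_rand:02d}", seq))
            n_rand += 1
    return {"chrF": genome}, probes
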