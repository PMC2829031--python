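"""Shared plumbing for the numbered analysis drivers."""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
CONFIG = ROOT / "analysis" / "demo_config.yaml"
RUN = ROOT / "results" / "run"


def load_config():
    from lncdev.pipeline import PipelineConfig

    return PipelineConfig.from_yaml(CONFIG)


def read(name: str) -> pd.DataFrame:
    path = RUN / name
    if not path.exists():
        raise SystemExit(
            f"{path} not found — run the earlier analysis steps first "
            "(python analysis/01_simulate.py ...)"
        )
    return pd.read_csv(path, sep="\t", comment="#")


def emit(df: pd.DataFrame, name: str, chash: str, seed: int) -> None:
    from lncdev.annotation import write_tsv

    (RUN / name).parent.mkdir(parents=True, exist_ok=True)
    write_tsv(df, RUN / name, config_hash=chash, seed=seed)
    print(f"  wrote {RUN / name} ({len(df)} rows)")
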