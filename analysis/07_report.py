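"""Assemble the report table set (shaped like the study's supplementary
tables: mRNA/ncRNA DE, context + conservation, discordant switching,
marker-correlated sets, enrichment, TSA response) plus the data dictionary,
and a manifest with file hashes for reproducibility."""

import hashlib
import json

from common import RUN, load_config
from lncdev import __version__
from lncdev.pipeline import write_report


def main() -> None:
    cfg = load_config()
    write_report(RUN)
    files = {
        str(p.relative_to(RUN)): hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(RUN.rglob("*"))
        if p.is_file() and p.name != "manifest.json"
    }
    manifest = {
        "config_hash": cfg.config_hash(),
        "sim_config_hash": cfg.sim.config_hash(),
        "seed": cfg.sim.seed,
        "version": __version__,
        "files": files,
    }
    (RUN / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    print(f"report tables under {RUN / 'report'}:")
    for p in sorted((RUN / "report").glob("*.tsv")):
        print("  ", p.name)
    print(f"manifest: {RUN / 'manifest.json'} ({len(files)} files hashed)")


if __name__ == "__main__":
    main()
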