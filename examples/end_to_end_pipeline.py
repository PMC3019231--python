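"""The whole pipeline in one call: simulate inputs, annotate, overlap,
scan motifs, integrate expression, and write a report bundle.

Equivalent to ``nrcis run --seed 1 --out nrcis_demo`` on the command
line.
"""

import json
from pathlib import Path
from tempfile import TemporaryDirectory

from nrcis.pipeline import RunConfig, run_pipeline
from nrcis.synthetic_data import SimulationConfig

with TemporaryDirectory() as tmp:
    cfg = RunConfig(
        seed=1,
        out_dir=Path(tmp) / "run",
        sim=SimulationConfig(seed=1, n_peaks=800, n_genes=150, n_expressed_genes=2_000),
    )
    summary = run_pipeline(cfg)
    print("replicate overlap:", summary["replicate_overlap"]["pct_rep1_shared"], "%")
    print("targets:", json.dumps(summary["targets"], indent=1))
    print("motif classes:", summary["motifs"]["classes"]["percent"])
    print("files written:", sorted(p.name for p in (Path(tmp) / "run").iterdir()))
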