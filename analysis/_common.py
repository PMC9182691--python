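"""Shared run configuration for the numbered analysis drivers.

All drivers operate on the same run directory (``results/run``) so they can
be executed in order; each is a thin narrative wrapper over one pipeline
stage. Iteration counts are reduced from the 10,000 default to keep each
driver interactive (seconds, not minutes); the default synthetic conditions
are described in mirfeat/synth.py and docs/methods.md.
"""
from __future__ import annotations

import logging
import sys
from pathlib import Path

from mirfeat.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"


def default_config(seed: int = 1) -> RunConfig:
    logging.basicConfig(stream=sys.stderr, level=logging.INFO,
                        format="%(asctime)s %(levelname)s %(message)s")
    cfg = RunConfig(
        output_dir=RESULTS / "run",
        rng_seed=seed,
        n_iter_enrich=2000,
        n_iter_ratio=2000,
        n_background_regions=1000,
    )
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    return cfg
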