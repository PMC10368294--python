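"""Shared driver plumbing: default workspace construction and output paths."""

from __future__ import annotations

import argparse
from pathlib import Path

from mztseq.simulate import SimulationConfig
from mztseq.pipeline import Workspace

RESULTS = Path(__file__).resolve().parent.parent / "results"


def get_args(description: str) -> argparse.Namespace:
    ap = argparse.ArgumentParser(description=description)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-genes", type=int, default=2000)
    ap.add_argument("--outdir", type=Path, default=RESULTS)
    return ap.parse_args()


def default_workspace(args, with_sequences: bool = False) -> Workspace:
    cfg = SimulationConfig(n_genes=args.n_genes, seed=args.seed)
    return Workspace.from_config(cfg, with_sequences=with_sequences)
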