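"""Shared setup for the numbered analysis scripts.

Each script regenerates the synthetic study set deterministically from a
seed and writes small result tables to results/; nothing heavy is stored.
"""

from __future__ import annotations

import argparse
from pathlib import Path

RESULTS = Path(__file__).resolve().parent.parent / "results"


def parse_args(description: str, default_seed: int = 1) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=default_seed)
    parser.add_argument("--out", type=Path, default=RESULTS)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)
    return args
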