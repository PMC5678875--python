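"""Shared locations and study settings for the numbered analysis scripts."""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

N_CHILDREN = 300
SEED_SIMULATION = 2024
SEED_SAMPLING = 2025
SEED_PERMUTATION = 2026
SEED_BOOTSTRAP = 2027
K_GRID = (9, 19, 39, 59, 99, 149)
NPERM = 199
N_BOOT = 199
REFS = {"sex": "Male", "transport": "Active"}

for d in (SCRATCH, RESULTS):
    d.mkdir(parents=True, exist_ok=True)
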