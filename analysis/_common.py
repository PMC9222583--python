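"""Shared paths and settings for the numbered analysis scripts."""

from pathlib import Path

from ecomorphdiv.synthdata import SimConfig

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "data" / "synthetic"
RESULTS = ROOT / "results"

SEED = 20260930
SIM = SimConfig(n_genes=600, seed=SEED)

TARGET_COVERAGE = 20
MAF = 0.10
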