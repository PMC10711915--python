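"""Shared paths and panel settings for the numbered analysis scripts."""

from pathlib import Path

RESULTS = Path(__file__).resolve().parents[1] / "results"
PANEL_DIR = RESULTS / "panel"

#: Households in the demonstration panel. The source study's panel averages
#: 22,091 households per week; this scaled panel keeps the scripts fast while
#: leaving the weekly series' structure intact (the dominant weekly noise is
#: common across households).
N_HOUSEHOLDS = 150
FULL_PANEL_HOUSEHOLDS = 22_091
SEED = 2024
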