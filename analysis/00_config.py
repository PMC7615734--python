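"""Shared configuration for the analysis drivers.

One seed drives every simulated dataset so the whole analysis is
reproducible end to end; each driver derives its own sub-seed.
"""

from pathlib import Path

SEED = 1
ROOT = Path(__file__).resolve().parents[1]
# bulky simulated inputs and per-window tracks live under scratch/;
# results/ holds the compact summary tables
DATA_DIR = ROOT / "scratch" / "data"
TRACKS_DIR = ROOT / "scratch" / "tracks"
RESULTS_DIR = ROOT / "results"
RESULTS_DIR.mkdir(parents=True, exist_ok=True)

WINDOW_SIZE = 2_500
HMM_BIN_SIZE = 25_000
ANALYSIS_MIN_COVERAGE = 10
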