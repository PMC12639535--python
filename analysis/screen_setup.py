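"""Shared study configuration for the numbered analysis drivers.

A desk-scale rendition of the screen: 3 cell lines, 60 compounds with 3
replicates each, the full 978-gene / 728-DEG reference, planted antagonists
at overlap 0.5 / discordant 0.1, and 300 permutations per test.  Every driver
reads and writes under ``results/``.
"""

from pathlib import Path

from mycscreen import ScreenConfig, ScreenParams

RESULTS = Path(__file__).resolve().parent.parent / "results"
INPUTS = RESULTS / "inputs"
SEED = 7

CONFIG = ScreenConfig(n_cell_lines=3, n_compounds=60, n_antagonists=4,
                      n_line_decoys=2, n_low_tas_decoys=6, seed=SEED)
PARAMS = ScreenParams(n_perm=300, seed=SEED, min_lines=2)

CELL_LINES = [f"LINE_{i:02d}" for i in range(CONFIG.n_cell_lines)]
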