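"""Shared study configuration for the numbered analysis drivers.

The synthetic study emulates a genome-scale pathway model (3755 components,
4750 reactions, 30 pathways) simulated over a panel of 479 cell lines from 30
cancer types, screened against 8 receptor tyrosine kinase inhibitors with a
planted 5-component common signature.  Bulky intermediates (model JSON,
simulation matrix) live under scratch/analysis; the results/ directories hold
only small summary tables.
"""

from pathlib import Path

from metscreen.synth import SyntheticSpec

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"

SEED = 1

CANCER_TYPES = ("breast", "lung", "liver", "pancreas", "cns") + tuple(
    f"type{i:02d}" for i in range(25)
)

STUDY_SPEC = SyntheticSpec(
    n_components=3755,
    n_reactions=4750,
    n_pathways=30,
    n_cell_lines=479,
    cancer_types=CANCER_TYPES,
    seed=SEED,
)

MODEL_JSON = SCRATCH / "model.json"
SIM_MATRIX_TSV = SCRATCH / "sim_matrix.tsv"
IC50_CSV = SCRATCH / "ic50.csv"
ANNOTATIONS_CSV = SCRATCH / "annotations.csv"
GROUND_TRUTH_JSON = SCRATCH / "ground_truth.json"
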