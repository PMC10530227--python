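"""Shared configuration and paths for the numbered analysis scripts.

All scripts use the same default synthetic icescape (seed 1) so their
outputs describe one coherent analysis run.  Large arrays live under
scratch/ (regenerable); small result tables under results/.
"""

from pathlib import Path

from icehab import IceScapeConfig, PipelineConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

SEED = 1

ICE_CONFIG = IceScapeConfig(seed=SEED)
PIPE_CONFIG = PipelineConfig(icescape=ICE_CONFIG, seed=0)
# note: run_pipeline offsets the icescape seed by the pipeline seed; with
# pipeline seed 0 the stack equals generate_icescape(ICE_CONFIG) exactly

STACK_NPZ = SCRATCH / "icescape_stack.npz"
METRICS_NPZ = SCRATCH / "fastice_metrics.npz"
FEATURES_CSV = SCRATCH / "feature_table.csv"
SCORED_CSV = SCRATCH / "scored_cells.csv"


def ensure_dirs() -> None:
    SCRATCH.mkdir(exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
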