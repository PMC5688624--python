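"""Shared configuration for the numbered analysis drivers.

Every driver reruns its stage chain deterministically from the same seed,
so the scripts can be run independently and in any order; outputs land
under results/.
"""

from pathlib import Path

from irkit.pipeline import PipelineConfig, run

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def run_stages(*stages) -> dict:
    cfg = PipelineConfig(
        n_genes=200, n_species=5, n_conserved_core=86, seed=SEED,
        out_dir=str(RESULTS), run_stages=tuple(stages),
    )
    return run(cfg)
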