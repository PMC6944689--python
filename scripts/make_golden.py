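"""Regenerate the frozen golden outputs for the end-to-end pipeline test.

Inputs are synthesized at run time (demo preset, fixed seed); only the
pipeline's output tables are committed, under tests/data/golden/.
"""

import shutil
import tempfile
from pathlib import Path

from lncscout import simdata
from lncscout.pipeline import PipelineConfig, run_pipeline, simulate_to_dir

GOLDEN_FILES = (
    "candidates.tsv",
    "survival.tsv",
    "survival_km.tsv",
    "gsea.tsv",
    "cis.tsv",
    "cis_methylation.json",
    "drugscreen.tsv",
)

SIM_SEED = 7
RUN_SEED = 3
N_PERM = 50


def main():
    golden = Path(__file__).resolve().parent.parent / "tests" / "data" / "golden"
    golden.mkdir(parents=True, exist_ok=True)
    with tempfile.TemporaryDirectory() as tmp:
        data = Path(tmp) / "data"
        out = Path(tmp) / "out"
        simulate_to_dir(simdata.demo_config(seed=SIM_SEED), data)
        run_pipeline(PipelineConfig.from_data_dir(data, out, seed=RUN_SEED, n_perm=N_PERM))
        for name in GOLDEN_FILES:
            shutil.copy(out / name, golden / name)
            print(f"froze {name} ({(golden / name).stat().st_size} bytes)")


if __name__ == "__main__":
    main()
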