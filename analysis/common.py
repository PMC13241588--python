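"""Shared configuration for the numbered analysis scripts.

The scripts walk the inference chain on a reduced synthetic riverscape
(16 tributary populations, 150 SNP loci, 200 main-stem fish per year) so
each step runs in about a minute on a laptop; the full study design is
exercised by scripts/acceptance.py and the test suite.  All scripts are
deterministic given SEED.
"""

from pathlib import Path

from rivergsi.pipeline import PipelineConfig, SamplerSettings
from rivergsi.riverscape import SimulationConfig

SEED = 20260920
RESULTS = Path(__file__).resolve().parents[1] / "results"


def demo_config(outdir=None) -> PipelineConfig:
    return PipelineConfig(
        seed=SEED,
        simulation=SimulationConfig(
            seed=SEED, n_populations=16, n_loci=150, n_sections=6, n_years=3,
            n_split_populations=3, n_small_collections=2,
            mixture_size_per_year=200, connectivity_counts=None),
        sampler=SamplerSettings(
            gsi_sweeps=1000, gsi_burn=250, bootstrap_reps=25,
            bootstrap_sweeps=300, bootstrap_burn=100,
            zib_chains=2, zib_warmup=500, zib_iterations=400,
            dirichlet_chains=1, dirichlet_warmup=150,
            dirichlet_iterations=130, dirichlet_top_k=6),
        outdir=str(outdir) if outdir else None,
    )
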