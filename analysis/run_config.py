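"""Shared run configuration for the numbered analysis scripts.

One place for the study conditions: 3 reconstruction textures x 3 dose
fractions, 5 repetitions, 40 slices of 128^2 at the protocol pixel size.
"""

from ctnps.pipeline import RunConfig

SEED = 20260923


def get_config() -> RunConfig:
    return RunConfig(
        seed=SEED,
        matrix_size=128,
        n_slices=40,
        n_rep=5,
        out_dir="results/analysis",
        input_dir="scratch/ensembles",
    )
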