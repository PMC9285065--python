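import numpy as np
import pytest

from moca import (
    BlockMatrix,
    MocaOptions,
    MultiBlockData,
    SyntheticSpec,
    center_scale,
    fit_moca,
    generate,
)


def make_block(values, name="X", missing=None, var_names=None, obs_ids=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return BlockMatrix(
        name=name,
        values=values,
        missing_mask=missing,
        var_names=var_names or [f"{name}_v{j}" for j in range(p)],
        obs_ids=obs_ids or [f"o{i}" for i in range(n)],
        preprocessing="raw",
    )


@pytest.fixture(scope="session")
def three_block_spec():
    """Planted 1 global + 1 local(b1,b2) + 1 unique-per-block layout."""

    def _spec(seed, n_obs=200, noise_sd=0.3):
        return SyntheticSpec(
            n_obs=n_obs,
            blocks=[("b1", 30), ("b2", 50), ("b3", 80)],
            global_latents=1,
            local_latents=[(("b1", "b2"), 1)],
            unique_latents=1,
            noise_sd=noise_sd,
            seed=seed,
        )

    return _spec


@pytest.fixture(scope="session")
def planted_model(three_block_spec):
    """One fitted model + truth on the standard 3-block fixture."""
    data, truth = generate(three_block_spec(seed=1))
    pre = data.center_scale()
    model = fit_moca(pre, MocaOptions(strictness=-0.1))
    return pre, model, truth
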