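import numpy as np
import pytest

import atlasthresh as at


def make_outcome_arrays(
    n: int,
    seed: int,
    spec: at.SpeciesResponseSpec,
    cover_mean: float = 63.1,
    cover_concentration: float = 3.5,
):
    """Generate a landscape + species dynamics and return (x, y_persist)."""
    side = int(np.ceil(np.sqrt(n)))
    profile = at.RegionProfile(
        name="sim", n_blocks=n, grid_dims=(side, side),
        cover_mean=cover_mean, cover_concentration=cover_concentration,
    )
    blocks = at.generate_landscape(profile, seed)
    records = at.simulate_species_dynamics(blocks, spec, seed)
    presence = at.apply_confidence_filter(at.deduplicate_records(records))
    outcomes = at.classify_outcomes(presence, spec.species_code, blocks)
    x = np.array([o.covariate_x for o in outcomes], dtype=float)
    y = np.array([o.persisted for o in outcomes], dtype=float)
    return x, y


@pytest.fixture
def strong_threshold_spec():
    """Species with an unambiguous breakpoint at 60 % cover."""
    return at.SpeciesResponseSpec(
        species_code="STRONG", psi_true=60.0, intercept=-2.0,
        slope_below=0.0, slope_change=0.5,
    )


@pytest.fixture
def moderate_threshold_spec():
    """Species with a clear but noisier breakpoint at 60 % cover."""
    return at.SpeciesResponseSpec(
        species_code="MOD", psi_true=60.0, intercept=-2.0,
        slope_below=0.0, slope_change=0.25,
    )


@pytest.fixture
def flat_spec():
    """Non-threshold species: constant persistence probability ~0.73."""
    return at.SpeciesResponseSpec(
        species_code="FLAT", psi_true=60.0, intercept=1.0,
        slope_below=0.0, slope_change=0.0,
    )
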