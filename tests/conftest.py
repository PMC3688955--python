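"""Shared fixtures: synthetic references, clone sets and intrinsic profiles.

Session-scoped where construction is expensive (48-clone calibration) so the
whole suite reuses one deterministic instance.
"""

from __future__ import annotations

import numpy as np
import pytest

from tracemix import pipeline
from tracemix.signal_prep import NormalizedSignals, normalize_direct_read
from tracemix.synthetic import GeneratorConfig, clone_set, make_reference


@pytest.fixture(scope="session")
def noiseless_cfg() -> GeneratorConfig:
    return GeneratorConfig(
        seed=101, position_noise_sd=0.0, baseline_noise=0.0, offpoint_attenuation=0.0, n_clones=3
    )


@pytest.fixture(scope="session")
def noisy_cfg() -> GeneratorConfig:
    # the study conditions: 5% per-position scatter, 2% baseline, 48 clones
    return GeneratorConfig(seed=202, n_clones=48)


@pytest.fixture(scope="session")
def reference(noiseless_cfg):
    return make_reference(noiseless_cfg)


@pytest.fixture(scope="session")
def noiseless_profile(reference, noiseless_cfg):
    rng = np.random.default_rng(noiseless_cfg.seed)
    clones = clone_set(reference, noiseless_cfg, rng)
    return pipeline.intrinsic_from_clones(clones, reference.amplicon, reference.sites)


@pytest.fixture(scope="session")
def noisy_profile(reference, noisy_cfg):
    rng = np.random.default_rng(noisy_cfg.seed)
    clones = clone_set(reference, noisy_cfg, rng)
    return pipeline.intrinsic_from_clones(clones, reference.amplicon, reference.sites)


def normalized_from_expected(sim_values: np.ndarray, sequence: str) -> NormalizedSignals:
    """Wrap a simulated expected-signal array as a normalized direct read,
    bypassing the generator (used for self-consistency oracles)."""
    return NormalizedSignals(
        called_bases=list(sequence[: len(sim_values)]),
        values=sim_values.copy(),
        position_sums=sim_values.sum(axis=1),
        scale_factor=1.0,
        read_type="direct",
        region=(0, len(sim_values)),
    )


@pytest.fixture(scope="session")
def its1_site(reference):
    return reference.site_for_region("ITS1")


def make_direct_norm(reference, cfg, components, rng, direction="forward", substitutions=()):
    """Generate a direct read and normalize it over the whole read."""
    from tracemix.synthetic import simulate_direct_read

    table = simulate_direct_read(
        reference, components, cfg, rng, direction=direction, substitutions=list(substitutions)
    )
    return normalize_direct_read(table, (0, len(table)))


def site_index(reference, site) -> int:
    return next(i for i, s in enumerate(reference.sites) if s.start == site.start)
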