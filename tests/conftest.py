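"""Shared fixtures: phantoms and pipeline outputs are expensive (a cube is
45 x 45 x ~550 samples), so they are built once per session and reused."""

from __future__ import annotations

import numpy as np
import pytest

import cryoraman as cr

#: true partitioning ratios spanning strong trapping to strong exclusion
SWEEP_RATIOS = (0.2, 0.5, 1.0, 1.3, 2.0)


def sweep_params(n: int = 20, **overrides) -> list[cr.SceneParams]:
    """Twenty phantom parameter sets (seeds 1..n) cycling through the ratios."""
    return [
        cr.SceneParams(
            dmso_channel=SWEEP_RATIOS[i % len(SWEEP_RATIOS)], seed=i + 1, **overrides
        )
        for i in range(n)
    ]


@pytest.fixture(scope="session")
def small_axis() -> cr.SpectralAxis:
    """21-sample axis around the DMSO band for unit tests."""
    return cr.SpectralAxis(625.0 + 4.83 * np.arange(21))


@pytest.fixture(scope="session")
def dmso_band() -> cr.BandDefinition:
    return cr.default_bands()[2]


@pytest.fixture(scope="session")
def baseline_scene() -> cr.SyntheticScene:
    return cr.generate_scene(cr.SceneParams(dmso_channel=1.3, seed=1))


@pytest.fixture(scope="session")
def baseline_cube(baseline_scene) -> cr.SpectralCube:
    return cr.render_cube(baseline_scene)


@pytest.fixture(scope="session")
def baseline_output(baseline_cube) -> cr.AnalysisOutput:
    return cr.run_analyze(baseline_cube)


@pytest.fixture(scope="session")
def noisefree_scene() -> cr.SyntheticScene:
    return cr.generate_scene(cr.SceneParams(dmso_channel=1.3, noise_sd=0.0, seed=2))


@pytest.fixture(scope="session")
def noisefree_output(noisefree_scene) -> cr.AnalysisOutput:
    return cr.run_analyze(cr.render_cube(noisefree_scene))


@pytest.fixture(scope="session")
def sweep_outputs() -> list[tuple[cr.SyntheticScene, cr.AnalysisOutput]]:
    """Pipeline results on the 20-phantom sweep at default noise."""
    results = []
    for params in sweep_params():
        scene = cr.generate_scene(params)
        results.append((scene, cr.run_analyze(cr.render_cube(scene))))
    return results
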