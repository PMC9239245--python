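"""Shared fixtures: the six-strain study panel and pipeline products.

All fixtures are session-scoped and seeded, so the expensive simulation
and pangenome construction run once for the whole suite.
"""

import pytest

from cyanopan.orthologs import build_pangenome
from cyanopan.synthgenomes import make_study_panel
from cyanopan.variants import call_pangenome_variants

PANEL_SEED = 1
REFERENCE = "legacy1"


@pytest.fixture(scope="session")
def panel():
    """Full-size six-strain panel: (bundles, truth)."""
    return make_study_panel(seed=PANEL_SEED)


@pytest.fixture(scope="session")
def panel_bundles(panel):
    return panel[0]


@pytest.fixture(scope="session")
def panel_truth(panel):
    return panel[1]


@pytest.fixture(scope="session")
def panel_by_id(panel_bundles):
    return {b.strain_id: b for b in panel_bundles}


@pytest.fixture(scope="session")
def panel_pangenome(panel_bundles):
    """Pangenome of the study panel (group identities not filled; the
    identity-dependent tests use the reduced panel)."""
    return build_pangenome(panel_bundles, compute_identities=False)


@pytest.fixture(scope="session")
def panel_calls(panel_bundles, panel_pangenome):
    return call_pangenome_variants(panel_pangenome, panel_bundles,
                                   reference=REFERENCE)


@pytest.fixture(scope="session")
def small_panel():
    """Reduced panel (scaled genomes) for identity-heavy tests."""
    return make_study_panel(seed=7, scale=0.35)


@pytest.fixture(scope="session")
def small_pangenome(small_panel):
    return build_pangenome(small_panel[0], compute_identities=True)
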