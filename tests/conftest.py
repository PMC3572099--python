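"""Shared fixtures: a small synthetic bundle and derived network views.

The bundle is generated once per session at a reduced size so individual
tests stay fast; tests that need the full default study conditions generate
their own bundles.
"""

from __future__ import annotations

import pytest

from paralognet.netbuild import assemble_full_network, extract_paralog_subnetwork
from paralognet.simulate import GeneratorConfig, generate_bundle

SMALL = dict(n_proteins=400, partner_set_size=60)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    return GeneratorConfig(seed=11, **SMALL)


@pytest.fixture(scope="session")
def bundle(small_config):
    return generate_bundle(small_config)


@pytest.fixture(scope="session")
def full_net(bundle):
    return assemble_full_network(bundle.interactions, bundle.annotations, bundle.isoform_map)


@pytest.fixture(scope="session")
def pnets(bundle, full_net):
    return {
        lab: extract_paralog_subnetwork(full_net, lab, bundle.isoform_map)
        for lab in sorted(bundle.isoform_map)
    }


@pytest.fixture(scope="session")
def default_bundle():
    """Default study conditions (n=800, 120 partners per hub)."""
    return generate_bundle(GeneratorConfig(seed=5))
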