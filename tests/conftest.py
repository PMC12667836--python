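"""Shared fixtures: small panels and synthetic sections with known truth."""

import numpy as np
import pytest

from striatlas import synth


@pytest.fixture(scope="session")
def toy_config():
    return synth.SimulationConfig(seed=5, n_types=3, n_genes=20, marker_fold=8)


@pytest.fixture(scope="session")
def toy_panel(toy_config):
    return synth.make_reference(toy_config)


@pytest.fixture(scope="session")
def demo_config():
    return synth.demo_config(seed=3)


@pytest.fixture(scope="session")
def demo_panel(demo_config):
    return synth.make_reference(demo_config)


@pytest.fixture(scope="session")
def demo_section(demo_config, demo_panel):
    return synth.make_section(demo_panel, demo_config, rc_level_mm=0.0, section_id="S0")


@pytest.fixture(scope="session")
def labeled_demo_section(demo_config, demo_panel, demo_section):
    from striatlas.label import label_cells

    sec = demo_section.copy()
    res = label_cells(sec, demo_panel, classify=False)
    sec.obs["assigned_label"] = res["assigned_label"]
    return sec


@pytest.fixture(scope="session")
def class_and_subtype_panels(demo_panel):
    """A major-class panel (MSN collapsed) plus the subtype panel."""
    msn = list(synth.DEMO_MSN_TYPES)
    idx = [demo_panel.type_ids.index(t) for t in msn]
    mu_msn = demo_panel.mu[idx].mean(axis=0)
    glia = [t for t in demo_panel.type_ids if t not in msn]
    rows = [mu_msn] + [demo_panel.mu[demo_panel.type_ids.index(t)] for t in glia]
    mu = np.vstack(rows)
    mu /= mu.sum(axis=1, keepdims=True)
    marker_map = {"MSN": sum((demo_panel.marker_map[t] for t in msn), [])}
    for t in glia:
        marker_map[t] = demo_panel.marker_map[t]
    class_panel = synth.ReferencePanel(
        gene_ids=list(demo_panel.gene_ids),
        type_ids=["MSN", *glia],
        mu=mu,
        panel_mask=demo_panel.panel_mask.copy(),
        marker_map=marker_map,
    )
    subtype_panel = demo_panel.subset_types(msn)
    return class_panel, subtype_panel
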