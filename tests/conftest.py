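import pytest

from hibed import (
    DEFAULT_HIERARCHY,
    SyntheticReferenceConfig,
    build_hibed_library,
    build_mixture_matrix,
    make_synthetic_reference,
    sample_mixture_proportions,
)


@pytest.fixture(scope="session")
def ref_panel():
    """Seed-42 synthetic purified panel at the package's default conditions."""
    cfg = SyntheticReferenceConfig(seed=42)
    beta, ann, planted = make_synthetic_reference(cfg)
    return beta, ann, planted


@pytest.fixture(scope="session")
def library(ref_panel):
    beta, ann, _ = ref_panel
    return build_hibed_library(beta, ann, DEFAULT_HIERARCHY, n_per_type=50, mode="hybrid")


@pytest.fixture(scope="session")
def planted_library(ref_panel):
    """Reference library whose sub-libraries sit exactly on the generator's
    disjoint planted marker blocks (no selection step)."""
    from hibed.library import ReferenceLibrary, build_sub_library
    from hibed.hierarchy import LAYER1

    beta, ann, planted = ref_panel
    h = DEFAULT_HIERARCHY
    leaf_labels = ann.set_index("sample_id")["cell_type"]
    group_labels = leaf_labels.map(h.group_of)
    subs = {
        LAYER1: build_sub_library(
            beta, group_labels, list(h.group_labels), planted[LAYER1], LAYER1
        )
    }
    for node, group in h.layer2_nodes().items():
        leaves = list(h.groups[group])
        probes = [p for leaf in leaves for p in planted[leaf]]
        off = [s for s, g in group_labels.items() if g != group]
        subs[node] = build_sub_library(
            beta, leaf_labels, leaves, probes, node, complement_samples=off
        )
    return ReferenceLibrary(hierarchy=h, sub_libraries=subs, provenance={})


@pytest.fixture(scope="session")
def truth50():
    return sample_mixture_proportions(50, list(DEFAULT_HIERARCHY.leaves), seed=42)


@pytest.fixture(scope="session")
def mixtures(ref_panel, truth50):
    beta, ann, _ = ref_panel
    mix, meta = build_mixture_matrix(beta, ann, truth50, noise_sd=0.0, seed=42)
    return mix, meta
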