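import pytest

from npannotate import libraries


@pytest.fixture(scope="session")
def signature_library():
    return libraries.default_signature_library()


@pytest.fixture(scope="session")
def compound_library():
    return libraries.default_compound_library()


@pytest.fixture(scope="session")
def group_library():
    return libraries.default_group_library()


@pytest.fixture(scope="session")
def prototypes():
    return libraries.default_prototypes()


@pytest.fixture(scope="session")
def three_class_compounds(compound_library, group_library):
    """30 compounds, 10 each of flavonol / phenolic acid / alkaloid, built
    from combinatorial candidates so every class has distinct members."""
    out = []
    for cls, n_max in (("flavonol", 2), ("phenolic acid", 2), ("alkaloid", 3)):
        parents = [c for c in compound_library if c.compound_class == cls][:3]
        cands = libraries.generate_combinations(
            parents, group_library, libraries.CombinatorialConfig(n_max=n_max)
        )
        picked = []
        for c in cands:
            picked.append(libraries.CompoundRecord(c.name, c.formula, c.compound_class))
            if len(picked) == 10:
                break
        assert len(picked) == 10
        out.extend(picked)
    return out
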