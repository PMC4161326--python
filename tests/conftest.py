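"""Collection order: run the expensive acceptance suite after the unit
and property tests, so fast feedback comes first."""


def pytest_collection_modifyitems(config, items):
    items.sort(key=lambda item: item.fspath.basename == "test_acceptance.py")
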