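import pytest
from hypothesis import settings

import renalcdm as r

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def analytes():
    import importlib.resources

    base = importlib.resources.files("renalcdm.data")
    return r.load_analyte_specs(str(base / "analytes.csv"),
                                str(base / "acceptable_units.csv"))


@pytest.fixture(scope="session")
def code_table():
    import importlib.resources

    base = importlib.resources.files("renalcdm.data")
    return r.load_code_lists(str(base / "code_lists.csv"))


@pytest.fixture(scope="session")
def small_study(tmp_path_factory):
    """A 400-patient 4-source synthetic study, generated and fully built."""
    root = tmp_path_factory.mktemp("study")
    gen = r.GeneratorConfig(seed=11, sources=r.default_sources(400))
    r.generate(gen, root / "raw")
    cfg = r.make_run_config(gen, root / "raw", root / "cdm")
    reports, failures = r.build_all(cfg)
    assert not failures
    store = r.TableStore(cfg, r.register_tables(cfg))
    return {"gen": gen, "cfg": cfg, "store": store, "raw": root / "raw",
            "reports": reports}
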