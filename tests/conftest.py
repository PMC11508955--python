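import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def panel():
    from hlatag import default_panel

    return default_panel()


@pytest.fixture(scope="session")
def tables():
    from hlatag.datasets import study_tables

    return study_tables()


def unit_result_for(results, table):
    """Find the fitted evaluation unit realising a study table's marker."""
    want = tuple(table.assay_ids)
    for r in results.unit_results:
        if tuple(r.unit.rule.assay_ids) == want:
            return r
    raise AssertionError(f"no fitted unit for assays {want}")
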