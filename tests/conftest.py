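import pytest

from pvsignal.replay import mock_dictionary
from pvsignal.reports import AdeReport, ReportSet
from pvsignal.simulate import catalog_dictionary, default_config


@pytest.fixture(scope="session")
def dictionary():
    return mock_dictionary()


@pytest.fixture(scope="session")
def sim_dictionary():
    return catalog_dictionary(default_config().pt_catalog)


def make_report(rid, drug="DRUG-X", pts=("Death",), **kwargs):
    return AdeReport(report_id=rid, drug=drug, pts=frozenset(pts), **kwargs)


@pytest.fixture
def small_universe():
    """Four reports, one per contingency cell for (DRUG-X, Nausea)."""
    return ReportSet(
        source_label="tiny",
        reports=[
            make_report("r1", "DRUG-X", ("Nausea", "Death")),   # a
            make_report("r2", "OTHER", ("Nausea",)),            # b
            make_report("r3", "DRUG-X", ("Death",)),            # c
            make_report("r4", "OTHER", ("Rash",)),              # d
        ],
    )
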