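import pandas as pd
import pytest

from sinas.fixtures import FixtureSpec, make_fixture_set
from sinas.pipeline import RunConfig, run_pipeline
from sinas.taxon_matcher import LocalBackbone


@pytest.fixture(scope="session")
def fixture_set(tmp_path_factory):
    """Default synthetic fixture set (seeded) with its ground-truth ledger."""
    dest = tmp_path_factory.mktemp("fixture_default")
    config_path, ledger = make_fixture_set(dest, FixtureSpec())
    return config_path, ledger


@pytest.fixture(scope="session")
def pipeline_result(fixture_set):
    config_path, _ = fixture_set
    return run_pipeline(RunConfig.from_file(config_path))


def make_backbone(rows):
    """Build a LocalBackbone from terse row tuples:
    (usage_key, canonical, authorship, status, accepted_key, higher-dict)."""
    records = []
    for key, canonical, authorship, status, accepted_key, higher in rows:
        rec = {
            "usage_key": key,
            "scientific_name": f"{canonical} {authorship}".strip(),
            "canonical_name": canonical,
            "authorship": authorship,
            "rank": "SPECIES",
            "status": status,
            "accepted_usage_key": accepted_key,
        }
        rec.update({r: higher.get(r, "") for r in
                    ("species", "genus", "family", "order", "class", "phylum", "kingdom")})
        records.append(rec)
    return LocalBackbone(pd.DataFrame(records))
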