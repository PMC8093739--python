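import pandas as pd
import pytest

from tidaltag import synthetic_data as sd


def det_frame(rows):
    """Detection frame from (minutes-offset, tag, receiver) triples."""
    t0 = pd.Timestamp("2019-12-01")
    return pd.DataFrame(
        {
            "timestamp": [t0 + pd.Timedelta(minutes=m) for m, _, _ in rows],
            "tag_id": [t for _, t, _ in rows],
            "receiver_id": [r for _, _, r in rows],
        }
    ).sort_values("timestamp", kind="stable").reset_index(drop=True)


@pytest.fixture(scope="session")
def small_bundle():
    """One 7-day synthetic deployment shared across tests."""
    return sd.make_fixture(seed=1, size="small")


@pytest.fixture(scope="session")
def fixture_dir(small_bundle, tmp_path_factory):
    """The same deployment written out as delimited-text files."""
    out = tmp_path_factory.mktemp("fixture")
    paths = sd.write_fixture(small_bundle, out)
    return paths
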