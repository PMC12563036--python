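import pandas as pd
import pytest

import primorisk as pk


@pytest.fixture(scope="session")
def refs():
    return pk.load_reference_table(pk.bundled_path("references.csv"))


@pytest.fixture(scope="session")
def campaign():
    """The bundled 83-sample monitoring campaign (149 detections)."""
    return pk.read_residues(pk.bundled_path("residues.csv"), n_samples_total=83)


@pytest.fixture(scope="session")
def profile():
    return pk.load_consumption_profile("nl_toddler")


@pytest.fixture(scope="session")
def campaign_summary():
    """Published per-substance campaign summary (detection counts, mean/max/total)."""
    frame = pd.read_csv(pk.bundled_path("campaign_summary.csv"), comment="#")
    frame["pesticide"] = frame["pesticide"].map(pk.normalize_name)
    return frame.set_index("pesticide")


@pytest.fixture()
def tiny_dataset():
    """Hand-sized campaign: 3 collected samples, one residue-free."""
    measurements = (
        pk.ResidueMeasurement("A1", "pyrimethanil", 0.5),
        pk.ResidueMeasurement("A1", "cyflumetofen", 0.02),
        pk.ResidueMeasurement("B1", "pyrimethanil", 0.1),
    )
    return pk.ResidueDataset(measurements, n_samples_total=3)
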