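import numpy as np
import pytest

from afidreg.io import FiducialRecord, FiducialSet, load_template_consensus


@pytest.fixture(scope="session")
def consensus():
    return load_template_consensus()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_set():
    """Factory building a FiducialSet from {afid_id: (x, y, z)}."""

    def _make(
        coords: dict,
        subject="sub-01",
        rater="rater-A",
        space="subject",
        labels: dict | None = None,
    ) -> FiducialSet:
        records = tuple(
            FiducialRecord(
                afid_id=i,
                label=(labels or {}).get(i, f"AFID{i:02d}" if i else "pt"),
                coordinate=np.asarray(xyz, dtype=float),
                rater_id=rater,
                subject_id=subject,
                space=space,
            )
            for i, xyz in coords.items()
        )
        return FiducialSet(records=records)

    return _make
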