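import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_ct_table() -> pd.DataFrame:
    """Two samples x two target genes + one reference, 1 bio x 2 tech reps."""
    rows = []
    for sid, date, cultivar, bio in [
        ("S1", "2017-10-01", "A", 1),
        ("S2", "2017-10-08", "A", 1),
    ]:
        for gene, ct in [("G1", 24.0), ("G2", 26.0), ("REF", 20.0)]:
            for tech in (1, 2):
                rows.append(
                    dict(sample_id=sid, date=date, cultivar=cultivar, gene=gene,
                         bio_rep=bio, tech_rep=tech, ct=ct, quality=1.0)
                )
    return pd.DataFrame(rows)
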