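import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from favtree.io import BestMatchTable

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_self_table(taxon: str, log_evalues) -> BestMatchTable:
    """Self best-match table: each gene is its own best hit."""
    records = {f"{taxon}_g{i}": (f"{taxon}_g{i}", float(e)) for i, e in enumerate(log_evalues)}
    return BestMatchTable(taxon, taxon, records)


def make_cross_table(query: str, subject: str, self_table: BestMatchTable, log_evalues) -> BestMatchTable:
    """Cross table matched gene-for-gene to a self table."""
    genes = list(self_table.records)
    records = {g: (f"{subject}_g{i}", float(e)) for i, (g, e) in enumerate(zip(genes, log_evalues))}
    return BestMatchTable(query, subject, records)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
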