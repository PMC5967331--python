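import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from relapsetrio.simulate import CnaSpec, SimulationConfig, simulate_trio
from relapsetrio.trio_io import ALLELE_COUNT_COLUMNS, BaitIntervals

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_counts(rows: list[dict]) -> pd.DataFrame:
    """Allele-count table from terse row dicts (gene optional)."""
    defaults = dict(qphred=60.0, variant_class="SNV", functional="missense",
                    pop_af=float("nan"), gene=None)
    full = []
    for r in rows:
        d = {**defaults, **r}
        if "ref" not in d:
            d["ref"], d["alt"] = "A", "T"
        full.append(d)
    return pd.DataFrame(full, columns=ALLELE_COUNT_COLUMNS + ["gene"])


def wide_baits(chroms=("chr1",), size=10_000_000) -> BaitIntervals:
    return BaitIntervals((c, 0, size) for c in chroms)


@pytest.fixture(scope="session")
def linear_sim():
    """One deterministic linear trio shared by read-only tests."""
    cfg = SimulationConfig.for_mode("linear", seed=7, n_germline_snps=300,
                                    n_cna_snps=0)
    return simulate_trio(cfg)


@pytest.fixture(scope="session")
def cna_sim():
    """A purity-0.8 trio with one gain, one loss and one cn-LOH event."""
    events = (
        CnaSpec("chr1", 1, 8_000_000, 3, 1),
        CnaSpec("chr2", 1, 8_000_000, 1, 0),
        CnaSpec("chr3", 1, 8_000_000, 2, 0),
    )
    cfg = SimulationConfig.for_mode("linear", seed=3, n_germline_snps=50,
                                    n_cna_snps=1500, purity_diagnosis=0.8,
                                    cna_events=events)
    return simulate_trio(cfg)
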