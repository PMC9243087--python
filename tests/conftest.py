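import pytest

from clonopanel import SimulationConfig, simulate_cohort
from clonopanel.panel import PanelResources


@pytest.fixture(scope="session")
def small_bundle():
    """Six-patient cohort on a 300 kb toy panel, moderately contaminated."""
    cfg = SimulationConfig(
        n_patients=6, panel_size=300_000, seed=1,
        somatic_rate_per_mb=20.0, contamination_fraction_range=(0.05, 0.3),
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def tiny_resources():
    """Hand-built panel: one 60 b contig, fully targeted, with one hotspot."""
    #          0         1         2         3         4         5
    #          0123456789012345678901234567890123456789012345678901234567890
    reference = "ATCAGGATTGCATCATTTGATCGGGATCAGTACGTGCATTCAGGATTGCATCATTTGAT"
    return PanelResources(
        targets={"chrT": [(0, 59)]},
        reference={"chrT": reference},
        hotspots={("chrT", 13): ("KRAS", "G12")},
        artifact_pool={("chrT", 21, "T", "A")},
        genes=[("chrT", 0, 59, "KRAS")],
    )
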