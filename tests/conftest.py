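import pytest

from xcimap.synthetic import (
    IndividualSpec,
    SimConfig,
    simulate_cohort,
    simulate_single_cells,
)


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort: 8 PAR / 30 escape / 120 inactive genes,
    4 XX (one cXCI), 3 XY, 1 X0 donors, six cell types."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def sc_setup():
    """Non-skewed (pi=0.5) single-cell run: ~200 cells, no leakage."""
    cfg = SimConfig(seed=23, n_cells_per_type=34)  # 6 x 34 = 204 cells
    result = simulate_cohort(cfg)
    cells = simulate_single_cells(cfg, result.truth)
    return cfg, result, cells


@pytest.fixture()
def toy_annotation():
    from xcimap.io_formats import GeneAnnotation

    return [
        GeneAnnotation("ESC1", "chrX", 5_000_000, "+", "nonPAR", "escape"),
        GeneAnnotation("INA1", "chrX", 6_000_000, "+", "nonPAR", "inactive"),
        GeneAnnotation("INA2", "chrX", 7_000_000, "-", "nonPAR", "inactive", True),
        GeneAnnotation("PAR1G", "chrX", 1_000_000, "+", "PAR1", "escape"),
        GeneAnnotation("AUT1", "chr2", 1_000_000, "+", "autosome", "unknown"),
    ]
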