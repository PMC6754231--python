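import numpy as np
import pytest

from grnqg import simdata
from grnqg.dataio import GenotypeMatrix, MarkerMap


@pytest.fixture(scope="session")
def small_map() -> MarkerMap:
    """Two chromosomes, five markers each, 10 cM spacing."""
    ids, chroms, bps, cms = [], [], [], []
    for c in ("I", "II"):
        for k in range(5):
            ids.append(f"{c}:{(k + 1) * 100000}")
            chroms.append(c)
            bps.append((k + 1) * 100000)
            cms.append(10.0 * k)
    return MarkerMap.from_arrays(ids, chroms, bps, cms)


@pytest.fixture(scope="session")
def small_panel(small_map):
    """Deterministic 8-strain homozygous panel on the small map."""
    rng = np.random.default_rng(11)
    vals = 2 * rng.integers(0, 2, size=(8, len(small_map.marker_ids)))
    return GenotypeMatrix([f"S{i}" for i in range(8)], small_map.marker_ids,
                          vals.astype(np.int8))


@pytest.fixture(scope="session")
def structured_panel():
    """Differentiated two-subpopulation panel used by mixed-model tests."""
    cfg = simdata.SimulationConfig(
        seed=202, n_strains=50, chromosomes=(("I", 60.0), ("II", 60.0)),
        markers_per_chromosome=100, n_subpopulations=2, fst=0.2)
    return simdata.simulate_isolate_panel(cfg)


@pytest.fixture(scope="session")
def ril_cross(small_map):
    """100 selfed RILs on the small map, plus the cross container."""
    from grnqg.qtlmap import CrossPopulation

    m = len(small_map.marker_ids)
    gm = simdata.simulate_ril_population(
        np.zeros(m, dtype=np.int8), np.ones(m, dtype=np.int8), small_map,
        n_rils=100, selfing_generations=10, seed=7)
    return CrossPopulation(gm, small_map)
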