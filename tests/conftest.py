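import numpy as np
import pandas as pd
import pytest

import recessmap as rm


def small_config(seed: int = 11, **overrides) -> rm.SimulationConfig:
    """A reduced study (shorter chromosome, smaller herd) for fast unit tests;
    the founder sire is used more heavily so a small population still yields
    enough homozygotes."""
    params = dict(
        seed=seed,
        n_generations=6,
        generation_size=250,
        n_founder_males=20,
        n_founder_females=150,
        founders_per_generation=5,
        founder_sire_usage_fraction=0.15,
        chrom_length=20_000_000,
        n_chip_markers=400,
        causal_pos=14_000_000,
        n_background_variants=500,
        n_genes=15,
        n_affected=8,
        n_controls=40,
    )
    params.update(overrides)
    return rm.SimulationConfig(**params)


@pytest.fixture(scope="session")
def small_study() -> rm.SimulatedStudy:
    return rm.simulate_study(small_config())


@pytest.fixture(scope="session")
def small_scan(small_study):
    return rm.scan(small_study.genotypes, small_study.marker_map,
                   small_study.phenotypes)


@pytest.fixture(scope="session")
def small_top_interval(small_study, small_scan):
    intervals = rm.detect_intervals(small_scan, small_study.genotypes,
                                    small_study.phenotypes)
    assert intervals, "small fixture must produce a homozygous interval"
    return intervals[0]


def grid_lrt(n1, n2, n3, f1, step=1e-4):
    """Independent LRT oracle: maximize the trinomial genotype log-likelihood
    over a p-grid of the given step, with one local refinement pass around the
    best grid point so grid resolution does not limit the comparison."""
    def ll(p):
        p = np.asarray(p, dtype=float)
        out = np.zeros_like(p)
        with np.errstate(divide="ignore", invalid="ignore"):
            for count, prob in ((n1, p * p), (n2, 2 * p * (1 - p)),
                                (n3, (1 - p) ** 2)):
                if count:
                    out = out + count * np.log(prob)
        return out
    grid = np.arange(0.0, 1.0 + step / 2, step)
    vals = ll(grid)
    j = int(np.nanargmax(vals))
    lo, hi = max(grid[j] - step, 0.0), min(grid[j] + step, 1.0)
    best = max(float(np.nanmax(ll(np.linspace(lo, hi, 20001)))), float(vals[j]))
    return 2.0 * (best - float(ll(np.array([f1]))[0]))


def toy_marker_map(n: int, chrom: str = "1", spacing: int = 1000,
                   alleles=("A", "G")) -> rm.MarkerMap:
    return rm.MarkerMap(pd.DataFrame({
        "marker_id": [f"m{i}" for i in range(n)],
        "chrom": chrom,
        "pos": np.arange(1, n + 1) * spacing,
        "allele1": alleles[0],
        "allele2": alleles[1],
    }))


def toy_matrix(rows: dict[str, list[int]], marker_map=None) -> rm.GenotypeMatrix:
    n = len(next(iter(rows.values())))
    mm = marker_map if marker_map is not None else toy_marker_map(n)
    data = np.array(list(rows.values()), dtype=np.int8)
    return rm.GenotypeMatrix(list(rows), mm, data)
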