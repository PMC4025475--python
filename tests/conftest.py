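import numpy as np
import pandas as pd
import pytest

from plasticqtl import (
    CrossDataset,
    GenotypeMatrix,
    PhenotypeTable,
    PlantedEffect,
    SimulationConfig,
    simulate_cross,
)


@pytest.fixture()
def toy_files(tmp_path):
    """3-segregant x 4-marker toy TSV fixtures (genotypes, phenotypes, map)."""
    gpath = tmp_path / "geno.tsv"
    gpath.write_text(
        "marker\ts1\ts2\ts3\n"
        "m1\tS\tY\tS\n"
        "m2\tS\tY\tNA\n"
        "m3\tY\tY\tS\n"
        "m4\tY\tS\tS\n"
    )
    mpath = tmp_path / "map.tsv"
    mpath.write_text(
        "marker\tchromosome\tposition_bp\n"
        "m1\tI\t100\n"
        "m2\tI\t2000\n"
        "m3\tII\t500\n"
        "m4\tII\t9000\n"
    )
    ppath = tmp_path / "pheno.tsv"
    lines = ["segregant\tenvironment\tparameter\tvalue"]
    vals = {"s1": 1.0, "s2": 2.0, "s3": 3.0}
    for seg, v in vals.items():
        for env in ("glucose", "ethanol"):
            lines.append(f"{seg}\t{env}\tdoubling_time\t{v}")
    ppath.write_text("\n".join(lines) + "\n")
    return gpath, ppath, mpath


def make_genotypes(calls, chrom=None, bp=None, ids=None):
    """Build a GenotypeMatrix from a (n_seg, n_marker) 0/1/NaN array."""
    calls = np.asarray(calls, dtype=float)
    n_seg, n_mark = calls.shape
    chrom = chrom if chrom is not None else [1] * n_mark
    bp = bp if bp is not None else [100 * (j + 1) for j in range(n_mark)]
    markers = pd.DataFrame({
        "id": ids if ids is not None else [f"m{j + 1}" for j in range(n_mark)],
        "chromosome": chrom,
        "position_bp": bp,
    })
    return GenotypeMatrix([f"s{i + 1}" for i in range(n_seg)], markers, calls)


def make_phenotypes(seg_ids, env_values, parameter="doubling_time"):
    """PhenotypeTable from {environment: vector} mapping."""
    envs = list(env_values)
    values = np.stack([np.asarray(env_values[e], dtype=float) for e in envs], axis=1)
    return PhenotypeTable(list(seg_ids), envs, [parameter], values[:, :, None])


@pytest.fixture()
def small_cross():
    """Simulated 144-segregant cross, 4 chromosomes, one planted additive QTL."""
    cfg = SimulationConfig(
        chromosomes=[(c, 100.0, 20) for c in range(1, 5)],
        environments=["glucose", "ethanol"],
        parameters=["doubling_time"],
        planted_effects=[PlantedEffect("additive", ((2, 50.0),), {"glucose": 1.2})],
        seed=42,
    )
    return simulate_cross(cfg), cfg
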