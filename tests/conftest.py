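from __future__ import annotations

import numpy as np
import pytest

from ageguess.datamodel import FeatureAnnotation, MethylomeMatrix, SampleMetadata


@pytest.fixture
def tiny_matrix() -> MethylomeMatrix:
    values = np.array(
        [
            [0.1, 0.2, 0.3],
            [0.5, np.nan, 0.7],
            [0.9, 0.8, 0.85],
        ]
    )
    return MethylomeMatrix(["cg01", "cg02", "cg03"], ["s1", "s2", "s3"], values)


@pytest.fixture
def tiny_metadata() -> list[SampleMetadata]:
    return [
        SampleMetadata("s1", 25.0, "male"),
        SampleMetadata("s2", 50.0, "female"),
        SampleMetadata("s3", 75.0, "unknown"),
    ]


@pytest.fixture
def tiny_annotation() -> list[FeatureAnnotation]:
    return [
        FeatureAnnotation("cg01", "1", "GENE1"),
        FeatureAnnotation("cg02", "chrX", None),
        FeatureAnnotation("cg03", "22", "GENE3"),
    ]


def make_planted_matrix(
    n: int,
    n_noise: int,
    n_planted: int,
    seed: int,
    slope: float = 0.005,
    noise_sd: float = 0.01,
):
    """Small hand-rolled dataset: planted linear-in-age probes plus noise.

    Independent of the package's synthetic_data module so selection tests
    do not lean on the generator they also exercise elsewhere.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(20, 100, size=n)
    rows = []
    ids = []
    for j in range(n_planted):
        s = slope if j % 2 == 0 else -slope
        b0 = 0.5 - s * 60
        rows.append(np.clip(b0 + s * ages + rng.normal(0, noise_sd, n), 0.001, 0.999))
        ids.append(f"pl{j:03d}")
    for j in range(n_noise):
        rows.append(np.clip(rng.uniform(0.2, 0.8) + rng.normal(0, noise_sd, n), 0.001, 0.999))
        ids.append(f"nz{j:03d}")
    matrix = MethylomeMatrix(ids, [f"s{i:03d}" for i in range(n)], np.array(rows))
    return matrix, ages, ids[:n_planted]
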