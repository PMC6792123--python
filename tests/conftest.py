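"""Shared fixtures: synthetic datasets and fitted kernel builders."""

import numpy as np
import pytest

from gxepred.bemkl import KernelWeightModel, environment_mean_targets
from gxepred.datamodel import extract_season, ztransform_yields
from gxepred.kernels import EnvironmentKernelBuilder, GenomicKernelBuilder
from gxepred.synthdata import SimConfig, simulate


@pytest.fixture(scope="session")
def small_dataset():
    """A quick 80-line, 12-environment breeding experiment."""
    return simulate(SimConfig(
        n_parents=20, n_progeny=60, n_markers=150, n_locations=4,
        years=(2010, 2011, 2012), seed=1))


@pytest.fixture(scope="session")
def default_dataset():
    """The default desk-scale experiment: 200 lines x 30 environments."""
    return simulate(SimConfig(seed=3))


def build_environment(dataset, registry=None):
    env_table = dataset.trials.environments
    seasons = {k: extract_season(w) for k, w in dataset.weather.items()}
    builder = EnvironmentKernelBuilder(registry)
    blocks = builder.covariate_blocks(env_table, seasons, dataset.soils, dataset.zones)
    builder.fit(blocks, env_table["env"].to_numpy(dtype=object))
    return builder


@pytest.fixture(scope="session")
def small_builders(small_dataset):
    """(genomic builder, environment builder, composite Ke) on the small set."""
    gkb = GenomicKernelBuilder().fit(
        small_dataset.genotypes.dosages, list(small_dataset.genotypes.line_ids))
    builder = build_environment(small_dataset)
    tz = ztransform_yields(small_dataset.trials)
    ids, targets = environment_mean_targets(tz)
    tmap = dict(zip(ids, targets))
    y_env = np.array([tmap[e] for e in builder.ids])
    weights = KernelWeightModel(builder.kernel_set, y_env).fit(seed=0).weights
    Ke = builder.composite(weights)
    return gkb, builder, Ke


@pytest.fixture(scope="session")
def default_builders(default_dataset):
    gkb = GenomicKernelBuilder().fit(
        default_dataset.genotypes.dosages, list(default_dataset.genotypes.line_ids))
    builder = build_environment(default_dataset)
    Ke = builder.composite(np.full(len(builder.kernel_set), 1 / np.sqrt(8)))
    return gkb, builder, Ke
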