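"""Shared fixtures: synthetic bundles and pipeline runs at two scales.

The small bundle exercises every stage quickly; the study-scale bundle
(500 miRNAs, 10^5 reads per library) backs the parameter-recovery
checks.  Both are generated once per session.
"""

from __future__ import annotations

import json

import pytest

from mejamir.config import RunConfig
from mejamir.pipeline import run_all
from mejamir.synthetic_data import SynthConfig, generate, truth_eval


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    path = tmp_path_factory.mktemp("bundle_small")
    cfg = SynthConfig(seed=1, depth=20_000)
    truth = generate(cfg, path)
    return path, truth


@pytest.fixture(scope="session")
def small_run(small_bundle, tmp_path_factory):
    inp, truth = small_bundle
    out = tmp_path_factory.mktemp("run_small")
    manifest = run_all(RunConfig(seed=1), inp, out, stem_permutations=2000)
    return out, truth, manifest


@pytest.fixture(scope="session")
def small_metrics(small_run):
    out, truth, _ = small_run
    return truth_eval(out, truth)


@pytest.fixture(scope="session")
def study_scale_run(tmp_path_factory):
    """500 miRNAs at 10^5 clean reads per library, fixed seed."""
    inp = tmp_path_factory.mktemp("bundle_study")
    cfg = SynthConfig(seed=1, depth=100_000, n_known=500, n_extra_ref=50,
                      n_genes=200)
    truth = generate(cfg, inp)
    out = tmp_path_factory.mktemp("run_study")
    run_all(RunConfig(seed=1), inp, out)
    return out, truth


@pytest.fixture(scope="session")
def study_scale_metrics(study_scale_run):
    out, truth = study_scale_run
    return truth_eval(out, truth)
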