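import numpy as np
import pytest

from cecgkit import (
    GeneratorConfig,
    TrainConfig,
    assemble_dataset,
    build_spec,
    generate_dataset,
    train_model,
)
from cecgkit.crossval import POSITION_LABELS, QUALITY_LABELS, task_arrays
from cecgkit.simulate import DEFAULT_PROFILES, DEFAULT_QUALITY_SPECS, DEFAULT_TEMPLATE

FS = 300.0

#: fast schedule used wherever a test needs a trained model
FAST_TRAIN = TrainConfig(learning_rate=3e-3, max_epochs=12, early_stop_patience=3, seed=0)


@pytest.fixture(scope="session")
def template():
    return DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def profiles():
    return DEFAULT_PROFILES


@pytest.fixture(scope="session")
def quality_specs():
    return DEFAULT_QUALITY_SPECS


@pytest.fixture(scope="session")
def tiny_dataset_2s():
    """Small 2-s dataset covering every class the two tasks need."""
    counts = {
        ("C1", "S"): 28, ("C1", "L"): 28, ("C1", "R"): 28,
        ("C2", "S"): 18, ("C2", "L"): 18,
        ("N", "S"): 20, ("N", "L"): 20,
    }
    cfg = GeneratorConfig(counts=counts, seg_len_s=2.0)
    records = generate_dataset(cfg, seed=42)
    return assemble_dataset(records, cfg.seg_len_s, cfg.overlap_frac)


@pytest.fixture(scope="session")
def trained_models_2s(tiny_dataset_2s):
    """Quality gate + position classifier fitted on the tiny 2-s dataset."""
    ds = tiny_dataset_2s
    models = {}
    for task, classes in (("quality", QUALITY_LABELS), ("position", POSITION_LABELS)):
        X, labels, _ = task_arrays(ds, task)
        spec = build_spec(3, X.shape[1], ds.fs, n_classes=len(classes))
        models[task] = train_model(spec, X, labels, config=FAST_TRAIN, label_map=classes)
    return models


@pytest.fixture(scope="session")
def trained_models_4s():
    """Study-depth 4-s models (quality depth 6, position depth 7)."""
    counts = {("C1", p): 60 for p in "SLR"}
    counts |= {("C2", p): 20 for p in "SLR"}
    counts |= {("N", p): 20 for p in "SLR"}
    cfg = GeneratorConfig(counts=counts, seg_len_s=4.0, records_per_cell=4)
    ds = assemble_dataset(generate_dataset(cfg, seed=2024), cfg.seg_len_s, cfg.overlap_frac)
    schedule = TrainConfig(learning_rate=3e-3, max_epochs=30, early_stop_patience=30, seed=0)
    models = {}
    for task, depth, classes in (("quality", 6, QUALITY_LABELS),
                                 ("position", 7, POSITION_LABELS)):
        X, labels, _ = task_arrays(ds, task)
        spec = build_spec(depth, X.shape[1], ds.fs, n_classes=len(classes))
        models[task] = train_model(spec, X, labels, config=schedule, label_map=classes)
    return models


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
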