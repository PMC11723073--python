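"""Training loop: schedule, determinism, checkpointing, history."""

import numpy as np
import pytest

from fundusgan.gan import CriticModel, GeneratorModel, LossWeights
from fundusgan.train import (HISTORY_COLUMNS, TrainConfig, _Trainer,
                             history_to_csv, load_generator,
                             prepare_conditions, train)


@pytest.fixture(scope="module")
def short_run(dataset40, quick_grader):
    config = TrainConfig(steps=6, seed=11, checkpoint_every=3)
    cache = prepare_conditions(dataset40, quick_grader, config.feature_layer)
    return dataset40, quick_grader, config, cache


def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(steps=1, n_critic=0)
    with pytest.raises(ValueError):
        TrainConfig(steps=1, side=60)
    with pytest.raises(ValueError):
        TrainConfig(steps=1, dtype="float16")


def test_config_meta_round_trip():
    cfg = TrainConfig(steps=9, seed=3, weights=LossWeights(wp=0.5, ws=2.0),
                      dtype="float64")
    assert TrainConfig.from_meta(cfg.to_meta()) == cfg


def test_zero_learning_rate_keeps_initialization(short_run):
    data, grader, _, cache = short_run
    config = TrainConfig(steps=2, seed=1, lr=0.0)
    res = train(data, grader, config, conditions_cache=cache)
    gen0 = GeneratorModel(side=config.side, base_width=config.base_width,
                          z_dim=config.z_dim, resample=config.resample,
                          init_seed=config.seed)
    crit0 = CriticModel(side=config.side, base_width=config.base_width,
                        init_seed=config.seed + 1)
    for k, p in res.generator.params.items():
        assert np.array_equal(p.data, gen0.params[k].data.astype(p.data.dtype))
    for k, p in res.critic.params.items():
        assert np.array_equal(p.data, crit0.params[k].data.astype(p.data.dtype))


def test_history_schedule_and_columns(short_run, tmp_path):
    data, grader, config, cache = short_run
    res = train(data, grader, config, conditions_cache=cache)
    assert res.history.shape == (config.steps, len(HISTORY_COLUMNS))
    assert np.array_equal(res.history[:, 0], np.arange(1, config.steps + 1))
    assert res.completed_steps == config.steps and not res.aborted
    path = tmp_path / "history.csv"
    history_to_csv(res.history, path)
    lines = path.read_text().splitlines()
    assert lines[0] == ",".join(HISTORY_COLUMNS)
    assert len(lines) == config.steps + 1


def test_rerun_is_bitwise_identical(short_run):
    data, grader, config, cache = short_run
    r1 = train(data, grader, config, conditions_cache=cache)
    r2 = train(data, grader, config, conditions_cache=cache)
    assert np.array_equal(r1.history, r2.history)
    for k in r1.generator.params:
        assert np.array_equal(r1.generator.params[k].data, r2.generator.params[k].data)
    for k in r1.critic.params:
        assert np.array_equal(r1.critic.params[k].data, r2.critic.params[k].data)


def test_resume_matches_unbroken_run(short_run, tmp_path):
    data, grader, config, cache = short_run
    full = train(data, grader, config, conditions_cache=cache,
                 checkpoint_dir=tmp_path / "a")
    resumed = train(data, grader, config, conditions_cache=cache,
                    resume_from=tmp_path / "a" / "gan_step000003.ckpt")
    assert np.array_equal(full.history, resumed.history)
    for k in full.generator.params:
        assert np.array_equal(full.generator.params[k].data,
                              resumed.generator.params[k].data)
    for k in full.critic.params:
        assert np.array_equal(full.critic.params[k].data,
                              resumed.critic.params[k].data)


def test_resume_rejects_changed_conditions(short_run, tmp_path):
    data, grader, config, cache = short_run
    train(data, grader, config, conditions_cache=cache, checkpoint_dir=tmp_path)
    altered = TrainConfig(steps=6, seed=12, checkpoint_every=3)
    with pytest.raises(ValueError, match="resume"):
        train(data, grader, altered, conditions_cache=cache,
              resume_from=tmp_path / "gan_step000003.ckpt")


def test_checkpoint_save_load_save_byte_identical(short_run, tmp_path):
    data, grader, config, cache = short_run
    train(data, grader, config, conditions_cache=cache, checkpoint_dir=tmp_path)
    final = tmp_path / "gan_final.ckpt"
    trainer = _Trainer.load(final)
    resaved = tmp_path / "resaved.ckpt"
    trainer.save(resaved)
    assert final.read_bytes() == resaved.read_bytes()


def test_load_truncated_checkpoint_fails(short_run, tmp_path):
    data, grader, config, cache = short_run
    train(data, grader, config, conditions_cache=cache, checkpoint_dir=tmp_path)
    final = tmp_path / "gan_final.ckpt"
    blob = final.read_bytes()
    broken = tmp_path / "broken.ckpt"
    broken.write_bytes(blob[: len(blob) // 2])
    with pytest.raises(Exception):
        _Trainer.load(broken)


def test_grader_is_not_mutated(short_run):
    data, grader, config, cache = short_run
    before = {k: v.data.copy() for k, v in grader.params.items()}
    train(data, grader, config, conditions_cache=cache)
    for k, v in grader.params.items():
        assert np.array_equal(v.data, before[k])


def test_load_generator_round_trip(short_run, tmp_path):
    data, grader, config, cache = short_run
    res = train(data, grader, config, conditions_cache=cache,
                checkpoint_dir=tmp_path)
    gen, cfg = load_generator(tmp_path / "gan_final.ckpt")
    assert cfg == config
    for k in res.generator.params:
        assert np.array_equal(gen.params[k].data, res.generator.params[k].data)
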