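import dataclasses

import numpy as np
import pytest

from histofusion import network, pipeline, sae, synthetic


@pytest.fixture(scope="session")
def tiny_spec():
    """Six-class dataset small enough for sub-second generation."""
    return synthetic.SyntheticSpec(
        class_counts=(5, 6, 5, 5, 7, 5),
        source_size=(96, 72),
        patch_size=64,
        target_size=32,
        patches_per_image=2,
        seed=0,
    )


@pytest.fixture(scope="session")
def tiny_pipeline_config(tiny_spec):
    return pipeline.PipelineConfig(
        spec=tiny_spec,
        net=network.scaled_network_config(input_size=32),
        train=network.TrainConfig(batch_size=16, epochs=3),
        sae_hidden=16,
        sae_opt=sae.SAEOptConfig(epochs=150),
        master_seed=7,
    )


@pytest.fixture(scope="session")
def tiny_trained(tiny_spec):
    """A briefly trained desk-scale network plus its patch dataset."""
    data = synthetic.make_patch_dataset(tiny_spec)
    net = network.build_network(network.scaled_network_config(input_size=32), seed=3)
    network.train_network(
        net, data, network.TrainConfig(batch_size=16, epochs=2, seed=3)
    )
    return net, data


@pytest.fixture(scope="session")
def desk_scale_result():
    """One full desk-scale three-arm run (the study conditions: six classes
    at scale 32/140 with the proportionally shrunk network)."""
    cfg = pipeline.desk_scale_config(master_seed=11)
    return cfg, pipeline.run_pipeline(cfg)
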