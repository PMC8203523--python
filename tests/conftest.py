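import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from bfnet import synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_session(tmp_path_factory):
    """A compact but complete synthetic session shared across tests.

    Two small cortical probes and a BF stub, one low-gamma hotspot in the
    decision epoch, a cholinergic light-responsive unit with an STA
    effect, one excitatory coupling, and the optotagging protocol.
    """
    cfg = synth.SynthConfig(
        seed=2026, n_trials=10,
        probes=[synth.ProbeLayout("BF", 2, 4), synth.ProbeLayout("OFC", 2, 4),
                synth.ProbeLayout("V2", 2, 4)],
        hotspots=[synth.HotspotSpec(channel_pairs=((8, 16), (9, 17)),
                                    band="low_gamma", epoch="decision",
                                    coupling=0.9)],
        units=[
            synth.cholinergic_unit(0),
            synth.UnitSpec(1, region="BF", mean_rate_hz=6.0, template="narrow"),
            synth.UnitSpec(2, region="OFC", mean_rate_hz=6.0),
            synth.UnitSpec(3, region="OFC", mean_rate_hz=8.0, template="narrow"),
            synth.UnitSpec(4, region="V2", mean_rate_hz=5.0),
            synth.UnitSpec(5, region="V2", mean_rate_hz=4.0,
                           epoch_rate_gain=(("decision", 2.0),)),
        ],
        couplings=[synth.CouplingSpec(pre=2, post=3, efficacy=0.3)],
        sta_effects=[synth.StaEffectSpec(trigger_unit=0, target_channels=(16,),
                                         band="low_gamma", gain=2.0)],
        light=synth.LightSpec(),
    )
    out = tmp_path_factory.mktemp("session")
    lfp, units, epochs, light, truth = synth.generate_dataset(cfg, out)
    return dict(config=cfg, dir=out, lfp=lfp, units=units, epochs=epochs,
                light=light, truth=truth)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
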