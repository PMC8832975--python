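import pytest

from famseg.channel import channel_preset, simulate_sweep
from famseg.cohort import SweepSet
from famseg.examples import af_family, candidate_variants
from famseg.genotypes import simulate_pedigree_genotypes
from famseg.protocols import protocol_preset


@pytest.fixture(scope="session")
def family():
    return af_family()


@pytest.fixture(scope="session")
def candidates():
    return candidate_variants()


@pytest.fixture(scope="session")
def family_genotypes(family, candidates):
    """Planted co-segregation genotypes for the three candidate variants."""
    return simulate_pedigree_genotypes(family, candidates, seed=11)


def noiseless_sweepset(preset: str, protocol_name: str, cm: float = 15.0) -> SweepSet:
    params = channel_preset(preset)
    proto = protocol_preset(protocol_name)
    sweeps = {
        float(lv): simulate_sweep(params, proto, lv, capacitance_pF=cm)[1]
        for lv in proto.sweep_levels
    }
    return SweepSet(
        cell_id=f"{preset}_{protocol_name}",
        group=preset.upper(),
        protocol=proto,
        capacitance_pF=cm,
        time_ms=proto.times(),
        sweeps=sweeps,
        truth=params,
    )


@pytest.fixture(scope="session")
def wt_iv_cell():
    return noiseless_sweepset("wt", "iv")


@pytest.fixture(scope="session")
def mutant_iv_cell():
    return noiseless_sweepset("v1686m", "iv")


@pytest.fixture(scope="session")
def wt_ssi_cell():
    return noiseless_sweepset("wt", "ssi")


@pytest.fixture(scope="session")
def wt_slow_inact_cell():
    return noiseless_sweepset("wt", "slow_inact")
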