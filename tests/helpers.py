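"""Shared toy-model builders for the test suite."""

from dsmcell.bk import BKParams
from dsmcell.calcium import CaPoolParams
from dsmcell.gating import HHChannelSpec
from dsmcell.geometry import CellGeometry, PassiveProperties
from dsmcell.simulator import CellModel
from dsmcell.trpm4 import TRPM4Params


def leak_only_model(e_leak: float = 0.0, gmax: float = None) -> CellModel:
    """Passive cell: ohmic leak only, every active conductance silenced."""
    geom = CellGeometry()
    passive = PassiveProperties(e_leak_mv=e_leak)
    g_leak = gmax if gmax is not None else 1.0 / (passive.rm_kohm_cm2 * 1e3)
    leak = HHChannelSpec("leak", g_leak, e_leak)
    return CellModel(
        geometry=geom,
        passive=passive,
        hh_channels=(leak,),
        bk=BKParams(gmax_s_cm2=0.0),
        trpm4=TRPM4Params(gmax_s_cm2=0.0),
        ca_pool=CaPoolParams(),
    )
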