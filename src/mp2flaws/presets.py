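"""Tissue parameter sets and the published protocol presets.

Adult 7T literature values for WM/GM/CSF relaxation and proton density are
bundled, together with the three initial protocols (TR_MP2RAGE 4000/4500/
5000 ms, TI 650/2220 ms, partial Fourier 6/8 in both phase-encode
directions) and the final 0.65 mm protocol (TR 4000 ms, TR_GRE 7.9 ms,
TI 650/2280 ms, flips 4/5 deg, partial Fourier 6/8 in the partition
direction only).  Protocols and tissue sets can also be read from YAML.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .epg import SpoilingSchedule, TissueParams
from .sequence import SequenceParams, center_index

__all__ = [
    "WM", "GM", "CSF", "TISSUES", "DEFAULT_B1_SCALES", "CONFIG_DIR",
    "table1_protocol", "final_protocol", "load_tissues", "load_protocol",
]

#: bundled YAML configs for the published protocols and tissue set
CONFIG_DIR = Path(__file__).parent / "configs"

# apparent diffusion coefficients are not part of the published tissue set;
# these are standard adult literature values (mm^2/s)
WM = TissueParams("WM", T1=1220.0, T2=45.9, PD=0.69, D=0.70e-3)
GM = TissueParams("GM", T1=2132.0, T2=55.0, PD=0.82, D=0.80e-3)
CSF = TissueParams("CSF", T1=3350.0, T2=1000.0, PD=1.0, D=3.0e-3)

TISSUES = {"WM": WM, "GM": GM, "CSF": CSF}

#: transmit-field scaling factors spanning the 7T B1+ range (50%-140%)
DEFAULT_B1_SCALES = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))

#: optimal flip-angle pairs of the initial protocols, keyed by TR_MP2RAGE
_TABLE1_FLIPS = {4000.0: (5.0, 4.0), 4500.0: (5.0, 6.0), 5000.0: (5.0, 7.0)}


def table1_protocol(tr_mp2rage: float, alpha1: float | None = None,
                    alpha2: float | None = None, ti1: float = 650.0,
                    ti2: float = 2220.0) -> SequenceParams:
    """One of the initial 0.65 mm protocols (TR_GRE 7.26 ms, 180 exc/block).

    240 partition-encode steps with 6/8 partial Fourier give 180 excitations
    per GRE block with the k-space center on line 60.
    """
    flips = _TABLE1_FLIPS.get(float(tr_mp2rage), (5.0, 4.0))
    n_inner, pf = 240, 6.0 / 8.0
    return SequenceParams(
        tr_mp2rage=float(tr_mp2rage), tr_gre=7.26, ti1=ti1, ti2=ti2,
        alpha1=flips[0] if alpha1 is None else alpha1,
        alpha2=flips[1] if alpha2 is None else alpha2,
        n_exc=int(round(n_inner * pf)), k_center=center_index(n_inner, pf),
        te=3.15,
    )


def final_protocol() -> SequenceParams:
    """The suggested combined UNI+FLAWS protocol at TR_MP2RAGE = 4000 ms.

    256 slices per slab with 6/8 slice partial Fourier give 192 excitations
    per block, k-space center on line 64; TR_GRE 7.9 ms at 160 Hz/Px.
    """
    n_inner, pf = 256, 6.0 / 8.0
    return SequenceParams(
        tr_mp2rage=4000.0, tr_gre=7.9, ti1=650.0, ti2=2280.0,
        alpha1=4.0, alpha2=5.0,
        n_exc=int(round(n_inner * pf)), k_center=center_index(n_inner, pf),
        te=3.15,
    )


def load_tissues(path: str | Path) -> dict[str, TissueParams]:
    """Read a tissue set from YAML: ``{name: {T1, T2, PD, D}}``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return {
        name: TissueParams(name=name, T1=v["T1"], T2=v["T2"], PD=v["PD"],
                           D=v.get("D", 0.0))
        for name, v in raw.items()
    }


def load_protocol(path: str | Path) -> SequenceParams:
    """Read a protocol from YAML; keys mirror ``SequenceParams`` fields."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    spoil = raw.pop("spoiling", None)
    if spoil is not None:
        raw["spoiling"] = SpoilingSchedule(**spoil)
    if "k_center" not in raw and "n_inner" in raw:
        n_inner = raw.pop("n_inner")
        pf = raw.pop("partial_fourier", 1.0)
        raw["n_exc"] = int(round(n_inner * pf))
        raw["k_center"] = center_index(n_inner, pf)
    return SequenceParams(**raw)
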