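"""Fixed rat CNS physiology.

The model treats the central nervous system as a brain-tissue compartment and
a CSF compartment connected to plasma across two barriers (BBB and BCSFB) and
to each other by ECF bulk flow, with CSF drained back to plasma. The constants
below are literature rat values and are shared by all drugs; only the
drug-specific permeabilities and scaling factors vary.

Units are cm^3 (volumes), cm^3/s (flows), cm^2 (barrier surfaces) and mL per
gram of brain tissue for the water-space fractions used by the unbound brain
volume of distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, fields


@dataclass(frozen=True)
class Physiology:
    """Rat CNS constants.

    Attributes
    ----------
    v_b : float
        Brain tissue volume (cm^3).
    v_csf : float
        Cerebrospinal fluid volume (cm^3).
    q_bulk : float
        Bulk flow of brain ECF into the CSF (cm^3/s).
    q_sink : float
        CSF drainage flow back to plasma (cm^3/s).
    s_bbb : float
        Blood-brain barrier surface area (cm^2).
    s_bcsfb : float
        Blood-CSF barrier surface area (cm^2).
    v_ecf : float
        Brain extracellular water space (mL/g brain).
    v_icf : float
        Brain intracellular water space (mL/g brain).
    """

    v_b: float = 1.28
    v_csf: float = 0.25
    q_bulk: float = 0.012
    q_sink: float = 0.132
    s_bbb: float = 187.5
    s_bcsfb: float = 0.0375
    v_ecf: float = 0.2
    v_icf: float = 0.6

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"Physiology.{f.name} must be strictly positive")


DEFAULT_PHYSIOLOGY = Physiology()
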