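"""Per-compartment tissue parameter tables for the discovertebral complex (DVC).

The discovertebral complex of the rat tail is modelled as five tissue
compartments — nucleus pulposus (NP), annulus fibrosus (AF), cartilage
endplate (CEP), growth plate (GP), subchondral bone (SB) — plus the vertebral
body. Each compartment carries a longitudinal relaxation time T1 (ms), a
transverse relaxation time T2 (ms), a proton density (arbitrary units, sets
the spin-echo / gradient-echo signal scale) and an ultrashort-echo-time (UTE)
signal-to-noise target (the UTE amplitude is materialized at simulation time
as ``ute_snr * sigma``).

Healthy tables are constant across the three study timepoints (baseline D0,
week 1, week 2). Degenerative-disc-disease (DDD) tables differ from the
healthy ones only in the NP and AF entries: the induced lesion lowers NP
T2/T1 (loss of the water signal) and raises AF T2 (inflammation), with a
matching rise of both structures on UTE. Values that could not be measured in
vivo (GP relaxation times, CEP T1, the whole vertebral body) are package
defaults flagged ``assumed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LABEL_LEGEND",
    "STRUCTURES",
    "TissueParamTable",
    "tissue_params_for",
]

#: Integer label legend shared by every volume in the package.
LABEL_LEGEND: dict[int, str] = {
    0: "background",
    1: "NP",
    2: "AF",
    3: "CEP",
    4: "GP",
    5: "SB",
    6: "body",
}

#: The five quantified DVC structures (ROI set), tail-axis order within a unit.
STRUCTURES: tuple[str, ...] = ("NP", "AF", "CEP", "GP", "SB")

_NAME_TO_LABEL = {v: k for k, v in LABEL_LEGEND.items()}

MATURITIES = ("immature", "mature")
STATES = ("healthy", "ddd")
TIMEPOINTS = ("D0", "W1", "W2")

_COLUMNS = ["name", "t1_ms", "t2_ms", "proton_density", "ute_snr", "assumed"]

# Healthy baseline values per maturity. T1/T2 from the in-vivo study tables;
# GP T2, GP/CEP T1 and every vertebral-body entry are assumed (unmeasurable in
# vivo: GP must stay invisible on T2 maps, CEP/GP indistinguishable on T1).
# Proton densities are arbitrary units ordered by water content.
_HEALTHY = {
    "mature": {
        # label: (t1_ms, t2_ms, pd, ute_snr, assumed)
        1: (1810.0, 105.0, 100.0, 11.5, False),   # NP
        2: (803.0, 6.0, 90.0, 16.8, False),       # AF
        3: (900.0, 28.2, 95.0, 7.9, True),        # CEP (T1 assumed)
        4: (1200.0, 2.0, 85.0, 18.5, True),       # GP (T1, T2 assumed)
        5: (568.0, 96.1, 60.0, 17.1, False),      # SB
        6: (568.0, 96.1, 70.0, 15.0, True),       # vertebral body (assumed)
    },
    "immature": {
        1: (1894.0, 119.0, 100.0, 14.5, False),
        2: (835.0, 5.8, 90.0, 19.8, False),
        3: (900.0, 25.7, 95.0, 10.6, True),
        4: (1200.0, 2.0, 85.0, 23.5, True),
        5: (574.0, 84.8, 60.0, 12.9, False),
        6: (574.0, 84.8, 70.0, 12.0, True),
    },
}

# DDD overrides, NP/AF only. D0 is pre-induction, identical to healthy.
_DDD = {
    ("mature", "W1"): {
        1: {"t1_ms": 1712.0, "t2_ms": 51.8, "ute_snr": 35.7},
        2: {"t1_ms": 797.0, "t2_ms": 20.7, "ute_snr": 45.6},
    },
    ("mature", "W2"): {
        1: {"t1_ms": 1558.0, "t2_ms": 48.5, "ute_snr": 52.7},
        2: {"t1_ms": 827.0, "t2_ms": 14.7, "ute_snr": 57.1},
    },
    ("immature", "W1"): {
        1: {"t1_ms": 1608.0, "t2_ms": 50.1, "ute_snr": 18.0},
        2: {"t1_ms": 804.0, "t2_ms": 20.1, "ute_snr": 27.7},
    },
    ("immature", "W2"): {
        1: {"t1_ms": 1268.0, "t2_ms": 45.4, "ute_snr": 22.0},
        2: {"t1_ms": 712.0, "t2_ms": 18.6, "ute_snr": 28.1},
    },
}


@dataclass(frozen=True)
class TissueParamTable:
    """Tissue parameters for one (maturity, state, timepoint) study cell.

    ``frame`` is indexed by integer label (1..6) with columns
    ``name, t1_ms, t2_ms, proton_density, ute_snr, assumed``.
    """

    maturity: str
    state: str
    timepoint: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        if (f["t1_ms"] <= 0).any() or (f["t2_ms"] <= 0).any():
            raise ValueError("relaxation times must be positive")
        if (f["t2_ms"] >= f["t1_ms"]).any():
            bad = f.index[f["t2_ms"] >= f["t1_ms"]].tolist()
            raise ValueError(f"T2 must be shorter than T1 (labels {bad})")

    def param_array(self, column: str, max_label: int | None = None) -> np.ndarray:
        """Dense lookup ``value[label]`` for vectorized voxel-wise use.

        Background (label 0) gets proton density / UTE SNR 0 and harmless
        positive relaxation times.
        """
        n = (max_label if max_label is not None else int(self.frame.index.max())) + 1
        fill = 0.0 if column in ("proton_density", "ute_snr") else 1.0
        out = np.full(n, fill, dtype=float)
        for lab, val in self.frame[column].items():
            if lab < n:
                out[lab] = val
        return out

    def value(self, structure: str, column: str) -> float:
        """Parameter for one structure by name, e.g. ``value('NP', 't2_ms')``."""
        return float(self.frame.loc[_NAME_TO_LABEL[structure], column])

    def ute_amplitude(self, sigma: float) -> np.ndarray:
        """UTE amplitudes (a.u.) calibrated to the SNR targets at noise ``sigma``."""
        return self.param_array("ute_snr") * float(sigma)

    def to_dict(self) -> dict:
        return {
            "maturity": self.maturity,
            "state": self.state,
            "timepoint": self.timepoint,
            "labels": {
                int(lab): {c: (row[c] if c == "name" else (bool(row[c]) if c == "assumed" else float(row[c])))
                           for c in _COLUMNS}
                for lab, row in self.frame.iterrows()
            },
        }


def _frame_from(records: dict[int, tuple]) -> pd.DataFrame:
    rows = {
        lab: {
            "name": LABEL_LEGEND[lab],
            "t1_ms": t1,
            "t2_ms": t2,
            "proton_density": pdens,
            "ute_snr": snr,
            "assumed": assumed,
        }
        for lab, (t1, t2, pdens, snr, assumed) in records.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index")[_COLUMNS]


def tissue_params_for(maturity: str, state: str, timepoint: str) -> TissueParamTable:
    """Tissue parameter table for one study arm and timepoint.

    Healthy tables are identical at D0/W1/W2 (within-arm means); DDD tables
    equal the healthy one at D0 and override NP/AF at W1/W2.

    Raises
    ------
    ValueError
        For an unknown maturity, state or timepoint.
    """
    if maturity not in MATURITIES:
        raise ValueError(f"unknown maturity {maturity!r}; expected one of {MATURITIES}")
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}; expected one of {TIMEPOINTS}")

    frame = _frame_from(_HEALTHY[maturity])
    if state == "ddd" and timepoint != "D0":
        for lab, over in _DDD[(maturity, timepoint)].items():
            for col, val in over.items():
                frame.loc[lab, col] = val
    return TissueParamTable(maturity=maturity, state=state, timepoint=timepoint, frame=frame)
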