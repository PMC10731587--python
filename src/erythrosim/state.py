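"""Physiological state vector of the erythropoiesis model."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

#: order of the nine physiological states in the packed vector
PHYSIO_FIELDS = (
    "hif_alpha",
    "epo_plasma",
    "epo_periphery",
    "epor_free",
    "epo_lr_complex",
    "progenitors",
    "precursors",
    "retics_plasma",
    "rbc_m",
)


@dataclass
class ErythroState:
    """The nine physiological state variables.

    hif_alpha : a.u.; epo_plasma, epo_periphery : ng/mL;
    epor_free, epo_lr_complex : molecules/mL; the four cell species : cells/mL.
    """

    hif_alpha: float
    epo_plasma: float
    epo_periphery: float
    epor_free: float
    epo_lr_complex: float
    progenitors: float
    precursors: float
    retics_plasma: float
    rbc_m: float

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PHYSIO_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ErythroState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape[-1] < len(PHYSIO_FIELDS):
            raise ValueError("state array too short")
        return cls(**{f: float(arr[i]) for i, f in enumerate(PHYSIO_FIELDS)})

    def validate(self) -> None:
        for f in PHYSIO_FIELDS:
            if getattr(self, f) < 0:
                raise ValueError(f"state component {f} is negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ErythroState":
        return cls(**{f: float(d[f]) for f in PHYSIO_FIELDS})

    def replace(self, **kw) -> "ErythroState":
        return dataclasses.replace(self, **kw)
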