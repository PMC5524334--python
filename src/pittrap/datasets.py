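"""Embedded example data.

The Tasmania copepod abundances: twelve copepod species counted on 16
transects at Eagle Neck, Tasmania, in a randomized blocks design — four
blocks (sites A-D), and within each block two crab-disturbed and two
undisturbed transects.  The scientific question is whether disturbance
affects the community and whether that effect differs between blocks
(block x treatment interaction), jointly across all twelve species.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Dataset", "tasmania_dataset", "TASMANIA_SHA256"]

_TASMANIA_CSV = """\
treatment,block,Am,Ad,Ec(a),Ec(b),Ha,Le(a),Le(b),Le(c),Mi,Pa,Qu,Rh
Disturbed,A,43,0,0,1,0,30,1,0,0,0,0,1
Disturbed,A,63,0,0,15,0,97,11,0,0,0,0,0
Undisturbed,A,124,0,0,7,2,151,0,0,0,0,2,6
Undisturbed,A,105,0,2,7,0,117,0,0,0,1,3,6
Disturbed,B,4,0,0,14,0,27,3,0,8,2,0,0
Disturbed,B,5,0,0,4,0,35,0,0,3,0,0,0
Undisturbed,B,91,0,0,4,0,15,2,0,0,0,0,0
Undisturbed,B,57,0,0,5,0,88,5,0,0,1,0,0
Disturbed,C,7,0,0,2,0,3,0,10,0,0,0,0
Disturbed,C,6,0,0,3,0,1,0,180,1,0,0,0
Undisturbed,C,10,0,1,5,0,3,0,0,1,0,0,0
Undisturbed,C,60,1,4,0,0,0,0,10,0,0,0,0
Disturbed,D,69,4,1,1,0,29,0,3,3,0,0,0
Disturbed,D,5,1,0,1,0,47,1,1,5,0,0,0
Undisturbed,D,142,3,6,2,0,6,0,0,0,0,2,0
Undisturbed,D,96,2,7,1,0,2,0,0,0,0,0,0
"""

#: checksum of the embedded CSV text, guarding fixture integrity
TASMANIA_SHA256 = hashlib.sha256(_TASMANIA_CSV.encode()).hexdigest()


@dataclass
class Dataset:
    """A response matrix with its aligned design table."""

    responses: pd.DataFrame
    design_table: pd.DataFrame
    family: str
    note: str = ""

    @property
    def Y(self) -> np.ndarray:
        return self.responses.to_numpy(dtype=float)

    @property
    def n(self) -> int:
        return len(self.responses)

    @property
    def p(self) -> int:
        return self.responses.shape[1]

    @property
    def var_names(self) -> list[str]:
        return list(self.responses.columns)


def tasmania_dataset() -> Dataset:
    """The 16 x 12 Tasmania copepod counts with treatment/block design."""
    df = pd.read_csv(io.StringIO(_TASMANIA_CSV))
    design = df[["treatment", "block"]].copy()
    responses = df.drop(columns=["treatment", "block"])
    return Dataset(
        responses=responses,
        design_table=design,
        family="negative.binomial",
        note="Copepod abundances, Eagle Neck, Tasmania; randomized blocks"
        " (4 blocks x {disturbed, undisturbed} x 2 replicates).",
    )


def tasmania_csv_text() -> str:
    """Raw CSV text of the fixture (responses + design columns)."""
    return _TASMANIA_CSV
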