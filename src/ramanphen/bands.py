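"""Built-in whole-cell Raman band assignments (cm^-1).

A compact table of the bands most informative for cyanobacterial
phenotyping; used to annotate contribution tables and to parameterise the
synthetic-spectrum generator.  Assignments follow common whole-cell
usage: glycogen 1,049/1,150/1,155; carotenoids 1,156/1,520; chlorophyll
a-associated 1,239; phenylalanine 1,005; amide I ~1,660.
"""

from __future__ import annotations

import pandas as pd

BAND_TABLE = pd.DataFrame(
    [
        (430, "sterols"),
        (509, "phosphatidylinositol"),
        (575, "phosphatidylinositol"),
        (719, "phospholipids"),
        (750, "protein"),
        (1005, "phenylalanine"),
        (1049, "glycogen"),
        (1063, "lipids"),
        (1074, "lipids"),
        (1102, "protein"),
        (1150, "glycogen"),
        (1155, "glycogen"),
        (1156, "carotenoids"),
        (1239, "chlorophyll a"),
        (1328, "phospholipids"),
        (1520, "carotenoids"),
        (1620, "porphyrin"),
        (1660, "amide I"),
    ],
    columns=["shift", "assignment"],
)


def assign_band(shift: float, tolerance: float = 5.0) -> str | None:
    """Nearest band label within ``tolerance`` cm^-1, else None."""
    d = (BAND_TABLE["shift"] - shift).abs()
    i = d.idxmin()
    if d[i] <= tolerance:
        return str(BAND_TABLE.loc[i, "assignment"])
    return None
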